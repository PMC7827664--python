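"""Exact HPD intervals and closed-form likelihood-approximate intervals.

Two families of credible intervals for the Beta-Binomial model:

* exact highest posterior density (HPD) intervals of the Beta posterior, on
  the proportion scale and on the log-odds scale — no closed form, obtained
  by root-finding (or, for the log-odds, optionally by the sample shortest
  window over Monte Carlo posterior draws);
* likelihood-approximate intervals from the normal approximation of the
  likelihood centred at the MLE ``x̄ = s/n`` with standard error
  ``sqrt(x̄(1−x̄)/n)``, and its delta-method transform for the log-odds.
  These have closed forms and do not depend on the prior.

The HPD solver is parameterized by the lower-tail probability ``p`` of the
lower bound: the candidate interval ``[Q(p), Q(p + level)]`` always has
posterior probability exactly ``level``, and the HPD interval is the ``p``
at which the densities at the two bounds match (equivalently, the width
``Q(p + level) − Q(p)`` is minimal).  The density gap is monotone in ``p``
for a unimodal posterior, so bracketed root-finding suffices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .model import BetaParams, BinomialSample, logodds_density

__all__ = [
    "Scale",
    "Method",
    "CredibleInterval",
    "DegenerateSampleError",
    "hpd_beta",
    "hpd_logodds",
    "approx_interval_proportion",
    "approx_interval_logodds",
]

_Z_CACHE: dict[float, float] = {}


def normal_quantile(level: float) -> float:
    """z_{1-gamma/2} for a two-sided interval of credibility ``level``."""
    try:
        return _Z_CACHE[level]
    except KeyError:
        z = float(stats.norm.ppf(0.5 + level / 2.0))
        _Z_CACHE[level] = z
        return z


class Scale(str, enum.Enum):
    PROPORTION = "proportion"
    LOG_ODDS = "log_odds"


class Method(str, enum.Enum):
    HPD_EXACT = "hpd_exact"
    HPD_MC = "hpd_mc"
    LIKELIHOOD_APPROX = "likelihood_approx"


class DegenerateSampleError(ValueError):
    """Raised when a log-odds quantity is requested for s in {0, n}."""


@dataclass(frozen=True)
class CredibleInterval:
    """A credible interval ``[lower, upper]`` with its construction metadata.

    ``degenerate`` flags the zero-width point interval produced by the
    likelihood approximation when the sample mean is 0 or 1.
    """

    lower: float
    upper: float
    level: float
    scale: Scale
    method: Method
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must lie in (0,1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.degenerate != (self.lower == self.upper):
            raise ValueError("degenerate flag must mark zero-width intervals")

    @property
    def width(self) -> float:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# Exact HPD, proportion scale
# ---------------------------------------------------------------------------

def _beta_logpdf_gap(a: float, b: float, lo: np.ndarray, up: np.ndarray):
    """log pdf(lo) − log pdf(up) for Be(a, b); the betaln term cancels."""
    return (a - 1.0) * (np.log(lo) - np.log(up)) + \
           (b - 1.0) * (np.log1p(-lo) - np.log1p(-up))


def hpd_beta(post: BetaParams, level: float = 0.90) -> CredibleInterval:
    """Exact HPD interval of a Beta posterior on the proportion scale.

    For an interior mode (``alpha > 1`` and ``beta > 1``) the bounds satisfy
    equal density and exact coverage.  For a boundary mode (monotone density)
    the HPD set is one-sided: ``[0, Q(level)]`` for a decreasing density,
    ``[Q(1−level), 1]`` for an increasing one.  A U-shaped density
    (``alpha < 1`` and ``beta < 1``) can have a disconnected HPD region and
    is rejected.
    """
    a, b = post.alpha, post.beta
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0,1), got {level}")
    if a < 1.0 and b < 1.0:
        raise ValueError(
            "U-shaped Beta posterior (alpha < 1 and beta < 1): the HPD set "
            "may be disconnected and is not supported"
        )
    if a > 1.0 and b > 1.0:
        gamma = 1.0 - level

        def density_gap(p: float) -> float:
            lo = special.betaincinv(a, b, p)
            up = special.betaincinv(a, b, p + level)
            return float(_beta_logpdf_gap(a, b, lo, up))

        # pdf(Q(p)) - pdf(Q(p+level)) rises from -inf-ish to +inf-ish on
        # (0, gamma); bracket slightly inside to avoid log(0).  For shapes a
        # hair above 1 the density decays so slowly at the boundary that the
        # root sits closer to an endpoint than double precision resolves; the
        # interval is then numerically one-sided in tail probability.
        eps = 1e-14
        lo_gap, hi_gap = density_gap(eps), density_gap(gamma - eps)
        if lo_gap >= 0.0:
            p_star = eps
        elif hi_gap <= 0.0:
            p_star = gamma - eps
        else:
            p_star = optimize.brentq(density_gap, eps, gamma - eps,
                                     xtol=1e-14, rtol=8.9e-16)
        lower = float(special.betaincinv(a, b, p_star))
        upper = float(special.betaincinv(a, b, p_star + level))
    elif a <= 1.0:  # decreasing (or uniform) density: left-anchored
        lower = 0.0
        upper = float(special.betaincinv(a, b, level))
    else:  # b <= 1: increasing density: right-anchored
        lower = float(special.betaincinv(a, b, 1.0 - level))
        upper = 1.0
    return CredibleInterval(lower, upper, level, Scale.PROPORTION,
                            Method.HPD_EXACT)


def hpd_beta_bounds(alpha, beta, level: float = 0.90,
                    iterations: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized HPD bounds for arrays of Beta shape parameters.

    Used by the predictive layer, which needs the HPD interval at every atom
    of the binomial predictive distribution.  Interior-mode entries are
    solved by bisection on the lower-tail probability (64 halvings of
    [0, 1−level] reach the limits of double precision); boundary-mode
    entries fall back to one-sided quantile intervals, mirroring
    :func:`hpd_beta`.
    """
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any((a < 1.0) & (b < 1.0)):
        raise ValueError("U-shaped Beta posterior in batch HPD")
    lower = np.empty_like(a)
    upper = np.empty_like(a)

    left = (a <= 1.0) & (b > 1.0) | ((a <= 1.0) & (b <= 1.0) & (a <= b))
    right = (b <= 1.0) & (a > 1.0) | ((a <= 1.0) & (b <= 1.0) & (a > b))
    interior = ~(left | right)

    if left.any():
        lower[left] = 0.0
        upper[left] = special.betaincinv(a[left], b[left], level)
    if right.any():
        lower[right] = special.betaincinv(a[right], b[right], 1.0 - level)
        upper[right] = 1.0
    if interior.any():
        ai, bi = a[interior], b[interior]
        lo_p = np.zeros_like(ai)
        hi_p = np.full_like(ai, 1.0 - level)
        for _ in range(iterations):
            mid = 0.5 * (lo_p + hi_p)
            lo_q = special.betaincinv(ai, bi, mid)
            up_q = special.betaincinv(ai, bi, mid + level)
            with np.errstate(divide="ignore", invalid="ignore"):
                gap = _beta_logpdf_gap(ai, bi, lo_q, up_q)
            # density at the lower bound still below the upper bound's:
            # move the window right.
            move_up = gap < 0.0
            # p = 0 has lo_q = 0 and gap = -inf for a > 1: handled by move_up
            lo_p = np.where(move_up, mid, lo_p)
            hi_p = np.where(move_up, hi_p, mid)
        p = 0.5 * (lo_p + hi_p)
        lower[interior] = special.betaincinv(ai, bi, p)
        upper[interior] = special.betaincinv(ai, bi, p + level)
    return lower, upper


# ---------------------------------------------------------------------------
# Exact and Monte Carlo HPD, log-odds scale
# ---------------------------------------------------------------------------

def _logodds_logpdf_gap(a: float, b: float, p_lo, p_up) -> np.ndarray:
    """log density gap of logit(theta) at the quantile pair (p_lo, p_up)."""
    lo = special.betaincinv(a, b, p_lo)
    up = special.betaincinv(a, b, p_up)
    # log f_psi(psi(q)) = a*log(q) + b*log(1-q) - log B(a,b); betaln cancels
    return a * (np.log(lo) - np.log(up)) + b * (np.log1p(-lo) - np.log1p(-up))


def hpd_logodds(post: BetaParams, level: float = 0.90, mode: str = "exact",
                draws: int = 100_000, seed: int | None = None,
                rng: np.random.Generator | None = None) -> CredibleInterval:
    """HPD interval for the log-odds ``psi = logit(theta)``.

    ``mode="exact"`` solves the equal-density/exact-coverage equations on the
    transformed density by bracketed root-finding; the log-odds density is
    unimodal for every positive shape pair, so no boundary cases arise.
    ``mode="mc"`` follows the simulation recipe: draw from the Beta
    posterior, transform by the logit, and take the shortest window
    containing ``ceil(level * draws)`` of the sorted draws (leftmost window
    on ties), the usual sample HPD estimator.
    """
    a, b = post.alpha, post.beta
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0,1), got {level}")
    if mode == "exact":
        gamma = 1.0 - level

        def density_gap(p: float) -> float:
            return float(_logodds_logpdf_gap(a, b, p, p + level))

        eps = 1e-14
        p_star = optimize.brentq(density_gap, eps, gamma - eps,
                                 xtol=1e-14, rtol=8.9e-16)
        lower = float(special.logit(special.betaincinv(a, b, p_star)))
        upper = float(special.logit(special.betaincinv(a, b, p_star + level)))
        return CredibleInterval(lower, upper, level, Scale.LOG_ODDS,
                                Method.HPD_EXACT)
    if mode == "mc":
        if draws < 10_000:
            raise ValueError("mc mode needs at least 10^4 draws")
        if rng is None:
            rng = np.random.default_rng(seed)
        theta = rng.beta(a, b, size=draws)
        psi = np.sort(special.logit(theta))
        window = int(np.ceil(level * draws))
        widths = psi[window - 1:] - psi[:draws - window + 1]
        j = int(np.argmin(widths))  # argmin takes the leftmost minimum
        return CredibleInterval(float(psi[j]), float(psi[j + window - 1]),
                                level, Scale.LOG_ODDS, Method.HPD_MC)
    raise ValueError(f"unknown mode {mode!r}")


def hpd_logodds_bounds(alpha, beta, level: float = 0.90,
                       iterations: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact log-odds HPD bounds (see :func:`hpd_beta_bounds`)."""
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    lo_p = np.zeros_like(a)
    hi_p = np.full_like(a, 1.0 - level)
    for _ in range(iterations):
        mid = 0.5 * (lo_p + hi_p)
        lo_q = special.betaincinv(a, b, mid)
        up_q = special.betaincinv(a, b, mid + level)
        with np.errstate(divide="ignore", invalid="ignore"):
            gap = a * (np.log(lo_q) - np.log(up_q)) + \
                  b * (np.log1p(-lo_q) - np.log1p(-up_q))
        move_up = gap < 0.0
        lo_p = np.where(move_up, mid, lo_p)
        hi_p = np.where(move_up, hi_p, mid)
    p = 0.5 * (lo_p + hi_p)
    lower = special.logit(special.betaincinv(a, b, p))
    upper = special.logit(special.betaincinv(a, b, p + level))
    return lower, upper


# ---------------------------------------------------------------------------
# Likelihood-approximate intervals
# ---------------------------------------------------------------------------

def approx_interval_proportion(data: BinomialSample,
                               level: float = 0.90) -> CredibleInterval:
    """Likelihood-normal interval ``x̄ ∓ z sqrt(x̄(1−x̄)/n)``.

    Bounds are deliberately not clipped to [0, 1]; the extended posterior
    cdf downstream handles out-of-range bounds, and non-containment in the
    parameter space is a documented drawback of this interval.  When the
    sample mean is 0 or 1 the estimated standard error vanishes and the
    interval collapses to a flagged point interval.
    """
    xbar = data.mean
    if data.is_degenerate:
        return CredibleInterval(xbar, xbar, level, Scale.PROPORTION,
                                Method.LIKELIHOOD_APPROX, degenerate=True)
    half = normal_quantile(level) * np.sqrt(xbar * (1.0 - xbar) / data.n)
    return CredibleInterval(xbar - half, xbar + half, level,
                            Scale.PROPORTION, Method.LIKELIHOOD_APPROX)


def approx_interval_logodds(data: BinomialSample,
                            level: float = 0.90) -> CredibleInterval:
    """Delta-method interval for the log-odds.

    Centre ``logit(x̄)``, half-width ``z / sqrt(n x̄ (1 − x̄))`` from
    ``|g'(x̄)| / sqrt(I_n(x̄))`` with ``g = logit``.  This is not the logit
    transform of the proportion-scale interval: the delta method linearizes
    ``g`` at the MLE instead of mapping the bounds through it.
    """
    if data.is_degenerate:
        raise DegenerateSampleError(
            f"log-odds undefined for s = {data.successes} of n = {data.n}"
        )
    xbar = data.mean
    centre = float(special.logit(xbar))
    half = normal_quantile(level) / np.sqrt(data.n * xbar * (1.0 - xbar))
    return CredibleInterval(centre - half, centre + half, level,
                            Scale.LOG_ODDS, Method.LIKELIHOOD_APPROX)
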