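"""Preposterior analysis and sample-size determination.

Before the trial runs, the dataset ``X_n`` — and therefore any discrepancy
``D(X_n)`` between the likelihood-approximate interval and the exact HPD
interval — is a random object.  Its expectation under the sampling
distribution ``Binomial(n, theta_d)`` at a design value ``theta_d``,

    e_n = E_d[D(X_n)],

decays as ``n`` grows, and the optimal sample size is the first ``n`` whose
expected discrepancy falls below a threshold:

    n* = min{ n : e_n < eps }.

Four criteria are supported: the calibration discrepancy ``P``, the bound
distance ``B``, and the average-length criterion (ALC) applied to the exact
HPD interval (``L_exact``) and to the closed-form approximate interval
(``L_approx``).  The binomial predictive has ``n + 1`` atoms, so ``e_n`` can
be computed by exact enumeration; a seeded Monte Carlo engine mirroring the
simulation recipe (draw ``N`` datasets, average ``D``) is provided as well.

Degenerate outcomes ``s ∈ {0, n}`` collapse the approximate interval.  On
the proportion scale they score maximal miscalibration (``P = 1``) and ``B``
is taken against the point interval; on the log-odds scale the approximate
interval does not exist, so such outcomes are excluded from ``e_n^B`` (with
the remaining probability renormalized) but never from ``e_n^P``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .intervals import (Scale, hpd_beta_bounds, hpd_logodds_bounds,
                        normal_quantile)
from .model import BetaParams, DesignValue

__all__ = [
    "Criterion",
    "Engine",
    "DesignConfig",
    "ExpectedCurve",
    "SSDResult",
    "expected_discrepancy_exact",
    "expected_discrepancy_mc",
    "expected_length",
    "expected_curve",
    "optimal_n",
    "NOT_FOUND",
]

#: Sentinel returned when no n <= n_max satisfies the criterion.
NOT_FOUND = -1

#: Predictive atoms with less mass than this are dropped from HPD-based
#: enumeration sums (criteria B and L_exact); the neglected mass is below
#: 1e-12 in total, far inside every tolerance used here.  The calibration
#: criterion P is cheap and always enumerated in full.
_ATOM_TAIL_MASS = 1e-13

_BRACKET_FACTOR = 1.3


class Criterion(str, enum.Enum):
    P = "P"
    B = "B"
    L_EXACT = "L_exact"
    L_APPROX = "L_approx"


class Engine(str, enum.Enum):
    EXACT = "exact_enumeration"
    MONTE_CARLO = "monte_carlo"


@dataclass(frozen=True)
class DesignConfig:
    """Everything a preposterior run needs.

    ``epsilon_p`` and ``epsilon_b`` are the thresholds for the two
    discrepancy criteria (default 0.01, i.e., 1% of the unit parameter
    space); ``epsilon_l`` is the ALC width threshold (default 0.1).
    ``level`` is the credibility ``1 − γ`` of every interval involved.
    """

    theta_d: DesignValue
    prior: BetaParams
    level: float = 0.90
    epsilon_p: float = 0.01
    epsilon_b: float = 0.01
    epsilon_l: float = 0.1
    n_min: int = 1
    n_max: int = 10_000
    engine: Engine = Engine.EXACT
    mc_draws: int = 10_000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must lie in (0,1), got {self.level}")
        for name in ("epsilon_p", "epsilon_b", "epsilon_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError(
                f"need 1 <= n_min <= n_max, got [{self.n_min}, {self.n_max}]"
            )
        if self.engine is Engine.MONTE_CARLO and self.mc_draws < 1000:
            raise ValueError("mc_draws must be >= 1000 for the MC engine")

    def threshold(self, criterion: Criterion) -> float:
        if criterion is Criterion.P:
            return self.epsilon_p
        if criterion is Criterion.B:
            return self.epsilon_b
        return self.epsilon_l


@dataclass(frozen=True)
class ExpectedCurve:
    """Evaluated points of an expected-discrepancy (or length) curve."""

    criterion: Criterion
    scale: Scale
    ns: tuple[int, ...]
    values: tuple[float, ...]
    engine: Engine
    stderrs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.ns) != len(self.values):
            raise ValueError("ns and values must have equal length")
        if any(b <= a for a, b in zip(self.ns, self.ns[1:])):
            raise ValueError("ns must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("expected discrepancies are nonnegative")

    def value_at(self, n: int) -> float:
        return self.values[self.ns.index(n)]


@dataclass(frozen=True)
class SSDResult:
    """Optimal sample size plus the evaluated curve that justifies it."""

    n_star: int
    criterion: Criterion
    scale: Scale
    threshold: float
    curve: ExpectedCurve
    config: DesignConfig

    @property
    def found(self) -> bool:
        return self.n_star != NOT_FOUND


# ---------------------------------------------------------------------------
# Per-outcome discrepancies, vectorized over the binomial support
# ---------------------------------------------------------------------------

def _approx_bounds_proportion(n: int, s: np.ndarray, level: float):
    """Eq-(3)-style bounds for every outcome; degenerate rows give x̄ twice."""
    xbar = s / n
    half = normal_quantile(level) * np.sqrt(xbar * (1.0 - xbar) / n)
    return xbar - half, xbar + half


def _approx_bounds_logodds(n: int, s: np.ndarray, level: float):
    """Delta-method bounds; caller must exclude degenerate outcomes."""
    xbar = s / n
    centre = special.logit(xbar)
    half = normal_quantile(level) / np.sqrt(n * xbar * (1.0 - xbar))
    return centre - half, centre + half


def _calibration_by_outcome(n: int, prior: BetaParams, level: float,
                            scale: Scale) -> np.ndarray:
    """P(n, s) for s = 0..n.  Degenerate outcomes score 1."""
    s = np.arange(n + 1)
    alpha = prior.alpha + s
    beta = prior.beta + n - s
    out = np.ones(n + 1)
    inner = (s > 0) & (s < n)
    si = s[inner]
    if scale is Scale.PROPORTION:
        lo, up = _approx_bounds_proportion(n, si, level)
        lo, up = np.clip(lo, 0.0, 1.0), np.clip(up, 0.0, 1.0)
    else:
        lo, up = _approx_bounds_logodds(n, si, level)
        lo, up = special.expit(lo), special.expit(up)
    cov = special.betainc(alpha[inner], beta[inner], up) \
        - special.betainc(alpha[inner], beta[inner], lo)
    out[inner] = np.abs(cov - level) / level
    return out


def _bound_distance_by_outcome(n: int, s: np.ndarray, prior: BetaParams,
                               level: float, scale: Scale) -> np.ndarray:
    """B(n, s) for the given outcomes (already restricted by the caller)."""
    alpha = prior.alpha + s
    beta = prior.beta + n - s
    if scale is Scale.PROPORTION:
        lo_a, up_a = _approx_bounds_proportion(n, s, level)
        lo_e, up_e = hpd_beta_bounds(alpha, beta, level)
    else:
        lo_a, up_a = _approx_bounds_logodds(n, s, level)
        lo_e, up_e = hpd_logodds_bounds(alpha, beta, level)
    return np.abs(lo_a - lo_e) + np.abs(up_a - up_e)


def _support(n: int, theta_d: float, full: bool) -> np.ndarray:
    """Binomial outcomes to enumerate; optionally trimmed to the bulk."""
    if full or n <= 64:
        return np.arange(n + 1)
    lo = int(stats.binom.ppf(_ATOM_TAIL_MASS, n, theta_d))
    hi = int(stats.binom.ppf(1.0 - _ATOM_TAIL_MASS, n, theta_d))
    return np.arange(max(lo - 1, 0), min(hi + 2, n + 1))


# ---------------------------------------------------------------------------
# Expected discrepancies and lengths
# ---------------------------------------------------------------------------

def expected_discrepancy_exact(n: int, cfg: DesignConfig,
                               criterion: Criterion = Criterion.P,
                               scale: Scale = Scale.PROPORTION) -> float:
    """e_n by exact enumeration over the binomial predictive atoms."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    theta_d = cfg.theta_d.theta_d
    if criterion is Criterion.P:
        pmf = stats.binom.pmf(np.arange(n + 1), n, theta_d)
        return float(pmf @ _calibration_by_outcome(n, cfg.prior, cfg.level,
                                                   scale))
    if criterion is Criterion.B:
        s = _support(n, theta_d, full=False)
        pmf = stats.binom.pmf(s, n, theta_d)
        if scale is Scale.LOG_ODDS:
            inner = (s > 0) & (s < n)
            s, pmf = s[inner], pmf[inner]
            pmf = pmf / pmf.sum()  # exclude-and-renormalize policy
        dist = _bound_distance_by_outcome(n, s, cfg.prior, cfg.level, scale)
        return float(pmf @ dist)
    raise ValueError(f"use expected_length for criterion {criterion}")


def expected_discrepancy_mc(n: int, cfg: DesignConfig,
                            criterion: Criterion = Criterion.P,
                            scale: Scale = Scale.PROPORTION,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[float, float]:
    """Monte Carlo e_n: average the discrepancy over N simulated datasets.

    Returns the estimate and the Monte Carlo standard error of the mean.
    Draws are aggregated over the distinct simulated outcomes, so the cost
    is bounded by the support size rather than by ``N``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(cfg.mc_seed)
    draws = rng.binomial(n, cfg.theta_d.theta_d, size=cfg.mc_draws)
    s, counts = np.unique(draws, return_counts=True)

    if criterion is Criterion.P:
        d_all = _calibration_by_outcome(n, cfg.prior, cfg.level, scale)
        d = d_all[s]
    elif criterion is Criterion.B:
        if scale is Scale.LOG_ODDS:
            inner = (s > 0) & (s < n)
            s, counts = s[inner], counts[inner]
            if counts.sum() == 0:
                raise ValueError("all MC draws degenerate; increase n or N")
        d = _bound_distance_by_outcome(n, s, cfg.prior, cfg.level, scale)
    else:
        raise ValueError(f"use expected_length for criterion {criterion}")

    n_eff = counts.sum()
    mean = float((counts @ d) / n_eff)
    var = float((counts @ (d - mean) ** 2) / n_eff)
    stderr = math.sqrt(var / n_eff)
    return mean, stderr


def expected_length(n: int, cfg: DesignConfig,
                    which: Criterion = Criterion.L_APPROX,
                    scale: Scale = Scale.PROPORTION) -> float:
    """Expected interval width under the design sampling distribution.

    ``L_exact`` averages the width of the exact HPD interval of the posterior
    at every predictive atom; ``L_approx`` averages the closed-form
    approximate width (degenerate outcomes contribute width zero on the
    proportion scale and are excluded, with renormalization, on the
    log-odds scale).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    theta_d = cfg.theta_d.theta_d
    if which is Criterion.L_APPROX:
        s = np.arange(n + 1)
        pmf = stats.binom.pmf(s, n, theta_d)
        inner = (s > 0) & (s < n)
        if not inner.any():
            # n = 1: the approximate interval exists on no outcome, so the
            # expected width is undefined rather than zero.
            return math.inf
        xbar = s[inner] / n
        if scale is Scale.PROPORTION:
            width = 2.0 * normal_quantile(cfg.level) * \
                np.sqrt(xbar * (1.0 - xbar) / n)
            return float(pmf[inner] @ width)  # degenerate: width 0
        width = 2.0 * normal_quantile(cfg.level) / \
            np.sqrt(n * xbar * (1.0 - xbar))
        return float((pmf[inner] / pmf[inner].sum()) @ width)
    if which is Criterion.L_EXACT:
        s = _support(n, theta_d, full=False)
        pmf = stats.binom.pmf(s, n, theta_d)
        alpha = cfg.prior.alpha + s
        beta = cfg.prior.beta + n - s
        if scale is Scale.PROPORTION:
            lo, up = hpd_beta_bounds(alpha, beta, cfg.level)
        else:
            inner = (s > 0) & (s < n)
            s, pmf = s[inner], pmf[inner]
            pmf = pmf / pmf.sum()
            lo, up = hpd_logodds_bounds(cfg.prior.alpha + s,
                                        cfg.prior.beta + n - s, cfg.level)
        return float(pmf @ (up - lo))
    raise ValueError(f"{which} is not a length criterion")


def _evaluate(n: int, cfg: DesignConfig, criterion: Criterion, scale: Scale,
              rng: np.random.Generator | None) -> tuple[float, float | None]:
    if criterion in (Criterion.L_EXACT, Criterion.L_APPROX):
        return expected_length(n, cfg, criterion, scale), None
    if cfg.engine is Engine.EXACT:
        return expected_discrepancy_exact(n, cfg, criterion, scale), None
    return expected_discrepancy_mc(n, cfg, criterion, scale, rng)


def expected_curve(cfg: DesignConfig, n_grid, criterion: Criterion,
                   scale: Scale = Scale.PROPORTION) -> ExpectedCurve:
    """Evaluate e_n on an explicit grid of sample sizes."""
    ns = [int(n) for n in n_grid]
    if any(b <= a for a, b in zip(ns, ns[1:])) or not ns:
        raise ValueError("n_grid must be nonempty and strictly increasing")
    rng = np.random.default_rng(cfg.mc_seed)
    values, errs = [], []
    for n in ns:
        v, e = _evaluate(n, cfg, criterion, scale, rng)
        values.append(v)
        errs.append(e)
    stderrs = None if errs[0] is None else tuple(errs)
    return ExpectedCurve(criterion, scale, tuple(ns), tuple(values),
                         cfg.engine, stderrs)


def optimal_n(cfg: DesignConfig, criterion: Criterion = Criterion.P,
              scale: Scale = Scale.PROPORTION) -> SSDResult:
    """Smallest n in [n_min, n_max] with e_n strictly below the threshold.

    A geometric grid (factor 1.3) first brackets the crossing, then every n
    inside the final bracket is evaluated so that first-crossing semantics
    hold even if the curve is locally non-monotone.  Returns the sentinel
    ``n_star = NOT_FOUND`` when no evaluated n qualifies by ``n_max``.
    """
    eps = cfg.threshold(criterion)
    rng = np.random.default_rng(cfg.mc_seed)
    evaluated: dict[int, tuple[float, float | None]] = {}

    def value(n: int) -> float:
        if n not in evaluated:
            evaluated[n] = _evaluate(n, cfg, criterion, scale, rng)
        return evaluated[n][0]

    # geometric bracketing pass
    n = cfg.n_min
    prev = None
    hit = None
    while True:
        if value(n) < eps:
            hit = n
            break
        if n >= cfg.n_max:
            break
        prev = n
        n = min(cfg.n_max, max(n + 1, math.ceil(n * _BRACKET_FACTOR)))

    n_star = NOT_FOUND
    if hit is not None:
        n_star = hit
        if prev is not None:
            # exhaustive scan inside the bracket (prev, hit)
            for m in range(prev + 1, hit):
                if value(m) < eps:
                    n_star = m
                    break

    ns = tuple(sorted(evaluated))
    values = tuple(evaluated[m][0] for m in ns)
    errs = tuple(evaluated[m][1] for m in ns)
    stderrs = None if errs[0] is None else errs
    curve = ExpectedCurve(criterion, scale, ns, values, cfg.engine, stderrs)
    return SSDResult(n_star, criterion, scale, eps, curve, cfg)
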