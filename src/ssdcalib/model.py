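"""Conjugate Beta-Binomial machinery.

Bernoulli observations :math:`X_i \\mid \\theta \\sim \\mathrm{Ber}(\\theta)`
with a conjugate prior :math:`\\theta \\sim \\mathrm{Be}(\\alpha, \\beta)` lead
to the posterior :math:`\\mathrm{Be}(\\alpha + s_n, \\beta + n - s_n)`, where
``s_n`` is the number of successes.  This module holds the prior/posterior
parameters, the sufficient statistic, the design value used in preposterior
calculations, and the posterior distribution on two scales: the proportion
``theta`` and the log-odds ``psi = logit(theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


__all__ = [
    "BetaParams",
    "BinomialSample",
    "DesignValue",
    "posterior_update",
    "posterior_cdf",
    "logodds_density",
    "logodds_cdf",
]


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta distribution (prior or posterior).

    The prior mean is ``alpha / (alpha + beta)`` and the prior sample size —
    the number of pseudo-observations the prior is worth — is
    ``alpha + beta``.  Non-integer shapes are first-class: eliciting a prior
    by mean and sample size routinely produces values such as (10.8, 9.2).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shape parameters must be positive, got "
                f"({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sample_size(self) -> float:
        """Prior sample size ``alpha + beta``."""
        return self.alpha + self.beta

    @property
    def mode(self) -> float:
        """Interior mode; requires ``alpha > 1`` and ``beta > 1``."""
        if not (self.alpha > 1 and self.beta > 1):
            raise ValueError("mode is interior only for alpha > 1 and beta > 1")
        return (self.alpha - 1) / (self.alpha + self.beta - 2)


@dataclass(frozen=True)
class BinomialSample:
    """Sufficient statistic ``(n, successes)`` of a Bernoulli sample."""

    n: int
    successes: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be nonnegative, got {self.n}")
        if not (0 <= self.successes <= self.n):
            raise ValueError(
                f"successes must lie in [0, {self.n}], got {self.successes}"
            )

    @property
    def mean(self) -> float:
        """Sample mean, which is also the MLE of the proportion."""
        if self.n == 0:
            raise ValueError("empty sample has no mean")
        return self.successes / self.n

    @property
    def is_degenerate(self) -> bool:
        """True when every trial succeeded or every trial failed.

        At these outcomes the estimated standard error collapses to zero and
        the likelihood-approximate interval degenerates to a point.
        """
        return self.successes in (0, self.n)


@dataclass(frozen=True)
class DesignValue:
    """Parameter value generating future data in preposterior calculations."""

    theta_d: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_d < 1.0):
            raise ValueError(f"theta_d must lie in (0, 1), got {self.theta_d}")


def posterior_update(prior: BetaParams, data: BinomialSample) -> BetaParams:
    """Conjugate update: Be(a, b) + (n, s) -> Be(a + s, b + n - s)."""
    return BetaParams(prior.alpha + data.successes,
                      prior.beta + data.n - data.successes)


def posterior_cdf(post: BetaParams, t) -> np.ndarray | float:
    """Beta cdf extended to the whole real line.

    Returns 0 for ``t <= 0`` and 1 for ``t >= 1``.  The extension matters
    because likelihood-approximate interval bounds are not guaranteed to lie
    inside [0, 1]; their exact posterior probability must still be defined.
    """
    t_arr = np.asarray(t, dtype=float)
    out = special.betainc(post.alpha, post.beta, np.clip(t_arr, 0.0, 1.0))
    if np.ndim(t) == 0:
        return float(out)
    return out


def logodds_density(post: BetaParams, psi) -> np.ndarray | float:
    """Density of ``psi = logit(theta)`` for ``theta ~ Be(alpha, beta)``.

    Change of variables: with ``theta(psi) = expit(psi)`` the Jacobian is
    ``theta (1 - theta)``, so the density is
    ``Be-pdf(theta(psi)) * theta(psi) * (1 - theta(psi))``.  Computed in log
    space; both tails decay exponentially, so the density is unimodal for all
    positive shapes.
    """
    psi_arr = np.asarray(psi, dtype=float)
    a, b = post.alpha, post.beta
    # log f(psi) = a*log(theta) + b*log(1-theta) - log B(a, b)
    #            = -a*log(1+e^-psi) - b*log(1+e^psi) - log B(a, b)
    log_f = (-a * np.logaddexp(0.0, -psi_arr)
             - b * np.logaddexp(0.0, psi_arr)
             - special.betaln(a, b))
    out = np.exp(log_f)
    if np.ndim(psi) == 0:
        return float(out)
    return out


def logodds_cdf(post: BetaParams, psi) -> np.ndarray | float:
    """Cdf of ``psi = logit(theta)``: the Beta cdf at ``expit(psi)``."""
    theta = special.expit(np.asarray(psi, dtype=float))
    out = special.betainc(post.alpha, post.beta, theta)
    if np.ndim(psi) == 0:
        return float(out)
    return out
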