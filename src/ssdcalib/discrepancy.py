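"""Discrepancy measures between approximate and exact credible intervals.

For a single observed dataset two summaries quantify how far the
likelihood-approximate interval is from the exact Bayesian answer:

* the calibration discrepancy ``P(x_n) = |P(theta in C~ | x_n) − (1−γ)| /
  (1−γ)``: the normalized gap between the exact posterior probability of the
  approximate interval and its nominal credibility;
* the bound distance ``B(x_n) = |l~ − l| + |u~ − u|``: the summed absolute
  differences between the approximate and exact HPD endpoints.

``P`` is scale-free and lives in [0, 1] for the usual levels above one half;
``B`` carries the units of the parameter scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import CredibleInterval, Method, Scale
from .model import BetaParams, logodds_cdf, posterior_cdf

__all__ = [
    "DiscrepancySummary",
    "coverage_of",
    "calibration_discrepancy",
    "bound_discrepancy",
]


@dataclass(frozen=True)
class DiscrepancySummary:
    """Coverage and both discrepancies for one dataset.

    ``b_value_measure`` is ``None`` on the log-odds scale for degenerate
    samples, where the approximate interval (and hence ``B``) is undefined.
    """

    coverage: float
    p_value_measure: float
    b_value_measure: float | None
    degenerate: bool


def coverage_of(approx: CredibleInterval, post: BetaParams) -> float:
    """Exact posterior probability of an (approximate) interval.

    Proportion scale: extended Beta cdf difference, so bounds outside [0, 1]
    are handled.  Log-odds scale: cdf of ``logit(theta)``, i.e., the Beta cdf
    at the inverse-logit of the bounds.  A degenerate point interval carries
    no posterior mass under a continuous posterior.
    """
    if approx.degenerate:
        return 0.0
    if approx.scale is Scale.PROPORTION:
        return float(posterior_cdf(post, approx.upper)
                     - posterior_cdf(post, approx.lower))
    return float(logodds_cdf(post, approx.upper)
                 - logodds_cdf(post, approx.lower))


def calibration_discrepancy(coverage: float, level: float) -> float:
    """Relative calibration gap ``|coverage − level| / level``.

    Zero for a perfectly calibrated interval; one when the interval carries
    no posterior mass at all.  Bounded by 1 whenever ``level > 1/2``.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValueError(f"coverage must lie in [0,1], got {coverage}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0,1), got {level}")
    return abs(coverage - level) / level


def bound_discrepancy(approx: CredibleInterval,
                      exact: CredibleInterval) -> float:
    """Summed absolute endpoint distance ``|l~ − l| + |u~ − u|``.

    Both intervals must live on the same scale at the same level, and the
    exact one must be an exact HPD interval.  On the proportion scale a
    degenerate approximate interval is the point ``[x̄, x̄]`` and the formula
    applies unchanged; on the log-odds scale degenerate samples never reach
    this function (the approximate interval does not exist there).
    """
    if approx.scale is not exact.scale:
        raise ValueError(
            f"scale mismatch: {approx.scale.value} vs {exact.scale.value}"
        )
    if approx.level != exact.level:
        raise ValueError(
            f"level mismatch: {approx.level} vs {exact.level}"
        )
    if exact.method is not Method.HPD_EXACT:
        raise ValueError("exact interval must have method hpd_exact")
    return abs(approx.lower - exact.lower) + abs(approx.upper - exact.upper)
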