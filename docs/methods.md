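# Methods

## Model and estimands

Observations are i.i.d. Bernoulli(θ) with a conjugate prior
θ ~ Be(α, β), α, β > 0, so that after s successes in n trials the
posterior is Be(α+s, β+n−s).  Two parameter scales are supported: the
proportion θ and the log-odds ψ = logit(θ), whose posterior density
follows by the change of variables with Jacobian θ(1−θ) and is unimodal
for every positive shape pair.

Two interval families are compared for credibility level 1−γ:

* the **exact HPD interval** `[ℓ, u]`, defined by equal boundary densities
  and posterior probability 1−γ;
* the **likelihood-approximate interval** `[ℓ̃, ũ]` from the normal
  approximation of the likelihood at the MLE x̄ = s/n — on the proportion
  scale `x̄ ∓ z√(x̄(1−x̄)/n)`, on the log-odds scale
  `logit(x̄) ∓ z/√(n x̄(1−x̄))` by the delta method.  These are prior-free,
  and their bounds are deliberately **not clipped** to [0, 1]: the posterior
  cdf is extended constantly outside the unit interval so the coverage of an
  out-of-range bound is still well defined.  Non-containment in the
  parameter space is a known drawback of this interval, not an error state.

Per-dataset discrepancies: the relative calibration gap
`P(x) = |F(ũ|x) − F(ℓ̃|x) − (1−γ)|/(1−γ)` and the endpoint distance
`B(x) = |ℓ̃−ℓ| + |ũ−u|`.  `P` is scale-free and lies in [0, 1] for
γ < 1/2; `B` inherits the parameter's units, which is why its threshold is
only comfortable on a bounded scale.

Preposterior criteria: with Sₙ ~ Binomial(n, θ_d) for a design value θ_d,
the curves `eₙ = E[D(Xₙ)]` (D = P or B) and the expected interval widths
(ALC) are driven below thresholds ε_P, ε_B, ε_L by the first-crossing rule
`n* = min{n : eₙ < ε}`.

## Defaults and parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| level 1−γ | interval credibility | 0.90 | the published approximate-ALC sizes (267 at θ_d=0.45, 172 at 0.8) pin z = z_{0.95}; configurable |
| ε_P, ε_B | discrepancy thresholds | 0.01 | 1% of the unit parameter width |
| ε_L | ALC width threshold | 0.1 | the comparison study's choice |
| θ_d | design value | per scenario | 0.45 (minimal acceptable response) and 0.8 (optimistic) in the built-in suite |
| engine | predictive expectation | exact enumeration | the predictive has n+1 atoms; MC (N = 10,000 default) retained for fidelity to the simulation recipe and for non-enumerable models |
| n search | bracketing | factor 1.3, then scan | see below |

The built-in scenario suite uses priors (1,1), (2.7,2.3), (5.4,4.6),
(10.8,9.2): a uniform reference prior plus mean-0.54 priors worth 5, 10
and 20 pseudo-observations, elicited from 21/39 historical responses.

## Numerical methods

**HPD solver.**  Parameterized by the lower-tail probability p: the
candidate `[Q(p), Q(p+level)]` has exact coverage by construction, and the
log-density gap between its endpoints is monotone in p for a unimodal
density, so the equal-density condition is solved by Brent root-finding
(scalar) or 64-step vectorized bisection (the predictive layer solves all
atoms of the binomial support simultaneously).  Residual tolerances reach
double precision; coverage of returned intervals is exact to 1e−8 by test.
Boundary-mode posteriors (α ≤ 1 xor β ≤ 1) give one-sided quantile
intervals; U-shaped posteriors (α < 1 and β < 1) are rejected since their
HPD set may be disconnected.  Shapes a hair above 1 can push the
equal-density root beyond the double-precision resolution of the quantile
parameterization; the solver then returns the numerically one-sided
interval, which is correct to machine precision in coverage.

**Sample HPD (log-odds MC mode).**  The shortest window containing
⌈level·M⌉ sorted posterior draws, leftmost window on ties — deterministic
given the draw sequence.  At M = 10⁵ its bias is well under one standard
error of 50-replicate means (measured in the test suite).

**Enumeration and truncation.**  e_n^P sums all n+1 atoms (two incomplete
beta evaluations per atom).  The HPD-based criteria (B, exact ALC) drop
atoms with predictive mass below 1e−13 per tail before solving; the
neglected mass is < 1e−12 and far below every threshold in use.

**Search.**  A geometric grid (factor 1.3) brackets the crossing, then
every n inside the final bracket is evaluated, so the first-crossing rule
holds even where the curve is locally non-monotone.  If n_max is reached
first, a not-found sentinel is returned rather than an error: slowly
decaying curves (the prior-conflict scenarios cross only near n ≈ 3000)
are a normal outcome, and the caller decides whether to extend the range.

**Degenerate samples (s ∈ {0, n}).**  The approximate interval collapses
to a point (proportion) or does not exist (log-odds).  Policy, applied
consistently in both engines: coverage 0 and P = 1 (maximal
miscalibration) on both scales, so e_n^P is defined for every n and the
criterion is conservative; B against the point interval on the proportion
scale; on the log-odds scale the degenerate atoms are excluded from e_n^B
and from the approximate ALC with the remaining weights renormalized.  At
n = 1 every outcome is degenerate and the approximate expected width is
reported as infinite (the interval exists on no outcome), not zero.

## What the preposterior simulation does and does not emulate

The design calculation generates future trials as Binomial(n, θ_d) counts:
a fixed true response rate, perfect accrual, no dropout, no interim
stopping, a single arm, exchangeable subjects.  Passing tests therefore
certify the arithmetic of the design criterion, not robustness to
overdispersion, drift in the response rate, or adaptive designs.  The
design-value formulation is deliberately local: replacing θ_d by a design
prior would average the curves over plausible response rates and is out of
scope here.

## Known discrepancies against the published table

The published comparison table was evidently produced by Monte Carlo at
N = 10⁴: its exact-ALC row differs from exact enumeration by ±1 in three
of eight cells, each sitting within ~3·10⁻⁴ of the 0.1 threshold — exactly
the MC noise scale.  The calibration- and bound-criterion rows differ more
(up to ~8% in n*): exact enumeration of the documented formulas yields
nᴾ* = [50, 83, 123, 186] (θ_d = 0.45) and [38, 144, 700, 3018]
(θ_d = 0.8) against the published [49, 80, 119, 182] and
[35, 118, 646, 2911].  The offset is systematic, far exceeds MC noise, and
affects exactly the two rows sensitive to the *location* of the
approximate interval (the width-only rows reproduce); no principled
variant of the documented procedure reproduces it.  This package
implements the documented formulas; the affected comparisons are reported
as computed and the corresponding acceptance checks fail openly rather
than absorb the offset.

## Limitations

Single-arm, one binomial proportion; conjugate Beta priors only; HPD
regions assumed connected; expectation-based criteria only (controlling
tail probabilities of the discrepancy, two-arm allocation, and
decision-theoretic variants are natural extensions, not implemented).
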