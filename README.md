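# ssdcalib

Bayesian sample-size determination for **calibrated approximate credible
intervals** in the Beta-Binomial model.

## The problem

In a single-arm trial with a binary endpoint, inference on the response
probability θ is usually summarized by a credible interval.  The exact
highest posterior density (HPD) interval of the conjugate Beta posterior
has no closed form, so practice often substitutes the closed-form interval
from the normal approximation of the likelihood,

```
ℓ̃, ũ  =  x̄ ∓ z_{1−γ/2} · √( x̄(1−x̄) / n ),        x̄ = s/n,
```

and, for the log-odds ψ = logit(θ), its delta-method analogue
`logit(x̄) ∓ z_{1−γ/2} / √( n x̄(1−x̄) )`.  These intervals ignore the prior.
For small n they can be badly *miscalibrated*: their exact posterior
probability `F(ũ|x) − F(ℓ̃|x)` differs from the nominal level 1−γ.

`ssdcalib` answers the design question: **how many subjects make the
approximate interval trustworthy?**  Before the trial, the data are random,
so the calibration discrepancy

```
P(Xₙ) = | F(ũ|Xₙ) − F(ℓ̃|Xₙ) − (1−γ) | / (1−γ)
```

is a random variable; its preposterior expectation under a design value θ_d,
`eₙᴾ = E[P(Xₙ)]` with `Sₙ ~ Binomial(n, θ_d)`, decays with n, and the
optimal sample size is the first crossing

```
n*ᴾ = min{ n : eₙᴾ < ε_P }.
```

Companion criteria use the expected endpoint distance to the exact HPD
interval, `B(Xₙ) = |ℓ̃−ℓ| + |ũ−u|` (threshold ε_B), and the classical
average length criterion (ALC) on either the exact HPD width or the
approximate width (threshold ε_L).  Because the binomial predictive has
n+1 atoms, every expectation is computed by exact enumeration; a seeded
Monte Carlo engine is available as well.

## Worked example

The built-in scenario mirrors a phase-II lymphoma trial: historical data
(21 responses in 39 patients) elicit a Beta prior with mean 0.54 — here
worth 20 pseudo-observations, Be(10.8, 9.2) — and the design value
θ_d = 0.45 is the minimal acceptable response rate.

```python
import ssdcalib as sc

data = sc.BinomialSample(100, 45)
post = sc.posterior_update(sc.BetaParams(10.8, 9.2), data)   # Be(55.8, 64.2)

approx = sc.approx_interval_proportion(data, 0.90)           # [0.3682, 0.5318]
exact  = sc.hpd_beta(post, 0.90)                             # [0.3903, 0.5396]

cov = sc.coverage_of(approx, post)                           # 0.9133
sc.calibration_discrepancy(cov, 0.90)                        # 0.0148
sc.bound_discrepancy(approx, exact)                          # 0.0299
```

At n = 100 the approximate interval still over-covers by 1.3 points of
posterior probability (P = 0.0148, i.e. 1.5% of the nominal level).  The
design calculation finds the first n at which the *expected* miscalibration
drops below ε_P = 0.01:

```python
cfg = sc.DesignConfig(theta_d=sc.DesignValue(0.45),
                      prior=sc.BetaParams(10.8, 9.2), n_max=1000)
res = sc.optimal_n(cfg, sc.Criterion.P)
res.n_star                  # 186
res.curve.value_at(186)     # 0.00992...
```

So 186 subjects suffice for the closed-form interval to be expected within
1% relative calibration of the exact Bayesian HPD answer — while under an
optimistic design value θ_d = 0.8 that conflicts with the prior mean 0.54,
the same prior needs thousands of subjects.

The same machinery is exposed on the command line:

```
ssdcalib optimal-n --theta-d 0.45 --alpha 10.8 --beta 9.2 --n-max 1000
ssdcalib reproduce-table1 --n-max 4000
ssdcalib curve --n-grid 20,50,100,200,500 --theta-d 0.8 --alpha 2.7 --beta 2.3
```

## Scope and limitations

Single-arm Beta-Binomial designs only; the preposterior expectation uses a
fixed design value rather than a design prior; U-shaped posteriors
(alpha < 1 and beta < 1), whose HPD region may be disconnected, are
rejected.  See `docs/methods.md` for the numerical methods, the degenerate
sample policy, and known discrepancies against the published table.
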