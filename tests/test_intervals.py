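"""HPD construction on both scales and the closed-form approximate intervals."""

import numpy as np
import pytest
from scipy import special, stats

from ssdcalib import (BetaParams, BinomialSample, DegenerateSampleError,
                      Method, Scale, approx_interval_logodds,
                      approx_interval_proportion, hpd_beta, hpd_logodds,
                      posterior_cdf)
from ssdcalib.model import logodds_cdf


def hpd_grid_oracle(post, level, n_grid=100_000):
    """Brute-force HPD: sweep the lower bound, density-match the upper.

    Independent of the production solver: the upper bound is found by
    bisection on the density (not by quantile functions), and the best lower
    bound is chosen by scanning a dense grid for coverage closest to the
    level.
    """
    a, b = post.alpha, post.beta
    mode = (a - 1) / (a + b - 2)
    lo = np.linspace(1e-9, mode - 1e-9, n_grid)
    f_lo = stats.beta.pdf(lo, a, b)
    left, right = np.full_like(lo, mode), np.ones_like(lo)
    for _ in range(60):  # bisection: pdf decreases on [mode, 1]
        mid = 0.5 * (left + right)
        high = stats.beta.pdf(mid, a, b) > f_lo
        left = np.where(high, mid, left)
        right = np.where(high, right, mid)
    up = 0.5 * (left + right)
    cover = stats.beta.cdf(up, a, b) - stats.beta.cdf(lo, a, b)
    j = np.argmin(np.abs(cover - level))
    return lo[j], up[j]


class TestHpdBeta:
    def test_symmetric_posterior_equal_tails(self):
        ci = hpd_beta(BetaParams(2, 2), 0.90)
        assert ci.lower + ci.upper == pytest.approx(1.0, abs=1e-9)
        pdf_gap = stats.beta.pdf(ci.lower, 2, 2) - stats.beta.pdf(ci.upper, 2, 2)
        assert pdf_gap == pytest.approx(0.0, abs=1e-7)

    def test_monotone_density_is_left_anchored(self):
        # uniform prior, 10 trials, 0 successes: Be(1, 11) decreases on [0,1]
        ci = hpd_beta(BetaParams(1, 11), 0.90)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(stats.beta.ppf(0.90, 1, 11))

    def test_increasing_density_is_right_anchored(self):
        ci = hpd_beta(BetaParams(11, 1), 0.90)
        assert ci.upper == 1.0
        assert ci.lower == pytest.approx(stats.beta.ppf(0.10, 11, 1))

    def test_u_shaped_posterior_rejected(self):
        with pytest.raises(ValueError, match="U-shaped"):
            hpd_beta(BetaParams(0.5, 0.5), 0.90)

    def test_against_grid_oracle(self, lymphoma_posterior):
        ci = hpd_beta(lymphoma_posterior, 0.90)
        lo, up = hpd_grid_oracle(lymphoma_posterior, 0.90)
        assert ci.lower == pytest.approx(lo, abs=1e-4)
        assert ci.upper == pytest.approx(up, abs=1e-4)

    def test_exact_coverage_and_density_match(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b = rng.uniform(1.1, 60, size=2)
            post = BetaParams(a, b)
            ci = hpd_beta(post, 0.90)
            cover = posterior_cdf(post, ci.upper) - posterior_cdf(post, ci.lower)
            assert cover == pytest.approx(0.90, abs=1e-8)
            f_lo = stats.beta.pdf(ci.lower, a, b)
            f_up = stats.beta.pdf(ci.upper, a, b)
            assert f_lo == pytest.approx(f_up, rel=1e-6)

    def test_never_longer_than_equal_tails(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b = rng.uniform(1.1, 60, size=2)
            ci = hpd_beta(BetaParams(a, b), 0.90)
            et = stats.beta.ppf([0.05, 0.95], a, b)
            assert ci.width <= et[1] - et[0] + 1e-9
            if abs(a - b) > 0.05:
                assert ci.width < et[1] - et[0]

    def test_equals_equal_tails_when_symmetric(self):
        for k in (2.0, 7.5, 33.0):
            ci = hpd_beta(BetaParams(k, k), 0.90)
            et = stats.beta.ppf([0.05, 0.95], k, k)
            assert ci.width == pytest.approx(et[1] - et[0], abs=1e-6)


class TestHpdLogodds:
    def test_symmetric_about_zero(self):
        ci = hpd_logodds(BetaParams(2, 2), 0.90, mode="exact")
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-8)

    def test_exact_coverage(self, lymphoma_posterior):
        ci = hpd_logodds(lymphoma_posterior, 0.90, mode="exact")
        cover = logodds_cdf(lymphoma_posterior, ci.upper) - \
            logodds_cdf(lymphoma_posterior, ci.lower)
        assert cover == pytest.approx(0.90, abs=1e-8)

    def test_mc_matches_exact_within_mc_error(self, lymphoma_posterior):
        """Sample-HPD bounds agree with the root-finding bounds to 3 SE."""
        exact = hpd_logodds(lymphoma_posterior, 0.90, mode="exact")
        reps = np.array([
            [hpd_logodds(lymphoma_posterior, 0.90, mode="mc",
                         draws=10_000, seed=s).lower,
             hpd_logodds(lymphoma_posterior, 0.90, mode="mc",
                         draws=10_000, seed=s).upper]
            for s in range(50)
        ])
        for j, bound in enumerate((exact.lower, exact.upper)):
            se = reps[:, j].std(ddof=1) / np.sqrt(len(reps))
            # sample HPD carries a small shortest-window bias on top of MC
            # noise; compare the replicate mean at 3 SE plus that bias slack
            assert abs(reps[:, j].mean() - bound) < 3 * se + 0.01

    def test_mc_deterministic_given_seed(self, lymphoma_posterior):
        a = hpd_logodds(lymphoma_posterior, 0.90, mode="mc",
                        draws=20_000, seed=42)
        b = hpd_logodds(lymphoma_posterior, 0.90, mode="mc",
                        draws=20_000, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)


class TestApproxProportion:
    def test_frozen_values_n100_s45(self, sample_100_45):
        ci = approx_interval_proportion(sample_100_45, 0.90)
        half = stats.norm.isf(0.05) * np.sqrt(0.45 * 0.55 / 100)
        assert half == pytest.approx(0.0818304, abs=1e-6)
        assert ci.lower == pytest.approx(0.45 - half, abs=1e-12)
        assert ci.upper == pytest.approx(0.45 + half, abs=1e-12)

    def test_degenerate_sample_collapses(self):
        ci = approx_interval_proportion(BinomialSample(10, 0), 0.90)
        assert ci.degenerate and ci.lower == ci.upper == 0.0

    def test_symmetric_at_half(self):
        ci = approx_interval_proportion(BinomialSample(4, 2), 0.90)
        assert ci.lower == pytest.approx(1.0 - ci.upper)

    def test_bounds_not_clipped(self):
        ci = approx_interval_proportion(BinomialSample(5, 4), 0.90)
        assert ci.upper > 1.0  # 0.8 + 1.645*sqrt(0.16/5) = 1.09

    def test_converges_to_hpd(self):
        """Bayesian CLT: approximate and HPD bounds merge for large n."""
        n = 10_000
        s = round(n * 0.45)
        approx = approx_interval_proportion(BinomialSample(n, s), 0.90)
        exact = hpd_beta(BetaParams(1 + s, 1 + n - s), 0.90)
        gap = max(abs(approx.lower - exact.lower),
                  abs(approx.upper - exact.upper))
        assert gap < 5e-3


class TestApproxLogodds:
    def test_frozen_values_n100_s45(self, sample_100_45):
        ci = approx_interval_logodds(sample_100_45, 0.90)
        centre = np.log(0.45 / 0.55)
        half = stats.norm.isf(0.05) / np.sqrt(100 * 0.45 * 0.55)
        assert centre == pytest.approx(-0.2006707, abs=1e-6)
        assert half == pytest.approx(0.3306282, abs=1e-6)
        assert ci.lower == pytest.approx(centre - half, abs=1e-12)
        assert ci.upper == pytest.approx(centre + half, abs=1e-12)

    def test_symmetric_at_half(self):
        ci = approx_interval_logodds(BinomialSample(100, 50), 0.90)
        assert ci.lower == pytest.approx(-ci.upper)

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            approx_interval_logodds(BinomialSample(10, 0), 0.90)

    def test_is_not_the_transformed_proportion_interval(self, sample_100_45):
        """Delta method linearizes at the MLE; it does not map the bounds."""
        direct = approx_interval_logodds(sample_100_45, 0.90)
        mapped = approx_interval_proportion(sample_100_45, 0.90)
        assert abs(direct.lower - special.logit(mapped.lower)) > 1e-3
        assert abs(direct.upper - special.logit(mapped.upper)) > 1e-3


def test_interval_invariants():
    with pytest.raises(ValueError):
        from ssdcalib import CredibleInterval
        CredibleInterval(0.6, 0.4, 0.9, Scale.PROPORTION, Method.HPD_EXACT)
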