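import pytest

from ssdcalib import BetaParams, BinomialSample, DesignConfig, DesignValue


@pytest.fixture
def lymphoma_posterior() -> BetaParams:
    """Posterior from the historical 21/39 responses under a uniform prior."""
    return BetaParams(22.0, 19.0)


@pytest.fixture
def informative_prior() -> BetaParams:
    """Mean-0.54 prior worth 20 pseudo-observations."""
    return BetaParams(10.8, 9.2)


@pytest.fixture
def uniform_prior() -> BetaParams:
    return BetaParams(1.0, 1.0)


def make_config(theta_d: float, prior: BetaParams, **kw) -> DesignConfig:
    defaults = dict(level=0.90, epsilon_p=0.01, epsilon_b=0.01,
                    epsilon_l=0.1, n_min=1, n_max=5000)
    defaults.update(kw)
    return DesignConfig(theta_d=DesignValue(theta_d), prior=prior, **defaults)


@pytest.fixture
def sample_100_45() -> BinomialSample:
    return BinomialSample(100, 45)
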