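import pytest

from brackish.mcmc import McmcConfig


@pytest.fixture
def fast_cfg():
    """Short chains for smoke-level fits where only mechanics matter."""
    return McmcConfig(n_chains=2, n_iter=800, n_burn=400, seed=11)


@pytest.fixture
def medium_cfg():
    """Chains long enough for stable posterior summaries in unit tests."""
    return McmcConfig(n_chains=3, n_iter=2000, n_burn=1000, seed=11)
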