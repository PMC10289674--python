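import numpy as np
import pytest

from spikeprecision import (GaussianPairSpec, MothLikeSpec, gaussian_pair,
                            moth_like, RunConfig, default_noise_grid)


@pytest.fixture(scope="session")
def gaussian_dataset():
    """N=2500 correlated-Gaussian single-spike dataset (rho=0.9)."""
    return gaussian_pair(GaussianPairSpec(n=2500, rho=0.9, seed=11))


@pytest.fixture(scope="session")
def moth_dataset():
    """Moderate moth-like multi-spike dataset for estimator tests."""
    return moth_like(MothLikeSpec(n=1200, timing_rho=0.8, seed=12))


@pytest.fixture
def light_config():
    """A small-noise-sweep config keeping unit tests fast."""
    return RunConfig(n_noise_reps=8,
                     noise_grid=default_noise_grid(12, 0.2, 16.0), seed=5)
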