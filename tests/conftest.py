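import numpy as np
import pytest

import spectralmap as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_symmetric():
    def _make(n, seed=0, scale=1.0):
        r = np.random.default_rng(seed)
        X = r.standard_normal((n, n)) * scale
        return (X + X.T) / 2.0

    return _make


@pytest.fixture
def planted_pair():
    """Noiseless planted pair (n=20, true order 2) with ground truth."""
    spec = sm.SyntheticSpec(n=20, true_k=2, seed=42)
    return sm.make_planted_pair(spec)


@pytest.fixture
def small_cohort():
    """Heterogeneous cohort of 6 subjects (n=20), noiseless."""
    spec = sm.SyntheticSpec(n=20, true_k=2, seed=7)
    cohort, truth = sm.make_cohort(spec, 6, heterogeneity=1.0)
    return cohort, truth


@pytest.fixture
def group_cohort():
    """Shared-basis planted cohort of 6 subjects (n=20), noiseless."""
    spec = sm.SyntheticSpec(n=20, true_k=2, seed=11)
    cohort, truth = sm.make_cohort(spec, 6, heterogeneity=0.0)
    return cohort, truth
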