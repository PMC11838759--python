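import numpy as np
import pytest

from skingwas.simulate import SimConfig, simulate_summary_stats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully populated study: 3 diseases, 12 loci each."""
    return SimConfig(n_diseases=3, loci_per_disease=12, variants_per_locus=8,
                     seed=42)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_summary_stats(small_cfg)
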