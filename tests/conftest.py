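import numpy as np
import pytest
from hypothesis import settings

from supergene.simulate import SimulationConfig, simulate_haplotypes

settings.register_profile("default", derandomize=True, max_examples=100,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg():
    """Small four-group scenario (both species' SB plus the Sb clade)."""
    return SimulationConfig(
        group_sizes={"outgroup": 1, "invicta_SB": 4, "richteri_SB": 4,
                     "Sb": 4},
        seq_length=50_000, n_blocks=10, chrom_length_bp=500_000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_haplotypes(small_cfg)


@pytest.fixture(scope="session")
def fig_tree_sim():
    """The two-haplotype-group dating scenario (7 SB vs 7 Sb plus outgroup)."""
    cfg = SimulationConfig(seq_length=200_000, n_blocks=1, seed=5)
    return cfg, simulate_haplotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
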