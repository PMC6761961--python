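import numpy as np
import pytest

from neoxy.simulate import SimConfig, Stratum, simulate_genome_pair, simulate_sample_reads

# Desk-scale configuration for unit tests: same structure as the default
# (two PAR segments flanking an old and a young stratum) at reduced length.
SMALL_CFG = SimConfig(
    seed=11,
    autosome_lengths=(120_000,),
    x_length=150_000,
    par_segments=((0, 20_000), (130_000, 150_000)),
    strata=(Stratum((20_000, 90_000), 62.0), Stratum((90_000, 130_000), 20.0)),
    n_genes=18,
)


@pytest.fixture(scope="session")
def small_sim():
    male, female, truth = simulate_genome_pair(SMALL_CFG)
    return {"cfg": SMALL_CFG, "male": male, "female": female, "truth": truth}


@pytest.fixture(scope="session")
def small_reads(small_sim):
    cfg = small_sim["cfg"]
    return {
        "male": simulate_sample_reads(small_sim["male"], cfg, "male", 101),
        "female": simulate_sample_reads(small_sim["female"], cfg, "female", 102),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
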