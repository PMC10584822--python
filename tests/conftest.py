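import numpy as np
import pytest

import zygometh as z


@pytest.fixture(scope="session")
def toy_config():
    return z.SimConfig(
        genome_length=40_000,
        n_chromosomes=2,
        snp_rate=0.02,
        n_planted_dmrs={"CG": 6, "CHG": 4, "CHH": 4},
        depth=8.0,
        n_replicates=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_cross(toy_config):
    """One small simulated cross shared by read-level tests."""
    genomes = z.simulate_parental_genomes(toy_config)
    truth = z.simulate_methylomes(genomes, toy_config)
    readsets = z.generate_bisulfite_reads(
        truth, toy_config, cell_types=["egg", "sperm", "zygote"], replicates=[0]
    )
    return {
        "config": toy_config,
        "genomes": genomes,
        "truth": truth,
        "reads": readsets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
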