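import numpy as np
import pytest

from tipprof.simulate import FamilyConfig, SimConfig, simulate_population

VINE1 = FamilyConfig("VINE1", "TGTTGGAATACGCAACCAGA")
GRET1 = FamilyConfig("Gret1", "ACGGTCTTAACCTGGTATGC")
TVV1 = FamilyConfig("Tvv1", "GATCCGTAGTTCACAGGCTA")


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_cultivars=3,
        genome_length=100_000,
        families=[VINE1],
        n_shared_sites=3,
        n_specific_sites_per_cultivar=1,
        depth=40,
        base_error_rate=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_panel():
    """A tiny noiseless single-family panel shared across tests."""
    cfg = small_config()
    genomes, truth = simulate_population(cfg)
    return cfg, genomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
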