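"""Shared study configuration for the numbered analysis scripts.

One synthetic panel stands in for the real 24-cultivar sequencing study at
desk scale: 6 cultivars, the three retrotransposon families, 30 insertion
sites per family, of which every cultivar privately owns 4 (VINE1),
2 (Gret1) and 1 (Tvv1) — the structure of the target-specific site counts
the screening is meant to recover. Depth 100 reads per site (Poisson),
0.5% substitution error.
"""

from pathlib import Path

from tipprof.simulate import FamilyConfig, SimConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results" / "pipeline"
TABLES = ROOT / "results" / "tables"

TARGET = "cultivar03"
SEED = 20240917

FAMILIES = [
    FamilyConfig("VINE1", "TGTTGGAATACGCAACCAGA"),
    FamilyConfig("Gret1", "ACGGTCTTAACCTGGTATGC"),
    FamilyConfig("Tvv1", "GATCCGTAGTTCACAGGCTA"),
]


def sim_config(seed: int = SEED) -> SimConfig:
    return SimConfig(
        n_cultivars=6,
        genome_length=250_000,
        families=FAMILIES,
        n_shared_sites={"VINE1": 6, "Gret1": 18, "Tvv1": 24},  # 30 sites per family
        n_specific_sites_per_cultivar={"VINE1": 4, "Gret1": 2, "Tvv1": 1},
        depth=100.0,
        base_error_rate=0.005,
        seed=seed,
    )
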