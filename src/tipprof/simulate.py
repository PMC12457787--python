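"""Synthetic cultivar genomes and junction-fragment sequencing libraries.

The simulator emulates a transposon-display style library: genomic DNA is
randomly fragmented, adaptors are ligated, and only fragments carrying a
retrotransposon terminus adjacent to flanking genomic DNA are amplified (one
primer sits on the retrotransposon end, the other on the ligated adaptor).
Amplicons are size-selected to 500-1,000 bp and sequenced as 150 bp
paired-end reads, so read 1 always starts at the family primer site, runs
through the element terminus and into the flanking genome — the flank
identifies the insertion site.

All cultivar genomes are derived from one random backbone; an insertion site
is realised in a cultivar by inserting the family's terminal sequence at the
site coordinate. Sites are therefore co-linear across cultivars and the
informative 50 bp flank of a site is identical in every cultivar that
carries it.

Randomness is organised as numpy ``SeedSequence`` streams with a fixed draw
order so that identical seeds give bit-identical output: the population
stream draws backbone -> family end sequences -> site coordinates ->
presence patterns; each (cultivar, family) library then uses an independent
stream seeded as ``[seed, 1, cultivar_index, family_index]`` drawing
per-site Poisson read counts, then fragment geometry, substitution errors
and qualities, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LIB_STREAM_TAG = 1  # namespaces library streams apart from the population stream


@dataclass(frozen=True)
class FamilyConfig:
    """One retrotransposon family targeted by the library design.

    ``end_seq`` is the element's terminal sequence carrying the
    family-specific primer site; read 1 of every junction fragment begins
    with it.
    """

    name: str
    end_seq: str

    def __post_init__(self) -> None:
        if len(self.end_seq) < 10:
            raise ValueError(f"family {self.name}: end_seq shorter than 10 bp")
        if set(self.end_seq) - set("ACGT"):
            raise ValueError(f"family {self.name}: end_seq must be over ACGT")


def _default_families() -> list[FamilyConfig]:
    # Fixed synthetic 20 bp termini for the three grape families.
    return [
        FamilyConfig("VINE1", "TGTTGGAATACGCAACCAGA"),
        FamilyConfig("Gret1", "ACGGTCTTAACCTGGTATGC"),
        FamilyConfig("Tvv1", "GATCCGTAGTTCACAGGCTA"),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for one simulated cultivar panel.

    Defaults mirror the real library design where it is stated (500-1,000 bp
    size selection, 150 bp paired-end reads, 24 cultivars, three families)
    and realistic stand-ins elsewhere (Poisson depth 100 per site, 0.5%
    substitution error, mean Q35 qualities).
    """

    n_cultivars: int = 24
    genome_length: int = 400_000
    families: list[FamilyConfig] = field(default_factory=_default_families)
    n_shared_sites: Mapping[str, int] | int = 10
    n_specific_sites_per_cultivar: Mapping[str, int] | int = 1
    fragment_mean: float = 700.0
    fragment_sd: float = 150.0
    size_select_min: int = 500
    size_select_max: int = 1000
    read_length: int = 150
    depth: float = 100.0
    base_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    min_flank_edit_distance: int = 10
    seed: int = 0

    def specific_sites(self, family: str) -> int:
        if isinstance(self.n_specific_sites_per_cultivar, Mapping):
            return int(self.n_specific_sites_per_cultivar[family])
        return int(self.n_specific_sites_per_cultivar)

    def shared_sites(self, family: str) -> int:
        if isinstance(self.n_shared_sites, Mapping):
            return int(self.n_shared_sites[family])
        return int(self.n_shared_sites)

    def cultivar_names(self) -> list[str]:
        return [f"cultivar{1 + i:02d}" for i in range(self.n_cultivars)]

    def validate(self) -> None:
        if self.n_cultivars < 2:
            raise ValueError("n_cultivars must be >= 2")
        if self.size_select_min >= self.size_select_max:
            raise ValueError("size_select_min must be < size_select_max")
        if self.read_length > self.size_select_min:
            raise ValueError("read_length must be <= size_select_min")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be a probability")
        if not self.families:
            raise ValueError("at least one family required")
        n_sites = sum(
            self.shared_sites(f.name) + self.n_cultivars * self.specific_sites(f.name) for f in self.families
        )
        # Sites are kept >= 2 x size_select_max apart so fragments from
        # neighbouring insertions can never be chimeric.
        spacing = 2 * self.size_select_max
        usable = self.genome_length - 2 * self.size_select_max
        if n_sites * spacing > usable:
            raise ValueError(
                f"{n_sites} sites with minimum spacing {spacing} bp do not fit in a "
                f"{self.genome_length} bp genome; enlarge genome_length or reduce site counts"
            )


@dataclass
class Site:
    family: str
    site_id: str
    coordinate: int  # backbone coordinate of the junction (0-based)
    flank_seq: str  # 50 bp of genomic flank immediately downstream of the insertion
    presence: dict[str, int]  # cultivar -> 0/1


@dataclass
class TruthSet:
    """Ground truth for one simulated panel: planted sites and genotypes."""

    sites: list[Site]
    cultivars: list[str]
    backbone: str
    families: list[FamilyConfig]
    genome_paths: dict[str, Path] = field(default_factory=dict)

    def matrix(self, family: str | None = None) -> pd.DataFrame:
        """0/1 presence matrix, sites x cultivars."""
        rows = [s for s in self.sites if family is None or s.family == family]
        return pd.DataFrame(
            [[s.presence[c] for c in self.cultivars] for s in rows],
            index=[s.site_id for s in rows],
            columns=self.cultivars,
            dtype=int,
        )

    def unique_sites(self, cultivar: str, family: str | None = None) -> list[Site]:
        out = []
        for s in self.sites:
            if family is not None and s.family != family:
                continue
            if s.presence[cultivar] == 1 and sum(s.presence.values()) == 1:
                out.append(s)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s in self.sites:
            row = {"family": s.family, "site_id": s.site_id, "coordinate": s.coordinate, "flank_seq": s.flank_seq}
            row.update({c: s.presence[c] for c in self.cultivars})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _min_pairwise_edit(flanks: Sequence[str]) -> int:
    best = min(len(f) for f in flanks) if flanks else 0
    for i in range(len(flanks)):
        for j in range(i + 1, len(flanks)):
            d = edlib.align(flanks[i], flanks[j])["editDistance"]
            best = min(best, d)
    return best


def _place_sites(rng: np.random.Generator, config: SimConfig, n_sites: int, backbone: str) -> list[int]:
    """Draw site coordinates with minimum spacing and a flank-distinctness floor.

    Coordinates are redrawn wholesale until every pair of 50 bp downstream
    flanks is at least ``min_flank_edit_distance`` edits apart, which
    guarantees reads from distinct sites cannot share a cluster.
    """
    spacing = 2 * config.size_select_max
    lo = config.size_select_max
    hi = config.genome_length - config.size_select_max - 50
    for _ in range(100):
        # Uniform positions with a spacing floor via the order-statistics trick:
        # draw gaps, then stretch.
        raw = np.sort(rng.uniform(0, 1, size=n_sites))
        span = hi - lo - (n_sites - 1) * spacing
        if span <= 0:
            raise ValueError("site placement infeasible")  # pre-validated; defensive
        coords = (lo + raw * span + np.arange(n_sites) * spacing).astype(int)
        flanks = [backbone[c : c + 50] for c in coords]
        if _min_pairwise_edit(flanks) >= config.min_flank_edit_distance:
            return [int(c) for c in coords]
    raise RuntimeError("could not place sites with distinct flanks; genome too short?")


def simulate_population(config: SimConfig, out_dir: str | Path | None = None) -> tuple[dict[str, str], TruthSet]:
    """Simulate the cultivar panel: genomes with planted insertions plus truth.

    Returns a mapping cultivar -> genome sequence and the :class:`TruthSet`.
    When ``out_dir`` is given, one FASTA per cultivar and a truth TSV are
    also written there (paths recorded on the TruthSet).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cultivars = config.cultivar_names()

    backbone = _random_dna(rng, config.genome_length)

    n_total = sum(
        config.shared_sites(f.name) + config.n_cultivars * config.specific_sites(f.name) for f in config.families
    )
    coords = _place_sites(rng, config, n_total, backbone)
    rng.shuffle(coords)  # decouple coordinate order from family blocks
    coord_iter = iter(coords)

    sites: list[Site] = []
    for fam in config.families:
        fam_sites: list[Site] = []
        for k in range(config.shared_sites(fam.name)):
            c = next(coord_iter)
            # shared sites live in a random subset of >= 2 cultivars
            n_carriers = int(rng.integers(2, config.n_cultivars + 1))
            carriers = rng.choice(config.n_cultivars, size=n_carriers, replace=False)
            presence = {cv: int(i in carriers) for i, cv in enumerate(cultivars)}
            fam_sites.append(Site(fam.name, f"{fam.name}_sh{k + 1:03d}", c, backbone[c : c + 50], presence))
        for i, cv in enumerate(cultivars):
            for k in range(config.specific_sites(fam.name)):
                c = next(coord_iter)
                presence = {other: int(other == cv) for other in cultivars}
                fam_sites.append(
                    Site(fam.name, f"{fam.name}_{cv}_u{k + 1:02d}", c, backbone[c : c + 50], presence)
                )
        sites.extend(fam_sites)
    sites.sort(key=lambda s: s.coordinate)

    genomes: dict[str, str] = {}
    for cv in cultivars:
        parts = []
        prev = 0
        for s in sites:
            if s.presence[cv]:
                fam = next(f for f in config.families if f.name == s.family)
                parts.append(backbone[prev : s.coordinate])
                parts.append(fam.end_seq)
                prev = s.coordinate
        parts.append(backbone[prev:])
        genomes[cv] = "".join(parts)

    truth = TruthSet(sites=sites, cultivars=cultivars, backbone=backbone, families=list(config.families))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cv, seq in genomes.items():
            p = out / f"{cv}.fasta"
            SeqIO.write([SeqRecord(Seq(seq), id=cv, description="")], str(p), "fasta")
            truth.genome_paths[cv] = p
        truth.to_tsv(out / "truth.tsv")
    return genomes, truth


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray


def library_rng(config: SimConfig, cultivar_index: int, family_index: int) -> np.random.Generator:
    """The per-library random stream; part of the reproducibility contract."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _LIB_STREAM_TAG, cultivar_index, family_index])
    )


def _find_junctions(genome: str, end_seq: str) -> list[int]:
    """Positions immediately after each occurrence of the family terminus."""
    out, start = [], 0
    while True:
        i = genome.find(end_seq, start)
        if i < 0:
            return out
        out.append(i + len(end_seq))
        start = i + 1


def _apply_errors(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        seq = seq.copy()
        # substitute with one of the three other bases
        idx = np.searchsorted(BASES, seq[hits])
        shift = rng.integers(1, 4, size=hits.size)
        seq[hits] = BASES[(idx + shift) % 4]
    return seq


def simulate_library(
    genome: str,
    family: FamilyConfig,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Simulate the junction-fragment library for one (cultivar, family).

    Every occurrence of the family terminus in ``genome`` is a junction.
    For each junction, ``Poisson(depth)`` amplicons are drawn; an amplicon's
    length is the distance from the family primer (at the element terminus,
    ``len(end_seq)`` bases upstream of the junction) to a random downstream
    shear point, induced by normal fragment lengths with the junction
    uniform inside the fragment, then size-selected to
    ``[size_select_min, size_select_max]``. Read 1 is the amplicon prefix
    (terminus + flank), read 2 the reverse complement of its suffix.

    Draw order per library: per-site Poisson counts, then for each site in
    genome order its fragment geometry, then errors, then qualities.
    A genome with no insertion of the family yields an empty list.
    """
    junctions = _find_junctions(genome, family.end_seq)
    if not junctions:
        return []
    counts = rng.poisson(config.depth, size=len(junctions))
    prefix = np.frombuffer(family.end_seq.encode(), dtype=np.uint8)
    pairs: list[ReadPair] = []
    for j, (pos, n) in enumerate(zip(junctions, counts)):
        if n == 0:
            continue
        lengths = _draw_amplicon_lengths(rng, config, len(family.end_seq), int(n))
        flank_arr = np.frombuffer(
            genome[pos : pos + config.size_select_max].encode(), dtype=np.uint8
        )
        for k, amp_len in enumerate(lengths):
            flank_len = amp_len - len(family.end_seq)
            amplicon = np.concatenate([prefix, flank_arr[:flank_len]])
            r1 = _apply_errors(rng, amplicon[: config.read_length], config.base_error_rate)
            r2 = _revcomp_arr(
                _apply_errors(rng, amplicon[-config.read_length :], config.base_error_rate)
            )
            q1 = _draw_quals(rng, config, config.read_length)
            q2 = _draw_quals(rng, config, config.read_length)
            pairs.append(
                ReadPair(f"{family.name}_j{j + 1:03d}_{k + 1:04d}", r1.tobytes().decode(), q1, r2.tobytes().decode(), q2)
            )
    return pairs


def _draw_amplicon_lengths(
    rng: np.random.Generator, config: SimConfig, prefix_len: int, n: int
) -> np.ndarray:
    """Size-selected amplicon lengths by rejection from the fragment model."""
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        frag = rng.normal(config.fragment_mean, config.fragment_sd, size=m)
        frag = np.clip(frag, 1, None)
        # junction uniform within the fragment; amplicon spans primer->shear
        down = rng.uniform(0, 1, size=m) * frag
        amp = (prefix_len + down).astype(int)
        ok = amp[(amp >= config.size_select_min) & (amp <= config.size_select_max)]
        out.append(ok)
        got += ok.size
    return np.concatenate(out)[:n]


def _draw_quals(rng: np.random.Generator, config: SimConfig, n: int) -> np.ndarray:
    q = np.rint(rng.normal(config.quality_mean, config.quality_sd, size=n))
    return np.clip(q, 2, 41).astype(int)


_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


def _revcomp_arr(seq: np.ndarray) -> np.ndarray:
    return _COMP[seq][::-1]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_fastq_pairs(pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write read pairs as Sanger Phred+33 FASTQ (R1/R2 files)."""
    for path, which in ((r1_path, 1), (r2_path, 2)):
        with open(path, "w") as fh:
            for p in pairs:
                seq = p.seq1 if which == 1 else p.seq2
                qual = p.qual1 if which == 1 else p.qual2
                qstr = "".join(chr(33 + int(q)) for q in qual)
                fh.write(f"@{p.read_id}/{which}\n{seq}\n+\n{qstr}\n")


def simulate_panel_libraries(
    genomes: Mapping[str, str], config: SimConfig
) -> dict[tuple[str, str], list[ReadPair]]:
    """All (cultivar, family) libraries for a panel, with contract seeding."""
    out: dict[tuple[str, str], list[ReadPair]] = {}
    for ci, cv in enumerate(config.cultivar_names()):
        for fi, fam in enumerate(config.families):
            out[(cv, fam.name)] = simulate_library(genomes[cv], fam, config, library_rng(config, ci, fi))
    return out
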