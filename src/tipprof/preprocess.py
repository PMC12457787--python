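"""Read-cleaning cascade for junction libraries.

Four stages, applied in order, each reported with its surviving read count
and the percentage of raw reads it retains:

1. adaptor removal (3' suffix vs adaptor prefix, minimum overlap 5,
   at most 10% mismatches) together with removal of the configured
   retrotransposon-end prefix, then a mean-Phred >= 30 filter;
2. truncation of every read to its first 50 bases (shorter reads dropped);
3. a second mean-Phred >= 30 filter re-evaluated on the 50-mer;
4. "outlier filtering": groups of >= 10 identical sequences are collapsed
   to a single representative, smaller groups pass through untouched.

Only read 1 (the junction read) enters the cascade; read 2 exists solely to
confirm the library structure. Stage 4 is the only stage that does not
preserve input order (its output is sorted lexicographically by sequence so
results are byte-reproducible).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STAGE_RAW = "Raw data"
STAGE_ADAPTOR = "Adaptor removal and QV (>=30) filtering"
STAGE_LENGTH = "Trimming to specific length (50 bp)"
STAGE_QV = "QV (>=30) filtering"
STAGE_OUTLIER = "Outlier filtering"


@dataclass
class Read:
    id: str
    seq: str
    qual: np.ndarray  # Phred integers, len == len(seq)

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=int)
        if len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id}: qual length != seq length")

    def mean_qv(self) -> float:
        return float(self.qual.mean()) if len(self.qual) else 0.0


@dataclass
class PreprocessParams:
    adaptor_seq: str = "AGATCGGAAGAGCACACGTC"
    retro_prefix: str | None = None  # family terminus to strip from the 5' end
    min_qv: float = 30.0
    target_len: int = 50
    min_copies: int = 10
    min_overlap: int = 5
    max_mismatch_frac: float = 0.10
    # the element terminus is the amplification primer itself, so it is present
    # by construction; a generous tolerance avoids phantom junction 50-mers from
    # reads whose prefix merely carries base-call errors
    prefix_max_mismatch_frac: float = 0.20


def ratio_percent(n: int, raw: int) -> float:
    """Percentage of raw reads, rounded half-up to 2 decimals (0.00 if raw=0)."""
    if raw == 0:
        return 0.0
    return float((Decimal(n) * 100 / Decimal(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PreprocessReport:
    """Per-stage survivor counts in the summary-table layout."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, n: int) -> None:
        if self.stages and n > self.stages[-1][1]:
            raise ValueError("stage counts must be non-increasing")
        self.stages.append((name, n))

    @property
    def raw(self) -> int:
        return self.stages[0][1] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(name, n, ratio_percent(n, self.raw)) for name, n in self.stages],
            columns=["stage", "n_reads", "ratio_percent"],
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["ratio_percent"] = df["ratio_percent"].map(lambda x: f"{x:.2f}")
        df.to_csv(path, sep="\t", index=False)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_adaptor(seq: str, adaptor: str, min_overlap: int, max_mm_frac: float) -> int | None:
    """Leftmost position where a prefix of the adaptor matches the read 3' end."""
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        ov = min(len(adaptor), n - p)
        if ov < min_overlap:
            break
        if _mismatches(seq[p : p + ov], adaptor[:ov]) <= int(max_mm_frac * ov):
            return p
    return None


def trim_adaptor_and_qv(reads: Iterable[Read], params: PreprocessParams) -> list[Read]:
    """Stage 1: strip the element-terminus prefix and 3' adaptor, filter on mean QV.

    The retro-end prefix (when configured) is removed if it matches the read
    start within 10% mismatches, so the genomic flank begins at base 1. A
    read survives iff its mean Phred after trimming is >= ``min_qv``.
    """
    out: list[Read] = []
    lp = len(params.retro_prefix) if params.retro_prefix else 0
    for r in reads:
        seq, qual = r.seq, r.qual
        if lp and len(seq) > lp and _mismatches(seq[:lp], params.retro_prefix) <= int(
            params.prefix_max_mismatch_frac * lp
        ):
            seq, qual = seq[lp:], qual[lp:]
        p = _find_adaptor(seq, params.adaptor_seq, params.min_overlap, params.max_mismatch_frac)
        if p is not None:
            seq, qual = seq[:p], qual[:p]
        if len(seq) and qual.mean() >= params.min_qv:
            out.append(Read(r.id, seq, qual))
    return out


def trim_to_length(reads: Iterable[Read], target_len: int = 50) -> list[Read]:
    """Stage 2: truncate reads to their first ``target_len`` bases; drop shorter ones."""
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    return [
        Read(r.id, r.seq[:target_len], r.qual[:target_len]) for r in reads if len(r.seq) >= target_len
    ]


def filter_mean_qv(reads: Iterable[Read], min_qv: float = 30.0) -> list[Read]:
    """Stage 3: keep reads whose mean Phred is >= ``min_qv``."""
    return [r for r in reads if r.mean_qv() >= min_qv]


def collapse_high_copy(reads: Sequence[Read], min_copies: int = 10) -> list[Read]:
    """Stage 4: collapse groups of >= ``min_copies`` identical sequences to one read.

    Groups below the threshold pass through with every member. Output is
    ordered lexicographically by sequence (ties by original order within a
    group), making the result independent of input order up to read ids.
    """
    by_seq: dict[str, list[Read]] = {}
    for r in reads:
        by_seq.setdefault(r.seq, []).append(r)
    out: list[Read] = []
    for seq in sorted(by_seq):
        group = by_seq[seq]
        if len(group) >= min_copies:
            out.append(group[0])
        else:
            out.extend(group)
    return out


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Parse Sanger Phred+33 FASTQ; malformed records abort with the line number."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ header at line {lineno}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"{path}: truncated FASTQ record at line {lineno}")
            lineno += 3
            if not plus.startswith("+") or len(seq) != len(qual):
                raise ValueError(f"{path}: malformed FASTQ record at line {lineno}")
            yield Read(header[1:].split()[0], seq, np.frombuffer(qual.encode(), dtype=np.uint8) - 33)


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f">{r.id}\n{r.seq}\n")


def run_preprocess(
    reads: Iterable[Read] | str | Path,
    params: PreprocessParams,
    fasta_out: str | Path | None = None,
) -> tuple[list[Read], "PreprocessReport", Counter]:
    """Run the four-stage cascade; returns survivors, the stage report and the
    pre-collapse sequence multiplicities (needed downstream to re-attach raw
    read counts to clusters).
    """
    if isinstance(reads, (str, Path)):
        reads = list(read_fastq(reads))
    else:
        reads = list(reads)
    report = PreprocessReport()
    report.add(STAGE_RAW, len(reads))
    s1 = trim_adaptor_and_qv(reads, params)
    report.add(STAGE_ADAPTOR, len(s1))
    s2 = trim_to_length(s1, params.target_len)
    report.add(STAGE_LENGTH, len(s2))
    s3 = filter_mean_qv(s2, params.min_qv)
    report.add(STAGE_QV, len(s3))
    pre_collapse = Counter(r.seq for r in s3)
    s4 = collapse_high_copy(s3, params.min_copies)
    report.add(STAGE_OUTLIER, len(s4))
    if fasta_out is not None:
        write_fasta(s4, fasta_out)
    return s4, report, pre_collapse
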