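"""Presence/absence genotyping and cultivar-specific site screening.

An insertion is called absent in a cultivar when the reads of its cluster
make up less than 0.1% of all of that cultivar's reads for the family; at
exactly 0.1% the call is presence (the rule declares absence strictly below
the threshold). The denominator defaults to the cultivar's read count after
the quality stages of preprocessing — the reads whose multiplicities are
re-attached to clusters — and can be switched to the raw count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tipprof.cluster import Cluster

DEFAULT_THRESHOLD = 0.001  # fraction of a cultivar's reads; 0.1%


@dataclass
class GenotypeMatrix:
    """Clusters x cultivars: raw read counts plus binary presence calls."""

    family: str
    counts: pd.DataFrame  # sites x cultivars, non-negative ints
    totals: pd.Series  # cultivar -> total reads (denominator)
    calls: pd.DataFrame  # sites x cultivars, 0/1
    threshold: float = DEFAULT_THRESHOLD
    representatives: dict[str, str] = field(default_factory=dict)  # site_id -> flank 50-mer

    @property
    def sites(self) -> list[str]:
        return list(self.calls.index)

    @property
    def cultivars(self) -> list[str]:
        return list(self.calls.columns)

    def drop_empty_sites(self) -> "GenotypeMatrix":
        """Remove sites called absent everywhere (done before screening)."""
        keep = self.calls.sum(axis=1) > 0
        return GenotypeMatrix(
            self.family,
            self.counts.loc[keep],
            self.totals,
            self.calls.loc[keep],
            self.threshold,
            {s: r for s, r in self.representatives.items() if keep.get(s, False)},
        )

    def to_tsv(self, counts_path: str | Path, calls_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="site_id")
        self.calls.to_csv(calls_path, sep="\t", index_label="site_id")


@dataclass(frozen=True)
class MarkerCandidate:
    site_id: str
    target_cultivar: str
    family: str
    flank_seq: str
    specificity: str = "unique"


def call_genotypes(
    counts: pd.DataFrame, totals: pd.Series | Mapping[str, int], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Binary calls: 1 iff counts[s,c] / totals[c] >= threshold.

    The comparison is done on the read-share ratio so the boundary behaves
    exactly as stated: 999/1,000,000 (0.0999%) is absent, 1,000/1,000,000
    (0.1000%) is present.
    """
    totals = pd.Series(totals).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"no totals for cultivars: {missing}")
    zero = totals[totals <= 0].index
    for cv in zero:
        if counts[cv].sum() > 0:
            raise ValueError(f"cultivar {cv!r} has reads in clusters but a total of 0")
    share = counts.div(totals.replace(0, np.nan), axis=1)
    calls = (share >= threshold).fillna(False).astype(int)
    return calls


def build_genotype_matrix(
    family: str,
    clusters: Sequence[Cluster],
    totals: Mapping[str, int],
    threshold: float = DEFAULT_THRESHOLD,
) -> GenotypeMatrix:
    """Assemble the genotype matrix for one family from its clusters."""
    cultivars = list(totals)
    counts = pd.DataFrame(
        [[cl.per_cultivar_counts.get(cv, 0) for cv in cultivars] for cl in clusters],
        index=[cl.cluster_id for cl in clusters],
        columns=cultivars,
        dtype=int,
    )
    calls = call_genotypes(counts, pd.Series(totals), threshold)
    reps = {cl.cluster_id: cl.representative for cl in clusters}
    return GenotypeMatrix(family, counts, pd.Series(totals), calls, threshold, reps)


def screen_specific(matrix: GenotypeMatrix, target: str) -> list[MarkerCandidate]:
    """Sites present in the target cultivar and absent everywhere else."""
    if target not in matrix.cultivars:
        raise ValueError(f"unknown cultivar {target!r}; valid: {matrix.cultivars}")
    calls = matrix.drop_empty_sites().calls
    mask = (calls[target] == 1) & (calls.sum(axis=1) == 1)
    return [
        MarkerCandidate(site, target, matrix.family, matrix.representatives.get(site, ""))
        for site in sorted(calls.index[mask])
    ]


def specificity_summary(matrices: Sequence[GenotypeMatrix]) -> pd.DataFrame:
    """Cultivar x family table of unique-site counts, with per-family totals."""
    families = [m.family for m in matrices]
    cultivars: list[str] = []
    for m in matrices:
        for cv in m.cultivars:
            if cv not in cultivars:
                cultivars.append(cv)
    data = pd.DataFrame(0, index=cultivars, columns=families, dtype=int)
    for m in matrices:
        calls = m.drop_empty_sites().calls
        unique = calls[calls.sum(axis=1) == 1]
        for cv in m.cultivars:
            data.loc[cv, m.family] = int((unique[cv] == 1).sum())
    data.loc["Total"] = data.sum()
    return data
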