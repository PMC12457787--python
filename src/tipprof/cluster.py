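"""Tiled seed-and-extend self-alignment clustering of junction 50-mers.

Each preprocessed junction read is a fixed-length sequence anchored at the
element/genome boundary, so two reads from the same insertion site are
near-identical up to sequencing error and small terminus slippage. The
clustering therefore needs no gaps: two sequences are *linked* when

1. they share at least ``min_match`` seed tiles — non-overlapping
   ``tile_size``-mers (positions 0, t, 2t, ...) that match within
   ``one_off`` mismatches at tile offsets differing by at most
   ``max_shift``; and
2. the best ungapped offset alignment (shifts within ``±max_shift``)
   scores at least ``min_score``, with score = matches − mismatches over
   the overlap.

Clusters are the connected components of the link graph (single linkage),
each interpreted as one insertion site. Defaults mirror the published
parameterisation of the tiled aligner this emulates: tile size 8, one
shared tile suffices, minimum score 10, up to 2 mismatches inside a seed
tile, and no tile-abundance masking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_DNA = "ACGT"


@dataclass
class ClusterParams:
    tile_size: int = 8
    min_match: int = 1  # shared seed tiles required
    min_score: int = 10
    one_off: int = 2  # mismatches tolerated inside a seed tile
    max_shift: int = 10  # alignment offset bound, also bounds seed offset skew
    rep_match_masking: bool = False  # tile-abundance masking disabled

    def validate(self) -> None:
        if self.tile_size < 4:
            raise ValueError("tile_size must be >= 4")
        if self.min_score < self.tile_size:
            raise ValueError("min_score must be >= tile_size")


@dataclass
class Cluster:
    """One putative insertion site: a connected set of near-identical 50-mers."""

    cluster_id: str
    representative: str
    members: dict[str, int]  # sequence -> total multiplicity (pre-collapse)
    per_cultivar_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(self.members.values())


def tiles_of(seq: str, tile_size: int) -> list[tuple[int, str]]:
    """Non-overlapping tiles (offset, tile); tiles containing N are skipped."""
    out = []
    for off in range(0, len(seq) - tile_size + 1, tile_size):
        t = seq[off : off + tile_size]
        if "N" not in t:
            out.append((off, t))
    return out


def build_tile_index(seqs: Sequence[str], tile_size: int) -> dict[str, list[tuple[int, int]]]:
    """Index every non-overlapping tile of every sequence: tile -> [(seq_idx, offset)]."""
    index: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        for off, t in tiles_of(s, tile_size):
            index.setdefault(t, []).append((i, off))
    return index


def tile_neighbourhood(tile: str, one_off: int) -> Iterable[str]:
    """All sequences within ``one_off`` substitutions of ``tile`` (incl. itself)."""
    yield tile
    n = len(tile)
    for k in range(1, one_off + 1):
        for pos in itertools.combinations(range(n), k):
            for subs in itertools.product(_DNA, repeat=k):
                if any(tile[p] == b for p, b in zip(pos, subs)):
                    continue
                lst = list(tile)
                for p, b in zip(pos, subs):
                    lst[p] = b
                yield "".join(lst)


def seed_hits(a: str, b: str, params: ClusterParams) -> int:
    """Number of seed-tile pairs shared by ``a`` and ``b``.

    A pair of non-overlapping tiles (offset i in ``a``, offset j in ``b``)
    counts when |i − j| <= max_shift and the tiles differ at <= one_off
    positions.
    """
    hits = 0
    tb = tiles_of(b, params.tile_size)
    for i, ta in tiles_of(a, params.tile_size):
        for j, t in tb:
            if abs(i - j) <= params.max_shift and _hamming(ta, t) <= params.one_off:
                hits += 1
    return hits


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def pair_score(a: str, b: str, params: ClusterParams | None = None) -> int:
    """Best ungapped match−mismatch score over offsets within ±max_shift.

    Sequences must be the same length; N never matches. Non-overlapping
    ends contribute nothing.
    """
    if len(a) != len(b):
        raise ValueError("pair_score requires equal-length sequences")
    params = params or ClusterParams()
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    n_pos = ord("N")
    best = -len(a)
    for s in range(-params.max_shift, params.max_shift + 1):
        if s >= 0:
            ov_a, ov_b = xa[s:], xb[: len(b) - s]
        else:
            ov_a, ov_b = xa[: len(a) + s], xb[-s:]
        eq = (ov_a == ov_b) & (ov_a != n_pos)
        m = int(eq.sum())
        best = max(best, 2 * m - ov_a.size)
    return best


def is_linked(a: str, b: str, params: ClusterParams | None = None) -> bool:
    """Link rule: enough shared seed tiles AND alignment score >= min_score."""
    params = params or ClusterParams()
    return seed_hits(a, b, params) >= params.min_match and pair_score(a, b, params) >= params.min_score


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_seqs(
    seq_counts: Mapping[str, Mapping[str, int]] | Iterable[str],
    params: ClusterParams | None = None,
    id_prefix: str = "Cl",
) -> list[Cluster]:
    """Cluster unique sequences into insertion sites.

    ``seq_counts`` maps each unique sequence to its per-cultivar
    pre-collapse read counts (a plain iterable of sequences is accepted for
    count-free use; duplicates then accumulate multiplicity under the
    pseudo-cultivar ``"reads"``).

    Candidate pairs come from a tile index queried through the one_off
    substitution neighbourhood of each tile; each candidate is verified
    with the full link rule and merged by union-find (single linkage). The
    partition is independent of input order: sequences are processed in
    lexicographic order and the representative is the highest-multiplicity
    member (ties broken by lexicographically smallest sequence).
    """
    params = params or ClusterParams()
    params.validate()
    if not isinstance(seq_counts, Mapping):
        counts: dict[str, dict[str, int]] = {}
        for s in seq_counts:
            counts.setdefault(s, {"reads": 0})["reads"] += 1
        seq_counts = counts
    seqs = sorted(seq_counts)
    if not seqs:
        return []
    index = build_tile_index(seqs, params.tile_size)
    uf = _UnionFind(len(seqs))
    seen_pairs: set[tuple[int, int]] = set()
    for i, s in enumerate(seqs):
        for off_i, tile in tiles_of(s, params.tile_size):
            for nb in tile_neighbourhood(tile, params.one_off):
                for j, off_j in index.get(nb, ()):
                    if j == i or abs(off_i - off_j) > params.max_shift:
                        continue
                    key = (min(i, j), max(i, j))
                    if key in seen_pairs or uf.find(i) == uf.find(j):
                        continue
                    seen_pairs.add(key)
                    if is_linked(seqs[key[0]], seqs[key[1]], params):
                        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters: list[Cluster] = []
    # stable ordering: by smallest member sequence
    for root in sorted(groups, key=lambda r: seqs[min(groups[r])]):
        members = {seqs[i]: sum(seq_counts[seqs[i]].values()) for i in groups[root]}
        rep = min(members, key=lambda s: (-members[s], s))
        per_cv: dict[str, int] = {}
        for i in groups[root]:
            for cv, c in seq_counts[seqs[i]].items():
                per_cv[cv] = per_cv.get(cv, 0) + int(c)
        clusters.append(Cluster("", rep, members, per_cv))
    for k, cl in enumerate(clusters):
        cl.cluster_id = f"{id_prefix}{k + 1:03d}"
    return clusters


def clusters_to_frame(clusters: Sequence[Cluster], cultivars: Sequence[str]) -> pd.DataFrame:
    """Cluster table: id, representative, member count, per-cultivar read counts."""
    rows = []
    for cl in clusters:
        row = {
            "cluster_id": cl.cluster_id,
            "representative": cl.representative,
            "n_members": len(cl.members),
        }
        row.update({cv: cl.per_cultivar_counts.get(cv, 0) for cv in cultivars})
        rows.append(row)
    return pd.DataFrame(rows)
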