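"""Clustering: seed index, pair scoring, and oracle equivalence of the partition.

The independent oracle scores every pair of sequences with vectorised numpy
(all offsets, all tile pairs) and takes connected components with
scipy.sparse.csgraph — a completely separate route from the tile-index +
union-find implementation.
"""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from tipprof.cluster import (
    ClusterParams,
    build_tile_index,
    cluster_seqs,
    is_linked,
    pair_score,
    seed_hits,
    tile_neighbourhood,
    tiles_of,
)

from conftest import random_dna


def brute_force_partition(seqs, params: ClusterParams):
    """All-pairs single-linkage with the identical link rule, via numpy + scipy."""
    n = len(seqs)
    if n == 0:
        return []
    L = len(seqs[0])
    X = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    n_code = ord("N")
    best = np.full((n, n), -L, dtype=int)
    for s in range(-params.max_shift, params.max_shift + 1):
        if s >= 0:
            a, b = X[:, s:], X[:, : L - s]
        else:
            a, b = X[:, : L + s], X[:, -s:]
        eq = (a[:, None, :] == b[None, :, :]) & (a[:, None, :] != n_code)
        score = 2 * eq.sum(axis=2) - a.shape[1]
        np.maximum(best, score, out=best)
    t = params.tile_size
    offsets = range(0, L - t + 1, t)
    seed_ok = np.zeros((n, n), dtype=int)
    for oi in offsets:
        for oj in offsets:
            if abs(oi - oj) > params.max_shift:
                continue
            ta, tb = X[:, oi : oi + t], X[:, oj : oj + t]
            has_n = (ta[:, None, :] == n_code) | (tb[None, :, :] == n_code)
            mm = ((ta[:, None, :] != tb[None, :, :]) | has_n).sum(axis=2)
            n_in_a = (ta == n_code).any(axis=1)
            n_in_b = (tb == n_code).any(axis=1)
            valid = ~(n_in_a[:, None] | n_in_b[None, :])
            seed_ok += ((mm <= params.one_off) & valid).astype(int)
    linked = (seed_ok >= params.min_match) & (best >= params.min_score)
    np.fill_diagonal(linked, False)
    graph = coo_matrix(linked.astype(int))
    _, labels = connected_components(graph, directed=False)
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(seqs[i])
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: min(g))


def test_tile_index_positions_and_counts():
    seq = random_dna(np.random.default_rng(0), 50)
    idx = build_tile_index([seq], 8)
    entries = [(off, t) for t, lst in idx.items() for (_, off) in lst]
    assert sorted(off for off, _ in entries) == [0, 8, 16, 24, 32, 40]
    idx2 = build_tile_index([seq, seq], 8)
    for t, lst in idx2.items():
        assert {i for i, _ in lst} == {0, 1}


def test_tile_index_matches_direct_enumeration():
    rng = np.random.default_rng(5)
    seqs = [random_dna(rng, 50) for _ in range(20)]
    idx = build_tile_index(seqs, 8)
    for i, s in enumerate(seqs):
        for off, t in tiles_of(s, 8):
            assert (i, off) in idx[t]


def test_tiles_with_n_skipped():
    seq = "N" * 8 + "A" * 42
    assert [off for off, _ in tiles_of(seq, 8)] == [8, 16, 24, 32, 40]


def test_neighbourhood_size_and_radius():
    tile = "ACGTACGT"
    nb = set(tile_neighbourhood(tile, 2))
    assert len(nb) == 1 + 8 * 3 + 28 * 9
    assert all(sum(a != b for a, b in zip(tile, x)) <= 2 for x in nb)


def test_pair_score_identity_and_substitutions():
    rng = np.random.default_rng(7)
    a = random_dna(rng, 50)
    assert pair_score(a, a) == 50
    b = list(a)
    b[3] = "ACGT"[("ACGT".index(b[3]) + 1) % 4]
    b[20] = "ACGT"[("ACGT".index(b[20]) + 1) % 4]
    b = "".join(b)
    assert pair_score(a, b) == 46
    assert is_linked(a, b)


def test_random_pair_not_linked():
    rng = np.random.default_rng(42)
    a = random_dna(rng, 50)
    b = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(a))
    params = ClusterParams()
    assert not is_linked(a, b, params)
    # confirmed by enumeration: no qualifying seed-tile pair at this seed
    assert seed_hits(a, b, params) == 0 or pair_score(a, b, params) < params.min_score


def test_offset_alignment_within_shift_bound():
    rng = np.random.default_rng(8)
    core = random_dna(rng, 45)
    a = ("AAAAA" + core)[:50]
    b = (core + "TTTTT")[:50]  # same core shifted by 5
    assert pair_score(a, b) >= 45 - 5 - 5  # overlap 45, all matching


def test_three_identical_seqs_one_cluster_counts_by_cultivar():
    seq = random_dna(np.random.default_rng(9), 50)
    clusters = cluster_seqs({seq: {"cvA": 2, "cvB": 1}})
    assert len(clusters) == 1
    assert clusters[0].per_cultivar_counts == {"cvA": 2, "cvB": 1}
    assert clusters[0].representative == seq


def test_half_divergent_pair_splits():
    rng = np.random.default_rng(10)
    a = random_dna(rng, 50)
    b = list(a)
    for i in range(0, 50, 2):
        b[i] = "ACGT"[("ACGT".index(b[i]) + 2) % 4]
    b = "".join(b)
    params = ClusterParams()
    assert seed_hits(a, b, params) == 0  # every tile has 4 mismatches
    assert len(cluster_seqs([a, b])) == 2


def test_empty_input():
    assert cluster_seqs([]) == []


def test_partition_conserves_read_counts():
    rng = np.random.default_rng(11)
    flanks = [random_dna(rng, 50) for _ in range(5)]
    counts = {}
    for f in flanks:
        counts[f] = {"cv1": int(rng.integers(1, 30))}
        mut = list(f)
        mut[int(rng.integers(50))] = "A" if mut[0] != "A" else "C"
        counts["".join(mut)] = {"cv1": 1}
    clusters = cluster_seqs(counts)
    assert sum(c.n_reads for c in clusters) == sum(sum(v.values()) for v in counts.values())
    member_union = sorted(s for c in clusters for s in c.members)
    assert member_union == sorted(counts)


def test_permutation_invariance():
    rng = np.random.default_rng(12)
    seqs = []
    for _ in range(6):
        f = random_dna(rng, 50)
        seqs.append(f)
        for _ in range(3):
            mut = list(f)
            mut[int(rng.integers(50))] = "ACGT"[int(rng.integers(4))]
            seqs.append("".join(mut))
    ref = cluster_seqs(sorted(seqs))
    per = cluster_seqs(list(reversed(sorted(seqs))))
    assert [sorted(c.members) for c in ref] == [sorted(c.members) for c in per]
    assert [c.representative for c in ref] == [c.representative for c in per]


@pytest.mark.parametrize("instance_seed", range(20))
def test_partition_equals_brute_force_oracle(instance_seed):
    """Up to 200 reads around planted flanks: implementation == all-pairs oracle."""
    rng = np.random.default_rng(1000 + instance_seed)
    n_flanks = int(rng.integers(5, 11))
    flanks = [random_dna(rng, 50) for _ in range(n_flanks)]
    seqs = set(flanks)
    while len(seqs) < int(rng.integers(50, 201)):
        f = flanks[int(rng.integers(n_flanks))]
        mut = list(f)
        for _ in range(int(rng.integers(1, 4))):
            mut[int(rng.integers(50))] = "ACGT"[int(rng.integers(4))]
        seqs.add("".join(mut))
    seqs = sorted(seqs)
    params = ClusterParams()
    ours = sorted((frozenset(c.members) for c in cluster_seqs(seqs, params)), key=lambda g: min(g))
    oracle = brute_force_partition(seqs, params)
    assert ours == oracle


def test_noiseless_panel_gives_one_cluster_per_site(small_panel):
    from tipprof.simulate import simulate_panel_libraries

    cfg, genomes, truth = small_panel
    libs = simulate_panel_libraries(genomes, cfg)
    seqs = set()
    prefix_len = len(cfg.families[0].end_seq)
    for pairs in libs.values():
        for p in pairs:
            seqs.add(p.seq1[prefix_len : prefix_len + 50])
    clusters = cluster_seqs(sorted(seqs))
    assert len(clusters) == len(truth.sites)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ClusterParams(tile_size=2).validate()
    with pytest.raises(ValueError):
        ClusterParams(min_score=4).validate()
    with pytest.raises(ValueError):
        pair_score("ACGT", "ACGTA")
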