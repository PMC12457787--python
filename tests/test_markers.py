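"""In-silico PCR and LAMP primer-set structural validation."""

import pytest

from tipprof.markers import (
    LampPrimerSet,
    PrimerPair,
    check_duplex_labels,
    design_junction_pair,
    evaluate_marker_panel,
    revcomp,
    validate_lamp_set,
    virtual_pcr,
)

from conftest import random_dna


@pytest.fixture()
def planted_genome(rng):
    """Random genome with one planted junction: element terminus + flank."""
    end_seq = "TGTTGGAATACGCAACCAGA"
    flank = random_dna(rng, 120)
    genome = random_dna(rng, 3000) + end_seq + flank + random_dna(rng, 3000)
    return genome, end_seq, flank


def test_constructed_positive_single_amplicon(planted_genome):
    genome, end_seq, flank = planted_genome
    pair = design_junction_pair(end_seq, flank)
    amps = virtual_pcr(genome, pair)
    assert len(amps) == 1
    assert amps[0].seq.startswith(end_seq)
    assert amps[0].length == len(end_seq) + 45


def test_constructed_negative_no_amplicon(planted_genome, rng):
    _, end_seq, flank = planted_genome
    pair = design_junction_pair(end_seq, flank)
    other = random_dna(rng, 5000) + flank + random_dna(rng, 1000)  # flank without element
    assert virtual_pcr(other, pair) == []


def test_amplicons_match_exhaustive_scan(rng):
    """Random genome, exact matching: products equal a brute-force string search."""
    genome = random_dna(rng, 100_000)
    fwd, rev = genome[500:520], revcomp(genome[900:920])
    pair = PrimerPair(fwd, rev, max_mismatch=0, product_range=(50, 2000))

    def brute(g):
        hits = []
        rc = revcomp(rev)
        for strand, seq in (("+", g),):
            starts = [i for i in range(len(seq) - 19) if seq[i : i + 20] == fwd]
            ends = [i for i in range(len(seq) - 19) if seq[i : i + 20] == rc]
            for s in starts:
                for e in ends:
                    if e >= s + 20 and 50 <= e + 20 - s <= 2000:
                        hits.append((s, e + 20))
        return hits

    amps = virtual_pcr(genome, pair)
    plus = [(a.start, a.end) for a in amps if a.strand == "+"]
    assert plus == sorted(brute(genome))
    assert (500, 920) in plus


def test_three_prime_anchor_blocks_terminal_mismatch(rng):
    genome = random_dna(rng, 2000)
    fwd = genome[100:120]
    bad_last = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
    rev = revcomp(genome[300:320])
    ok = virtual_pcr(genome, PrimerPair(fwd, rev, 1, (50, 500)))
    bad = virtual_pcr(genome, PrimerPair(bad_last, rev, 1, (50, 500)))
    assert any(a.start == 100 for a in ok)
    assert not any(a.start == 100 for a in bad)


def test_strand_symmetry(rng):
    genome = random_dna(rng, 20_000)
    pair = PrimerPair(genome[1000:1020], revcomp(genome[1400:1420]), 0, (100, 1000))
    fwd_amps = virtual_pcr(genome, pair)
    mirror = virtual_pcr(revcomp(genome), pair)
    n = len(genome)
    mirrored = sorted((n - a.end, n - a.start, a.seq) for a in mirror)
    original = sorted((a.start, a.end, revcomp(a.seq)) for a in fwd_amps)
    assert [(s, e) for s, e, _ in mirrored] == [(s, e) for s, e, _ in original]
    assert sorted(a.seq for a in fwd_amps) == sorted(revcomp(s) for *_, s in mirrored)


def test_panel_verdicts_compose_per_genome_results(small_panel):
    cfg, genomes, truth = small_panel
    fam = cfg.families[0]
    site = truth.unique_sites("cultivar01", fam.name)[0]
    pair = design_junction_pair(fam.end_seq, site.flank_seq)
    presence, verdict = evaluate_marker_panel(genomes, pair)
    assert verdict == "specific to cultivar01"
    for cv, g in genomes.items():
        assert presence[cv] == bool(virtual_pcr(g, pair))


def test_panel_matches_truth_rows_for_all_sites(small_panel):
    cfg, genomes, truth = small_panel
    fam = cfg.families[0]
    for site in truth.sites:
        pair = design_junction_pair(fam.end_seq, site.flank_seq)
        presence, _ = evaluate_marker_panel(genomes, pair)
        assert {cv: int(v) for cv, v in presence.items()} == site.presence


def test_shared_site_not_specific(small_panel):
    cfg, genomes, truth = small_panel
    fam = cfg.families[0]
    shared = [s for s in truth.sites if sum(s.presence.values()) >= 2][0]
    pair = design_junction_pair(fam.end_seq, shared.flank_seq)
    _, verdict = evaluate_marker_panel(genomes, pair)
    assert verdict == "not specific"


def build_lamp_target(rng):
    """Construct a target and a primer set from its regions (the canonical layout)."""
    f3 = random_dna(rng, 18)
    f2 = random_dna(rng, 18)
    loopf = random_dna(rng, 16)
    f1 = random_dna(rng, 20)
    b1c = random_dna(rng, 20)
    loopb = random_dna(rng, 16)
    b2c = random_dna(rng, 18)
    b3c = random_dna(rng, 18)
    spacer = lambda n: random_dna(rng, n)
    target = spacer(10) + f3 + spacer(5) + f2 + loopf + f1 + spacer(8) + b1c + loopb + b2c + spacer(5) + b3c + spacer(10)
    primers = LampPrimerSet(
        F3=f3,
        B3=revcomp(b3c),
        FIP=revcomp(f1) + f2,
        BIP=b1c + revcomp(b2c),
        LoopF=revcomp(loopf),
        LoopB=loopb,
        tag_label=("FIP", "A1"),
        biotin_primer="BIP",
        name="synthetic",
    )
    return target, primers


def test_constructed_lamp_set_passes_all_checks(rng):
    target, primers = build_lamp_target(rng)
    rep = validate_lamp_set(target, primers)
    assert rep.passed, {k: v.detail for k, v in rep.checks.items() if not v.passed}
    order = [rep.elements[e][0] for e in ["F3", "F2", "F1", "B1", "B2", "B3"]]
    assert order == sorted(order)


def test_swapped_fip_halves_fail_composition(rng):
    target, primers = build_lamp_target(rng)
    f1c, f2 = primers.FIP[:20], primers.FIP[20:]
    swapped = LampPrimerSet(
        F3=primers.F3, B3=primers.B3, FIP=f2 + f1c, BIP=primers.BIP, LoopB=primers.LoopB
    )
    rep = validate_lamp_set(target, swapped)
    assert not rep.checks["fip_composition"].passed


def test_loopf_optional_loopb_only_set_accepted(rng):
    target, primers = build_lamp_target(rng)
    no_loopf = LampPrimerSet(
        F3=primers.F3, B3=primers.B3, FIP=primers.FIP, BIP=primers.BIP, LoopB=primers.LoopB
    )
    rep = validate_lamp_set(target, no_loopf)
    assert rep.passed
    assert "loopf_placement" not in rep.checks
    assert rep.checks["loopb_placement"].passed


def test_unmapped_primer_reported_not_raised(rng):
    target, primers = build_lamp_target(rng)
    broken = LampPrimerSet(
        F3="GGGGGGGGGGGGGGGGGG", B3=primers.B3, FIP=primers.FIP, BIP=primers.BIP, LoopB=primers.LoopB
    )
    rep = validate_lamp_set(target, broken)
    assert rep.elements["F3"] is None
    assert not rep.checks["ordering"].passed


def test_short_target_rejected():
    with pytest.raises(ValueError, match="120"):
        validate_lamp_set("ACGT" * 20, LampPrimerSet("A" * 18, "C" * 18, "G" * 36, "T" * 36))


def test_duplex_label_rule(rng):
    _, labelled = build_lamp_target(rng)
    _, bare = build_lamp_target(rng)
    bare.tag_label = None
    bare.name = "bare"
    result = check_duplex_labels([labelled, bare])
    assert result == {"synthetic": True, "bare": False}
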