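"""In-silico validation of insertion-site markers.

Two validators:

- :func:`virtual_pcr` treats amplification as mismatch-bounded string
  matching with a strict 3'-terminal anchor on both primers, on both
  strands, reporting every product whose length falls in the pair's range.
  Thermodynamics (Tm, cycling) is deliberately not modelled — the testable
  claim of a junction marker is the presence or absence of a priming site.
- :func:`validate_lamp_set` checks the architecture of a LAMP primer set
  against a target: FIP must decompose as F1c+F2 and BIP as B1c+B2, the six
  regions must appear in the canonical order F3 < F2 < F1 < B1 < B2 < B3
  along the target, and loop primers must sit inside their loops. Loop
  primers are optional (junction targets often only admit LoopB).

Primer label metadata (5' tag / biotin) for lateral-flow detection is
carried through and checked only for the duplex rule: one tag-labelled and
one biotin-labelled primer per set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

MIN_PRIMER_LEN = 15


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """A junction PCR pair: element-anchored forward, flank-anchored reverse."""

    forward: str
    reverse: str
    max_mismatch: int = 0
    product_range: tuple[int, int] = (40, 2000)
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.forward) < MIN_PRIMER_LEN or len(self.reverse) < MIN_PRIMER_LEN:
            raise ValueError("primers must be >= 15 bases")
        if self.product_range[0] > self.product_range[1]:
            raise ValueError("product_range min must be <= max")


@dataclass(frozen=True)
class Amplicon:
    start: int  # 0-based, forward strand
    end: int  # half-open
    strand: str  # '+': forward primer on plus strand; '-': on minus strand
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _match_positions(genome: np.ndarray, primer: str, max_mismatch: int) -> np.ndarray:
    """Start positions where primer matches with <= max_mismatch and an exact 3' base."""
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    L = len(primer)
    if genome.size < L:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(genome, L)
    mm = (windows != p).sum(axis=1)
    anchored = windows[:, -1] == p[-1]
    return np.nonzero((mm <= max_mismatch) & anchored)[0]


def _scan_plus(genome: np.ndarray, pair: PrimerPair) -> list[tuple[int, int]]:
    """(start, end) products with the forward primer on this strand."""
    fwd_starts = _match_positions(genome, pair.forward, pair.max_mismatch)
    # reverse primer anneals to the plus strand as its reverse complement,
    # 3' anchor at the leftmost base of the match
    rc = revcomp(pair.reverse)
    p = np.frombuffer(rc.encode(), dtype=np.uint8)
    L = len(rc)
    if genome.size < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(genome, L)
    mm = (windows != p).sum(axis=1)
    anchored = windows[:, 0] == p[0]
    rev_starts = np.nonzero((mm <= pair.max_mismatch) & anchored)[0]
    lo, hi = pair.product_range
    out = []
    for fs in fwd_starts:
        for rs in rev_starts:
            end = int(rs) + L
            length = end - int(fs)
            if int(rs) >= int(fs) + len(pair.forward) and lo <= length <= hi:
                out.append((int(fs), end))
    return out


def virtual_pcr(genome: str | Path, pair: PrimerPair) -> list[Amplicon]:
    """All products the pair would amplify from ``genome`` (string or FASTA path).

    Both strands are scanned; coordinates are 0-based half-open on the
    forward strand. An empty list means no amplification.
    """
    seq = _load_genome(genome)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    amps = [Amplicon(s, e, "+", seq[s:e]) for s, e in _scan_plus(arr, pair)]
    rc_seq = revcomp(seq)
    rc_arr = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
    for s, e in _scan_plus(rc_arr, pair):
        fs, fe = n - e, n - s  # mirror back to forward-strand coordinates
        amps.append(Amplicon(fs, fe, "-", seq[fs:fe]))
    return sorted(amps, key=lambda a: (a.start, a.end, a.strand))


def _load_genome(genome: str | Path) -> str:
    if isinstance(genome, Path) or (
        isinstance(genome, str)
        and len(genome) < 4096
        and "\n" not in genome
        and set(genome.upper()) - set("ACGTN")
        and Path(genome).is_file()
    ):
        records = list(SeqIO.parse(str(genome), "fasta"))
        return "".join(str(r.seq).upper() for r in records)
    return str(genome).upper()


def evaluate_marker_panel(
    genomes: Mapping[str, str | Path], pair: PrimerPair
) -> tuple[dict[str, bool], str]:
    """Amplification yes/no per cultivar and a specificity verdict.

    Verdict is ``"specific to X"`` iff exactly one cultivar amplifies,
    otherwise ``"not specific"``.
    """
    if len(genomes) < 2:
        raise ValueError("a marker panel needs >= 2 genomes")
    presence = {cv: bool(virtual_pcr(g, pair)) for cv, g in genomes.items()}
    positives = [cv for cv, ok in presence.items() if ok]
    verdict = f"specific to {positives[0]}" if len(positives) == 1 else "not specific"
    return presence, verdict


@dataclass
class LampPrimerSet:
    """A LAMP primer set; FIP = F1c + F2 and BIP = B1c + B2 against a target."""

    F3: str
    B3: str
    FIP: str
    BIP: str
    LoopF: str | None = None
    LoopB: str | None = None
    tag_label: tuple[str, str] | None = None  # (primer name, tag name), 5' tag
    biotin_primer: str | None = None
    name: str = ""


@dataclass
class LampCheck:
    passed: bool
    detail: str


@dataclass
class LampReport:
    """Structural validation result: per-element coordinates and checks."""

    elements: dict[str, tuple[int, int] | None] = field(default_factory=dict)
    checks: dict[str, LampCheck] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks.values())


def _find_exact(target: str, probe: str) -> tuple[int, int] | None:
    i = target.find(probe)
    return (i, i + len(probe)) if i >= 0 else None


def _decompose_composite(target: str, composite: str) -> tuple[tuple[int, int], tuple[int, int], int] | None:
    """Split FIP-style primer into 5' half (revcomp maps to target) + 3' half (direct).

    Returns (pos of 3'-half region, pos of 5'-half's complement region, split)
    for the first valid split with both halves >= MIN_PRIMER_LEN.
    """
    n = len(composite)
    for split in range(MIN_PRIMER_LEN, n - MIN_PRIMER_LEN + 1):
        head, tail = composite[:split], composite[split:]
        tail_pos = _find_exact(target, tail)
        head_pos = _find_exact(target, revcomp(head))
        if tail_pos and head_pos:
            return tail_pos, head_pos, split
    return None


def validate_lamp_set(target: str, primers: LampPrimerSet) -> LampReport:
    """Validate a LAMP set's architecture against a target sequence.

    On the target's sense strand the recognised regions run
    F3, F2, (LoopF loop), F1, B1c, (LoopB loop), B2c, B3c. Checks:
    composite decomposition of FIP and BIP, region ordering
    F3 < F2 < F1 < B1 < B2 < B3, and loop-primer placement. Elements not
    found at 0 mismatches are reported as unmapped (never an exception).
    """
    if len(target) < 120:
        raise ValueError("LAMP target must be >= 120 bases")
    target = target.upper()
    rep = LampReport()

    rep.elements["F3"] = _find_exact(target, primers.F3)
    rep.elements["B3"] = _find_exact(target, revcomp(primers.B3))

    fip = _decompose_composite(target, primers.FIP)
    if fip:
        f2, f1, _ = fip
        rep.elements["F2"], rep.elements["F1"] = f2, f1
        ok = f2[0] < f1[0]
        rep.checks["fip_composition"] = LampCheck(ok, "FIP = F1c + F2" if ok else "FIP halves map in the wrong order (F2 must precede F1)")
    else:
        rep.elements["F2"] = rep.elements["F1"] = None
        rep.checks["fip_composition"] = LampCheck(False, "FIP does not decompose as F1c + F2 on the target")

    bip = _decompose_composite(revcomp(target), primers.BIP)
    if bip:
        # mapped on the antisense strand; mirror to sense coordinates
        n = len(target)
        b2_rc, b1_rc, _ = bip
        b2 = (n - b2_rc[1], n - b2_rc[0])
        b1 = (n - b1_rc[1], n - b1_rc[0])
        rep.elements["B2"], rep.elements["B1"] = b2, b1
        ok = b1[0] < b2[0]
        rep.checks["bip_composition"] = LampCheck(ok, "BIP = B1c + B2" if ok else "BIP halves map in the wrong order (B1 must precede B2)")
    else:
        rep.elements["B2"] = rep.elements["B1"] = None
        rep.checks["bip_composition"] = LampCheck(False, "BIP does not decompose as B1c + B2 on the target")

    required = ["F3", "F2", "F1", "B1", "B2", "B3"]
    missing = [e for e in required if rep.elements.get(e) is None]
    if missing:
        rep.checks["ordering"] = LampCheck(False, f"unmapped elements: {', '.join(missing)}")
    else:
        starts = [rep.elements[e][0] for e in required]  # type: ignore[index]
        ok = all(x < y for x, y in zip(starts, starts[1:]))
        rep.checks["ordering"] = LampCheck(ok, "F3 < F2 < F1 < B1 < B2 < B3" if ok else f"region order violated: {dict(zip(required, starts))}")

    for loop, lo_el, hi_el, sense in (("LoopF", "F2", "F1", False), ("LoopB", "B1", "B2", True)):
        probe = getattr(primers, loop)
        if probe is None:
            continue
        pos = _find_exact(target, probe if sense else revcomp(probe))
        rep.elements[loop] = pos
        lo, hi = rep.elements.get(lo_el), rep.elements.get(hi_el)
        if pos is None:
            rep.checks[f"{loop.lower()}_placement"] = LampCheck(False, f"{loop} unmapped on target")
        elif lo is None or hi is None:
            rep.checks[f"{loop.lower()}_placement"] = LampCheck(False, f"{loop} flanking regions unmapped")
        else:
            ok = lo[1] <= pos[0] and pos[1] <= hi[0]
            rep.checks[f"{loop.lower()}_placement"] = LampCheck(ok, f"{loop} inside the {lo_el}-{hi_el} loop" if ok else f"{loop} at {pos} outside loop ({lo_el} ends {lo[1]}, {hi_el} starts {hi[0]})")
    return rep


def check_duplex_labels(sets: Sequence[LampPrimerSet]) -> dict[str, bool]:
    """Lateral-flow duplex rule: each set carries exactly one tag and one biotin label."""
    return {
        s.name or f"set{i + 1}": (s.tag_label is not None) and (s.biotin_primer is not None)
        for i, s in enumerate(sets)
    }


def design_junction_pair(
    end_seq: str,
    flank: str,
    reverse_offset: int = 25,
    reverse_len: int = 20,
    max_mismatch: int = 0,
) -> PrimerPair:
    """Derive a junction PCR pair from a family terminus and a site flank.

    Forward primer = the element terminus (3' end at the junction); reverse
    primer = reverse complement of ``flank[reverse_offset:reverse_offset+reverse_len]``.
    The expected product is ``len(end_seq) + reverse_offset + reverse_len`` long.
    """
    if reverse_offset + reverse_len > len(flank):
        raise ValueError("flank too short for the requested reverse primer")
    rev = revcomp(flank[reverse_offset : reverse_offset + reverse_len])
    product = len(end_seq) + reverse_offset + reverse_len
    return PrimerPair(end_seq, rev, max_mismatch, (product - 10, product + 10))
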