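"""End-to-end orchestration: simulate -> preprocess -> cluster -> genotype ->
screen -> validate, with a reproducible seed and bundled reports.

Every stage consumes and produces plain files (FASTQ/FASTA/TSV/JSON); the
run manifest records the seed, parameters and SHA-256 checksums of every
report so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from tipprof import genotype as gt
from tipprof import simulate as sim
from tipprof.cluster import ClusterParams, cluster_seqs, clusters_to_frame
from tipprof.markers import design_junction_pair, evaluate_marker_panel
from tipprof.preprocess import PreprocessParams, Read, run_preprocess
from tipprof.tables import summarize_read_counts

log = logging.getLogger("tipprof")


@dataclass
class RunConfig:
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    threshold: float = gt.DEFAULT_THRESHOLD
    denominator: str = "preprocessed"  # or "raw"
    target_cultivar: str | None = None
    out_dir: Path = Path("results/run")
    work_dir: Path = Path("scratch/run")  # FASTQ/FASTA intermediates
    write_intermediates: bool = True


@dataclass
class RunResult:
    truth: sim.TruthSet
    genomes: dict[str, str]
    reports: dict[tuple[str, str], "object"]  # (cultivar, family) -> PreprocessReport
    clusters: dict[str, list]  # family -> clusters
    matrices: dict[str, gt.GenotypeMatrix]
    candidates: dict[str, list[gt.MarkerCandidate]]
    marker_validation: pd.DataFrame | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline on a simulated panel and bundle the reports.

    Writes to ``config.out_dir``: the truth table, per-library
    preprocessing reports, the read-count summary in the
    Total/Minimum/Average/Maximum layout, per-family cluster tables,
    genotype count/call matrices, marker candidates, the in-silico PCR
    validation report and a JSON manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    work = Path(config.work_dir)
    if config.write_intermediates:
        work.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        genomes, truth = sim.simulate_population(
            config.sim, out_dir=work / "genomes" if config.write_intermediates else None
        )
        libraries = sim.simulate_panel_libraries(genomes, config.sim)
        truth.to_tsv(out / "truth.tsv")
        log.info("simulate: %d cultivars, %d sites, %d libraries", len(genomes), len(truth.sites), len(libraries))

        stage = "preprocess"
        reports: dict[tuple[str, str], object] = {}
        survivors: dict[tuple[str, str], list] = {}
        pre_counts: dict[tuple[str, str], Mapping[str, int]] = {}
        raw_counts = pd.DataFrame(
            0, index=config.sim.cultivar_names(), columns=[f.name for f in config.sim.families], dtype=int
        )
        for (cv, fam_name), pairs in libraries.items():
            fam = next(f for f in config.sim.families if f.name == fam_name)
            if config.write_intermediates:
                sim.write_fastq_pairs(
                    pairs, work / f"{cv}_{fam_name}_R1.fastq", work / f"{cv}_{fam_name}_R2.fastq"
                )
            r1_reads = [Read(p.read_id, p.seq1, p.qual1) for p in pairs]
            params = dataclasses.replace(config.preprocess, retro_prefix=fam.end_seq)
            kept, report, pre = run_preprocess(r1_reads, params)
            reports[(cv, fam_name)] = report
            survivors[(cv, fam_name)] = kept
            pre_counts[(cv, fam_name)] = pre
            raw_counts.loc[cv, fam_name] = len(pairs)
            report.to_tsv(out / f"preprocess_{cv}_{fam_name}.tsv")
        summarize_read_counts(raw_counts).to_csv(out / "read_count_summary.tsv", sep="\t", index_label="cultivar")

        stage = "cluster"
        clusters_by_family: dict[str, list] = {}
        matrices: dict[str, gt.GenotypeMatrix] = {}
        for fam in config.sim.families:
            seq_counts: dict[str, dict[str, int]] = {}
            totals: dict[str, int] = {}
            for cv in config.sim.cultivar_names():
                pre = pre_counts[(cv, fam.name)]
                totals[cv] = (
                    int(sum(pre.values()))
                    if config.denominator == "preprocessed"
                    else int(raw_counts.loc[cv, fam.name])
                )
                for seq, n in pre.items():
                    seq_counts.setdefault(seq, {})[cv] = seq_counts.setdefault(seq, {}).get(cv, 0) + int(n)
            clusters = cluster_seqs(seq_counts, config.cluster, id_prefix=f"{fam.name}_Cl")
            clusters_by_family[fam.name] = clusters
            clusters_to_frame(clusters, config.sim.cultivar_names()).to_csv(
                out / f"clusters_{fam.name}.tsv", sep="\t", index=False
            )
            stage = "genotype"
            m = gt.build_genotype_matrix(fam.name, clusters, totals, config.threshold).drop_empty_sites()
            matrices[fam.name] = m
            m.to_tsv(out / f"genotype_counts_{fam.name}.tsv", out / f"genotype_calls_{fam.name}.tsv")
            stage = "cluster"
        gt.specificity_summary(list(matrices.values())).to_csv(out / "specificity_summary.tsv", sep="\t", index_label="cultivar")

        stage = "screen"
        target = config.target_cultivar or config.sim.cultivar_names()[0]
        candidates: dict[str, list[gt.MarkerCandidate]] = {}
        cand_rows = []
        for fam in config.sim.families:
            cands = gt.screen_specific(matrices[fam.name], target)
            candidates[fam.name] = cands
            cand_rows.extend(
                {"site_id": c.site_id, "family": c.family, "target": c.target_cultivar, "flank_seq": c.flank_seq}
                for c in cands
            )
        pd.DataFrame(cand_rows, columns=["site_id", "family", "target", "flank_seq"]).to_csv(
            out / "marker_candidates.tsv", sep="\t", index=False
        )

        stage = "validate"
        val_rows = []
        for fam in config.sim.families:
            for c in candidates[fam.name]:
                if len(c.flank_seq) < 45:
                    continue
                pair = design_junction_pair(fam.end_seq, c.flank_seq)
                presence, verdict = evaluate_marker_panel(genomes, pair)
                row = {"site_id": c.site_id, "family": c.family, "verdict": verdict}
                row.update({cv: "+" if presence[cv] else "-" for cv in config.sim.cultivar_names()})
                val_rows.append(row)
        validation = pd.DataFrame(val_rows) if val_rows else None
        if validation is not None:
            validation.to_csv(out / "marker_validation.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "seed": config.sim.seed,
            "threshold": config.threshold,
            "denominator": config.denominator,
            "target_cultivar": target,
            "sim": dataclasses.asdict(config.sim),
            "cluster": dataclasses.asdict(config.cluster),
            "preprocess": dataclasses.asdict(config.preprocess),
            "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        # retain partial outputs under a .partial marker and surface the stage
        (out / ".partial").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunResult(truth, genomes, reports, clusters_by_family, matrices, candidates, validation, manifest)


PASS_PATTERN = (True, False, True, False)
CONCORDANCE_COLUMNS = (
    "target marker in target cultivar",
    "target marker in other cultivars",
    "control marker in all cultivars",
    "no-template control",
)


def concordance_table(replicates: Mapping[str, Sequence[bool]]) -> pd.DataFrame:
    """Interlaboratory-style concordance report.

    ``replicates`` maps a replicate/lab label to its four observations:
    (target marker amplified in the target cultivar, target marker in any
    other cultivar, control marker in all cultivars, amplification in the
    no-template control). A replicate passes iff the pattern is
    (+, -, +, -).
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    rows = []
    for label, pattern in replicates.items():
        pattern = tuple(bool(x) for x in pattern)
        if len(pattern) != 4:
            raise ValueError(f"replicate {label!r}: expected 4 observations, got {len(pattern)}")
        row = {"replicate": label}
        row.update({col: "+" if v else "-" for col, v in zip(CONCORDANCE_COLUMNS, pattern)})
        row["pass"] = pattern == PASS_PATTERN
        rows.append(row)
    return pd.DataFrame(rows)
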