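"""Simulate the synthetic cultivar panel and its junction libraries.

Writes cultivar genomes and demultiplexed FASTQ libraries under
scratch/pipeline/ (large intermediates) and the ground-truth site table
under results/pipeline/.
"""

from panel_config import RESULTS, SCRATCH, SEED, sim_config

from tipprof.simulate import simulate_panel_libraries, simulate_population, write_fastq_pairs


def main() -> None:
    cfg = sim_config()
    RESULTS.mkdir(parents=True, exist_ok=True)
    fastq_dir = SCRATCH / "fastq"
    fastq_dir.mkdir(parents=True, exist_ok=True)

    genomes, truth = simulate_population(cfg, out_dir=SCRATCH / "genomes")
    truth.to_tsv(RESULTS / "truth.tsv")
    libraries = simulate_panel_libraries(genomes, cfg)
    n_reads = 0
    for (cv, fam), pairs in libraries.items():
        write_fastq_pairs(pairs, fastq_dir / f"{cv}_{fam}_R1.fastq", fastq_dir / f"{cv}_{fam}_R2.fastq")
        n_reads += len(pairs)

    m = truth.matrix()
    print(f"seed {SEED}: {len(truth.sites)} planted sites across {cfg.n_cultivars} cultivars")
    print(f"{len(libraries)} libraries, {n_reads} read pairs total")
    print(f"sites per family: " + ", ".join(f"{f.name}={len(truth.matrix(f.name))}" for f in cfg.families))
    print(f"cultivar-specific sites overall: {(m.sum(axis=1) == 1).sum()}")


if __name__ == "__main__":
    main()
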