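"""Cluster the pooled 50-mers into insertion sites, call genotypes, screen.

For each family: pool every cultivar's pre-collapse 50-mer counts, cluster
them by tiled self-alignment, call presence/absence under the 0.1% rule and
screen for sites unique to the target cultivar. Writes cluster tables,
genotype matrices, the specificity summary and the marker candidates under
results/pipeline/, and reports concordance against the planted truth.
"""

import pandas as pd
from panel_config import RESULTS, SCRATCH, TARGET, sim_config

from tipprof.cluster import ClusterParams, cluster_seqs, clusters_to_frame
from tipprof.genotype import build_genotype_matrix, screen_specific, specificity_summary

def main() -> None:
    cfg = sim_config()
    truth = pd.read_csv(RESULTS / "truth.tsv", sep="\t")
    cultivars = cfg.cultivar_names()

    matrices, all_cands = {}, []
    for fam in cfg.families:
        seq_counts: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for cv in cultivars:
            tab = pd.read_csv(SCRATCH / "counts" / f"{cv}_{fam.name}.tsv", sep="\t")
            totals[cv] = int(tab["count"].sum())
            for seq, n in zip(tab["seq"], tab["count"]):
                seq_counts.setdefault(seq, {})[cv] = int(n)
        clusters = cluster_seqs(seq_counts, ClusterParams(), id_prefix=f"{fam.name}_Cl")
        clusters_to_frame(clusters, cultivars).to_csv(RESULTS / f"clusters_{fam.name}.tsv", sep="\t", index=False)
        m = build_genotype_matrix(fam.name, clusters, totals).drop_empty_sites()
        m.to_tsv(RESULTS / f"genotype_counts_{fam.name}.tsv", RESULTS / f"genotype_calls_{fam.name}.tsv")
        matrices[fam.name] = m

        # concordance with the planted truth, matched on the flank 50-mer
        t = truth[truth["family"] == fam.name].set_index("flank_seq")
        agree = total = 0
        for cl_id, rep in m.representatives.items():
            if rep in t.index:
                planted = t.loc[rep, cultivars].astype(int)
                agree += int((m.calls.loc[cl_id] == planted).sum())
                total += len(cultivars)
        cands = screen_specific(m, TARGET)
        all_cands.extend(cands)
        print(
            f"{fam.name}: {len(clusters)} clusters for {len(t)} planted sites; "
            f"genotype concordance {agree}/{total}; {len(cands)} sites unique to {TARGET}"
        )

    summary = specificity_summary(list(matrices.values()))
    summary.to_csv(RESULTS / "specificity_summary.tsv", sep="\t", index_label="cultivar")
    pd.DataFrame(
        [{"site_id": c.site_id, "family": c.family, "target": c.target_cultivar, "flank_seq": c.flank_seq} for c in all_cands]
    ).to_csv(RESULTS / "marker_candidates.tsv", sep="\t", index=False)
    print("\nunique-site counts per cultivar and family:")
    print(summary.to_string())


if __name__ == "__main__":
    main()
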