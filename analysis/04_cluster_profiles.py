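"""Cluster the ANOVA-selected genes and the condition profiles.

Mean-standardises each significant gene set (log2 differences vs the
gene's across-condition mean), clusters gene rows by UPGMA on
1 - Pearson r, and builds the condition-profile dendrogram.
"""

from pathlib import Path

from nitrosig import anova, cluster, io, preprocess

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    log2 = io.read_expression_tsv(
        BASE / "data" / "expression_log2_imputed.tsv", scale="log2"
    )
    design = io.read_design_tsv(BASE / "data" / "design.tsv")
    avg = preprocess.average_replicates(log2, design)
    (BASE / "cluster").mkdir(parents=True, exist_ok=True)

    import pandas as pd

    for regime in ("LN", "HN"):
        table = pd.read_csv(
            BASE / "anova" / f"anova_{regime}.tsv", sep="\t", comment="#", index_col=0
        )
        sets = anova.classify_effects(table, fdr=0.05)
        cols = [c for c in avg.columns if f"_{regime}_" in c]
        for factor in ("G", "E", "GEI"):
            genes = sorted(sets[factor])
            if len(genes) < 3:
                print(f"{regime}/{factor}: only {len(genes)} genes, skipping")
                continue
            std = cluster.standardize_by_gene_mean(avg.loc[genes, cols])
            std = std.loc[std.std(axis=1) > 0]
            dendro = cluster.cluster_gene_rows(std)
            io.write_expression_tsv(std, BASE / "cluster" / f"standardized_{regime}_{factor}.tsv")
            io.write_results_tsv(
                dendro.merge_table(),
                BASE / "cluster" / f"gene_dendrogram_{regime}_{factor}.tsv",
                f"UPGMA merges, 1 - Pearson r, {regime}/{factor}",
            )
            two = dendro.leaf_clusters(2)
            print(
                f"{regime}/{factor}: {len(std)} genes -> top split "
                f"{int((two == 1).sum())} vs {int((two == 2).sum())}"
            )

    profile_dendro = cluster.upgma(cluster.pearson_similarity(avg.T))
    io.write_results_tsv(
        profile_dendro.merge_table(),
        BASE / "cluster" / "condition_profile_dendrogram.tsv",
        "UPGMA over condition-profile Pearson similarities",
    )
    print(f"condition profiles clustered: {profile_dendro.n_leaves} leaves")


if __name__ == "__main__":
    main()
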