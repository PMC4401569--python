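"""Per-gene two-way ANOVA within each nitrogen regime.

Separates genotype (strain), environment (fermentation stage) and their
interaction, calling significance at BH FDR < 0.05 per factor, and
compares the detected genotype set against the planted truth.
"""

from pathlib import Path

import pandas as pd

from nitrosig import anova, io

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    log2 = io.read_expression_tsv(BASE / "data" / "expression_log2_imputed.tsv", scale="log2")
    design = io.read_design_tsv(BASE / "data" / "design.tsv")
    truth = pd.read_csv(
        BASE / "data" / "ground_truth.tsv", sep="\t", comment="#", index_col=0
    )
    (BASE / "anova").mkdir(parents=True, exist_ok=True)
    for regime in ("LN", "HN"):
        table = anova.fit_two_way_anova(log2, design, regime)
        io.write_results_tsv(
            table, BASE / "anova" / f"anova_{regime}.tsv",
            f"two-way strain x stage ANOVA, regime={regime}, BH FDR 0.05",
        )
        sets = anova.classify_effects(table, fdr=0.05)
        n = len(table)
        print(
            f"{regime}: genotype {len(sets['G'])} ({100*len(sets['G'])/n:.0f}%), "
            f"environment {len(sets['E'])} ({100*len(sets['E'])/n:.0f}%), "
            f"interaction {len(sets['GEI'])} ({100*len(sets['GEI'])/n:.0f}%)"
        )
        planted = set(truth.index[truth["has_g_effect"]]) & set(table.index)
        hit = len(sets["G"] & planted)
        print(
            f"  genotype screen: {hit}/{len(planted)} planted genes recovered, "
            f"{len(sets['G'] - planted)} extra calls"
        )


if __name__ == "__main__":
    main()
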