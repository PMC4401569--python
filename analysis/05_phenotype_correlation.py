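"""Spearman screen of gene expression against fermentation phenotypes.

Growth phenotypes (specific growth rate mu, nitrogen uptake rate Nrate)
are screened against the 24 h samples; maximum fermentation rate (MFR)
against the final-stage samples.  Calls use |rho| > 0.6 with BH-adjusted
p < 0.05, and each correlated set is tested for category enrichment.
"""

from pathlib import Path

import pandas as pd

from nitrosig import correlate, enrichment, io

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    log2 = io.read_expression_tsv(
        BASE / "data" / "expression_log2_imputed.tsv", scale="log2"
    )
    design = io.read_design_tsv(BASE / "data" / "design.tsv").set_index("sample_id")
    phen = io.read_phenotype_tsv(BASE / "data" / "phenotypes.tsv")
    categories, _ = io.read_gmt(BASE / "data" / "annotation_synthetic.gmt")
    (BASE / "correlation").mkdir(parents=True, exist_ok=True)

    late = int(design["time_h"].max())
    for trait, t in (("mu", 24), ("n_rate", 24), ("mfr", late)):
        cols = list(design.index[design["time_h"] == t])
        cell = phen.set_index(["strain", "regime"])[trait]
        vec = pd.Series(
            [cell[(design.loc[c, "strain"], design.loc[c, "regime"])] for c in cols],
            index=cols,
        )
        res = correlate.correlation_screen(log2[cols], vec)
        io.write_results_tsv(
            res, BASE / "correlation" / f"screen_{trait}_{t}h.tsv",
            f"Spearman vs {trait} at {t}h, |rho|>0.6, BH p<0.05",
        )
        pos = set(res.index[res["direction"] == "positive"])
        neg = set(res.index[res["direction"] == "negative"])
        print(f"{trait} ({t}h): {len(pos)} positive, {len(neg)} negative genes")
        for name, genes in (("positive", pos), ("negative", neg)):
            if not genes:
                continue
            enr = enrichment.enrich(genes, categories, set(log2.index))
            io.write_results_tsv(
                enr.set_index("category"),
                BASE / "correlation" / f"enrichment_{trait}_{name}.tsv",
                "hypergeometric enrichment, p<0.001",
            )
            top = enr.iloc[0]
            print(f"  {name}: top category {top['category']} (p={top['p']:.2e})")


if __name__ == "__main__":
    main()
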