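"""The nitrogen-limitation biomarker cascade and its enrichment.

Pools each strain's limitation-stage LN sample against the matching HN
sample in a two-class Rank Product, strips HN time-responders, requires
LN induction, and applies the 3-fold (candidate) and 4-fold (final)
linear fold filters.  Scores the panels against the planted truth.
"""

from pathlib import Path

import pandas as pd

from nitrosig import enrichment, io, signature

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7


def main() -> None:
    linear = io.read_expression_tsv(BASE / "data" / "expression_normalized_linear.tsv")
    log2 = io.read_expression_tsv(
        BASE / "data" / "expression_log2_imputed.tsv", scale="log2"
    )
    design = io.read_design_tsv(BASE / "data" / "design.tsv")
    truth = pd.read_csv(
        BASE / "data" / "ground_truth.tsv", sep="\t", comment="#", index_col=0
    )
    categories, _ = io.read_gmt(BASE / "data" / "annotation_synthetic.gmt")
    (BASE / "signature").mkdir(parents=True, exist_ok=True)

    panel = signature.nitrogen_signature_pipeline(
        linear, log2, design, n_perm=500, seed=SEED
    )
    io.write_results_tsv(
        panel.fold_table().set_index("gene_id"),
        BASE / "signature" / "signature_panel.tsv",
        "cascade panels at folds >= 3 (candidate) and >= 4 (final), RP alpha 0.05",
    )
    print(
        f"RP: {len(panel.rp_up)} up, {len(panel.rp_down)} down; "
        f"{len(panel.rp_up & panel.hn_responders)} up genes removed as HN responders"
    )
    print(
        f"panels: candidate {len(panel.candidate_up)} up / {len(panel.candidate_down)} down; "
        f"final {len(panel.final_up)} up / {len(panel.final_down)} down"
    )
    planted = set(truth.index[truth["is_nitrogen_responsive"] & (truth["true_fold_LN_over_HN"] >= 4)])
    planted &= set(log2.index)
    if planted:
        hit = len(panel.final_up & planted)
        print(f"planted >=4-fold nitrogen genes recovered in final up panel: {hit}/{len(planted)}")
    top = panel.fold_table().head(5)
    print("strongest signature genes:")
    print(top.to_string(index=False))

    for name, genes in (("final_up", panel.final_up), ("final_down", panel.final_down)):
        if not genes:
            continue
        enr = enrichment.enrich(genes, categories, set(log2.index))
        io.write_results_tsv(
            enr.set_index("category"),
            BASE / "signature" / f"enrichment_{name}.tsv",
            "hypergeometric enrichment, p<0.001",
        )
        sig = enr[enr["significant"]]
        print(f"{name}: {len(sig)} categories enriched at p<0.001"
              + (f" (top: {enr.iloc[0]['category']})" if len(enr) else ""))


if __name__ == "__main__":
    main()
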