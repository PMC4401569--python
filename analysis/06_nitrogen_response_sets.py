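"""Per-strain LN-vs-HN differential sets, their Venn overlaps, and the
pairwise correlation matrix of log2(LN/HN) response vectors.

Shows how conserved each strain's transcriptional response to nitrogen
availability is across fermentation stages.
"""

from pathlib import Path

import pandas as pd

from nitrosig import io, preprocess, signature

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 7
N_PERM = 300


def main() -> None:
    log2 = io.read_expression_tsv(
        BASE / "data" / "expression_log2_imputed.tsv", scale="log2"
    )
    design = io.read_design_tsv(BASE / "data" / "design.tsv")
    (BASE / "response").mkdir(parents=True, exist_ok=True)

    strains = sorted(design["strain"].unique())
    rows = []
    for t in sorted(design["time_h"].unique()):
        per_ln, per_hn = {}, {}
        for i, s in enumerate(strains):
            up_ln, up_hn = signature.condition_de_sets(
                log2, design, s, t, n_perm=N_PERM, seed=SEED * 100 + 10 * t + i
            )
            per_ln[s], per_hn[s] = up_ln, up_hn
        for regime, sets in (("LN", per_ln), ("HN", per_hn)):
            rep = signature.overlap_report(sets)
            common = rep.intersections[tuple(strains)]
            print(
                f"{t}h higher-in-{regime}: "
                + ", ".join(f"{s}={len(sets[s])}" for s in strains)
                + f"; common to all three: {common}"
            )
            for combo, count in sorted(rep.regions.items()):
                rows.append(
                    {"time_h": t, "higher_in": regime,
                     "region": "&".join(combo), "genes": count}
                )
    io.write_results_tsv(
        pd.DataFrame(rows).set_index(["time_h", "higher_in"]),
        BASE / "response" / "venn_regions.tsv",
        f"exclusive Venn regions of per-strain RP sets, alpha=0.05, L={N_PERM}",
    )

    avg = preprocess.average_replicates(log2, design)
    corr = signature.response_correlation_matrix(avg, design)
    io.write_results_tsv(
        corr, BASE / "response" / "response_correlation_matrix.tsv",
        "Pearson correlation of per-cell log2(LN/HN) response vectors",
    )
    print(f"response correlation matrix: {corr.shape[0]} strain x stage cells")


if __name__ == "__main__":
    main()
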