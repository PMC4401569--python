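"""Generate the synthetic factorial study the downstream analyses consume.

Emulates the wine-fermentation design: 3 strains x {LN, HN} nitrogen
regimes x {12, 24, 96} h x 2 membrane replicates, with planted genotype,
stage, interaction and nitrogen-response effects plus missing spots.
Writes the raw matrix, design, phenotypes, ground truth and a synthetic
GMT annotation under results/analysis/data/.
"""

from pathlib import Path

from nitrosig import io, simulate
from nitrosig.simulate import SimulationConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis" / "data"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_genes=2000, missing_rate=0.03, seed=SEED)
    matrix, design, truth = simulate.generate_expression(cfg)
    phen = simulate.generate_phenotypes(truth, cfg, noise_sd=0.1)

    io.write_expression_tsv(matrix, OUT / "expression_raw.tsv")
    io.write_design_tsv(design, OUT / "design.tsv")
    io.write_phenotype_tsv(phen, OUT / "phenotypes.tsv")
    io.write_results_tsv(truth.table, OUT / "ground_truth.tsv", "planted effect labels")
    simulate.write_synthetic_gmt(truth, OUT / "annotation_synthetic.gmt", seed=SEED)

    t = truth.table
    print(f"simulated {matrix.shape[0]} genes x {matrix.shape[1]} samples -> {OUT}")
    print(
        f"planted: {int(t['has_g_effect'].sum())} genotype, "
        f"{int(t['has_e_effect'].sum())} stage, "
        f"{int(t['has_gei_effect'].sum())} interaction, "
        f"{int(t['is_nitrogen_responsive'].sum())} nitrogen-responsive genes"
    )
    print(f"missing entries: {int(matrix.isna().to_numpy().sum())}")


if __name__ == "__main__":
    main()
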