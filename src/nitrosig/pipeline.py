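"""End-to-end driver: simulate/load -> correct -> screen -> signature.

``run_pipeline`` executes the whole comparative analysis and writes every
stage's tables under the configured output directory:

  data/        raw + corrected matrices, design, phenotypes, truth, GMT
  anova/       per-regime per-gene ANOVA tables and significant-set sizes
  cluster/     mean-standardised matrices and UPGMA merge tables
  correlation/ phenotype screens (mu, n_rate at the growth stage; mfr late)
  response/    per-strain LN-vs-HN sets, Venn regions, response correlations
  signature/   Rank Product table, cascade panels, fold table
  enrichment/  hypergeometric category tests of the signature panels
  run_log.yaml resolved thresholds, seed, per-stage gene counts

The run is a pure function of (inputs, config, seed): identical inputs
give byte-identical bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, anova, cluster, correlate, enrichment, io, preprocess
from . import rankprod, signature, simulate

__all__ = ["run_pipeline"]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def run_pipeline(config: io.PipelineConfig, sim_config=None) -> dict:
    """Run every stage; returns a dict of in-memory results.

    ``sim_config`` (a :class:`simulate.SimulationConfig`) overrides the
    default synthetic design when no input matrix is configured.
    """
    config.validate()
    out = Path(config.out_dir)
    for sub in (
        "data",
        "anova",
        "cluster",
        "correlation",
        "response",
        "signature",
        "enrichment",
    ):
        (out / sub).mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    log: dict = {
        "package": "nitrosig",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "presence_min_fraction": config.presence_min_fraction,
            "knn_k": config.knn_k,
            "anova_fdr": config.anova_fdr,
            "rho_threshold": config.rho_threshold,
            "corr_p_threshold": config.corr_p_threshold,
            "rp_alpha": config.rp_alpha,
            "fold_thresholds": list(config.fold_thresholds),
            "enrichment_p": config.enrichment_p,
            "n_permutations": config.n_permutations,
        },
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    # ---- inputs -----------------------------------------------------------
    truth = None
    phen = None
    if config.matrix_path is not None:
        raw = io.read_expression_tsv(config.matrix_path)
        design = io.read_design_tsv(config.design_path)
        if config.phenotype_path:
            phen = io.read_phenotype_tsv(config.phenotype_path)
    else:
        if sim_config is None:
            sim_config = simulate.SimulationConfig(
                n_genes=config.n_genes,
                missing_rate=config.missing_rate,
                noise_sd_log2=config.noise_sd_log2,
                seed=seeds[0],
            )
        raw, design, truth = simulate.generate_expression(sim_config)
        phen = simulate.generate_phenotypes(truth, sim_config, noise_sd=0.1)
        io.write_results_tsv(
            truth.table, out / "data" / "ground_truth.tsv", "planted effect labels"
        )
    io.validate_design(raw, design)
    io.write_expression_tsv(raw, out / "data" / "expression_raw.tsv")
    io.write_design_tsv(design, out / "data" / "design.tsv")
    if phen is not None:
        io.write_phenotype_tsv(phen, out / "data" / "phenotypes.tsv")

    categories: dict[str, set] | None = None
    if config.gmt_path is not None:
        categories, _ = io.read_gmt(config.gmt_path)
    elif truth is not None:
        gmt_path = out / "data" / "annotation_synthetic.gmt"
        simulate.write_synthetic_gmt(truth, gmt_path, seed=seeds[1])
        categories, _ = io.read_gmt(gmt_path)

    # ---- preprocessing ----------------------------------------------------
    linear, log2 = preprocess.run(
        raw, min_fraction=config.presence_min_fraction, k=config.knn_k
    )
    io.write_expression_tsv(linear, out / "data" / "expression_normalized_linear.tsv")
    io.write_expression_tsv(log2, out / "data" / "expression_log2_imputed.tsv")
    log["stages"]["preprocess"] = {
        "genes_in": int(raw.shape[0]),
        "genes_after_presence_filter": int(linear.shape[0]),
        "imputed_entries": int(linear.isna().to_numpy().sum()),
    }
    avg = preprocess.average_replicates(log2, design)

    # ---- ANOVA screen per regime ------------------------------------------
    anova_sets: dict[str, dict[str, set]] = {}
    for regime in sorted(design["regime"].unique()):
        table = anova.fit_two_way_anova(log2, design, regime)
        io.write_results_tsv(
            table,
            out / "anova" / f"anova_{regime}.tsv",
            f"two-way strain x stage ANOVA, regime={regime}, BH FDR {config.anova_fdr}",
        )
        sets = anova.classify_effects(table, fdr=config.anova_fdr)
        anova_sets[regime] = sets
        log["stages"][f"anova_{regime}"] = {k: len(v) for k, v in sets.items()}

    # ---- clustering of ANOVA-selected genes -------------------------------
    for regime, sets in anova_sets.items():
        regime_cols = [c for c in avg.columns if f"_{regime}_" in c]
        for factor in ("G", "E", "GEI"):
            genes = sorted(sets[factor])
            if len(genes) < 3:
                continue
            std = cluster.standardize_by_gene_mean(avg.loc[genes, regime_cols])
            io.write_expression_tsv(
                std, out / "cluster" / f"standardized_{regime}_{factor}.tsv"
            )
            keep = std.index[std.std(axis=1) > 0]
            if len(keep) >= 3:
                dendro = cluster.cluster_gene_rows(std.loc[keep])
                io.write_results_tsv(
                    dendro.merge_table(),
                    out / "cluster" / f"gene_dendrogram_{regime}_{factor}.tsv",
                    f"UPGMA merges, 1 - Pearson r distance, regime={regime}, factor={factor}",
                )
    profile_dendro = cluster.upgma(cluster.pearson_similarity(avg.T))
    io.write_results_tsv(
        profile_dendro.merge_table(),
        out / "cluster" / "condition_profile_dendrogram.tsv",
        "UPGMA over condition-profile Pearson similarities",
    )

    # ---- phenotype correlation screens ------------------------------------
    corr_results = {}
    if phen is not None:
        d = design.set_index("sample_id")
        times = sorted(design["time_h"].unique())
        growth_t = 24 if 24 in times else times[min(1, len(times) - 1)]
        late_t = times[-1]
        for trait, t in (("mu", growth_t), ("n_rate", growth_t), ("mfr", late_t)):
            cols = list(d.index[d["time_h"] == t])
            cell_value = phen.set_index(["strain", "regime"])[trait]
            pheno_vec = pd.Series(
                [cell_value[(d.loc[c, "strain"], d.loc[c, "regime"])] for c in cols],
                index=cols,
            )
            res = correlate.correlation_screen(
                log2[cols],
                pheno_vec,
                rho_threshold=config.rho_threshold,
                p_threshold=config.corr_p_threshold,
            )
            corr_results[trait] = res
            io.write_results_tsv(
                res,
                out / "correlation" / f"screen_{trait}_{t}h.tsv",
                f"Spearman screen vs {trait} at {t}h, |rho|>{config.rho_threshold}, "
                f"BH p<{config.corr_p_threshold}",
            )
            log["stages"][f"correlation_{trait}"] = {
                "positive": int((res["direction"] == "positive").sum()),
                "negative": int((res["direction"] == "negative").sum()),
                "time_h": int(t),
            }

    # ---- per-strain LN-vs-HN response sets, Venn, response matrix ---------
    rp_seeds = _child_seeds(seeds[2], 1 + len(design["strain"].unique()) * len(
        design["time_h"].unique()
    ))
    venn_rows = []
    strains = sorted(design["strain"].unique())
    shared_times = sorted(
        t
        for t in design["time_h"].unique()
        if all(
            not design[
                (design["strain"] == s)
                & (design["time_h"] == t)
                & (design["regime"] == r)
            ].empty
            for s in strains
            for r in ("LN", "HN")
        )
    )
    si = 0
    for t in shared_times:
        per_strain_ln = {}
        per_strain_hn = {}
        for s in strains:
            up_ln, up_hn = signature.condition_de_sets(
                log2,
                design,
                s,
                t,
                alpha=config.rp_alpha,
                n_perm=config.n_permutations,
                seed=rp_seeds[si],
            )
            si += 1
            per_strain_ln[s] = up_ln
            per_strain_hn[s] = up_hn
        for regime_name, sets in (("LN", per_strain_ln), ("HN", per_strain_hn)):
            report = signature.overlap_report(sets)
            for combo, count in sorted(report.regions.items()):
                venn_rows.append(
                    {
                        "time_h": t,
                        "higher_in": regime_name,
                        "region": "&".join(combo),
                        "genes": count,
                    }
                )
    venn = pd.DataFrame(venn_rows)
    io.write_results_tsv(
        venn.set_index(["time_h", "higher_in"]),
        out / "response" / "venn_regions.tsv",
        f"exclusive Venn regions of per-strain RP sets, alpha={config.rp_alpha}",
    )
    resp_corr = signature.response_correlation_matrix(avg, design)
    io.write_results_tsv(
        resp_corr,
        out / "response" / "response_correlation_matrix.tsv",
        "Pearson correlation of per-cell log2(LN/HN) response vectors",
    )

    # ---- nitrogen-limitation signature cascade ----------------------------
    panel = signature.nitrogen_signature_pipeline(
        linear,
        log2,
        design,
        alpha=config.rp_alpha,
        n_perm=config.n_permutations,
        seed=seeds[3],
        thresholds=config.fold_thresholds,
    )
    fold_table = panel.fold_table()
    io.write_results_tsv(
        fold_table.set_index("gene_id"),
        out / "signature" / "signature_panel.tsv",
        f"cascade panels at folds >= {config.fold_thresholds[0]} (candidate) "
        f"and >= {config.fold_thresholds[1]} (final), RP alpha {config.rp_alpha}",
    )
    log["stages"]["signature"] = {
        "rp_up": len(panel.rp_up),
        "rp_down": len(panel.rp_down),
        "hn_responders_removed": len(panel.rp_up & panel.hn_responders),
        "candidate_up": len(panel.candidate_up),
        "candidate_down": len(panel.candidate_down),
        "final_up": len(panel.final_up),
        "final_down": len(panel.final_down),
    }

    # ---- enrichment of the signature panels -------------------------------
    enrich_results = {}
    if categories is not None:
        universe = set(log2.index)
        for name, genes in (
            ("candidate_up", panel.candidate_up),
            ("candidate_down", panel.candidate_down),
        ):
            if not genes:
                continue
            res = enrichment.enrich(
                genes, categories, universe, p_threshold=config.enrichment_p
            )
            enrich_results[name] = res
            io.write_results_tsv(
                res.set_index("category"),
                out / "enrichment" / f"enrichment_{name}.tsv",
                f"hypergeometric enrichment, significant at p<{config.enrichment_p}",
            )
            log["stages"][f"enrichment_{name}"] = int(res["significant"].sum())

    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    (out / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1))
    return {
        "raw": raw,
        "design": design,
        "truth": truth,
        "phenotypes": phen,
        "linear": linear,
        "log2": log2,
        "anova_sets": anova_sets,
        "correlation": corr_results,
        "venn": venn,
        "response_correlation": resp_corr,
        "panel": panel,
        "enrichment": enrich_results,
        "log": log,
    }
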