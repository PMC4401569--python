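"""Nitrogen-limitation biomarker cascade and cross-strain response sets.

The cascade pools the limitation-phase samples of the three strains (24 h
for the fast strains, 36 h for the slow one) as the LN class and the
matching HN samples as the other class, runs a two-class Rank Product,
and then strips genes whose induction is not nitrogen-limitation
specific:

  up pipeline:  RP up set
                -> remove HN responders (genes also induced over time
                   under nitrogen excess, per strain, unioned)
                -> intersect LN-induced genes (induced at the selected
                   time vs 12 h under LN)
                -> candidate panel at linear fold >= 3
                -> final panel at linear fold >= 4

  down pipeline: RP down set -> fold filters only (the exclusion and
                 intersection steps are defined for the up direction).

Fold changes are ratios of linear normalized group means (LN/HN for up,
HN/LN magnitude for down).  The module also provides the per-strain
LN-vs-HN differential sets behind the Venn comparisons and the pairwise
response-correlation matrix across strain x time cells.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cluster import pearson_similarity
from .rankprod import RPResult, rp_permutation_p, rp_significant

__all__ = [
    "fold_change",
    "condition_de_sets",
    "overlap_report",
    "OverlapReport",
    "response_correlation_matrix",
    "nitrogen_signature",
    "nitrogen_signature_pipeline",
    "SignaturePanel",
]


def _design_indexed(design: pd.DataFrame) -> pd.DataFrame:
    return design.set_index("sample_id") if "sample_id" in design.columns else design


def _cols(design: pd.DataFrame, strain=None, regime=None, time_h=None) -> list[str]:
    d = _design_indexed(design)
    sel = pd.Series(True, index=d.index)
    if strain is not None:
        sel &= d["strain"] == strain
    if regime is not None:
        sel &= d["regime"] == regime
    if time_h is not None:
        sel &= d["time_h"] == time_h
    return list(d.index[sel])


def fold_change(matrix: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Per-gene linear fold: mean(A) / mean(B) of normalized intensities."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ma = matrix[group_a].mean(axis=1)
    mb = matrix[group_b].mean(axis=1)
    if (ma <= 0).any() or (mb <= 0).any():
        raise AssertionError("nonpositive group mean; expected floored intensities")
    return ma / mb


def condition_de_sets(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    strain: str,
    time_h: int,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[set, set]:
    """(up-in-LN, up-in-HN) gene sets for one strain at one stage.

    Two-class Rank Product of the strain's LN replicates against its HN
    replicates at ``time_h``; significance at the permutation-p cutoff.
    """
    ln = _cols(design, strain=strain, regime="LN", time_h=time_h)
    hn = _cols(design, strain=strain, regime="HN", time_h=time_h)
    if not ln or not hn:
        raise ValueError(f"missing regime columns for {strain} at {time_h}h")
    rp = rp_permutation_p(matrix[ln], matrix[hn], n_perm=n_perm, seed=seed)
    return rp_significant(rp, alpha=alpha)


@dataclasses.dataclass
class OverlapReport:
    """All Venn regions of k named gene sets.

    ``regions`` maps a membership pattern (tuple of set names the region
    belongs to) to its exclusive cardinality; ``intersections`` maps each
    non-empty name subset to the plain intersection cardinality.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], int]
    intersections: dict[tuple[str, ...], int]

    def check_inclusion_exclusion(self) -> bool:
        """|union| from exclusive regions equals inclusion–exclusion sum."""
        union = sum(self.regions.values())
        incl_excl = 0
        for k in range(1, len(self.set_names) + 1):
            for combo in itertools.combinations(self.set_names, k):
                incl_excl += (-1) ** (k + 1) * self.intersections[combo]
        return union == incl_excl


def overlap_report(sets: Mapping[str, Iterable]) -> OverlapReport:
    """Venn partition of >= 2 named gene sets."""
    names = tuple(sets.keys())
    if len(names) < 2:
        raise ValueError("need at least two sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(as_sets[c] for c in combo))
            outside = set.union(
                *(as_sets[c] for c in names if c not in combo), set()
            )
            regions[combo] = len(inside - outside)
    intersections = {
        combo: len(set.intersection(*(as_sets[c] for c in combo)))
        for k in range(1, len(names) + 1)
        for combo in itertools.combinations(names, k)
    }
    return OverlapReport(set_names=names, regions=regions, intersections=intersections)


def response_correlation_matrix(
    avg_matrix: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of per-cell log2(LN/HN) response vectors.

    ``avg_matrix`` is the replicate-averaged log2 matrix with columns
    named ``{strain}_{regime}_{time:02d}h``.  Each strain x time cell
    contributes one per-gene response vector (LN minus HN); the output is
    their correlation matrix.
    """
    d = _design_indexed(design)
    strains = sorted(d["strain"].unique())
    times = sorted(d["time_h"].unique())
    responses = {}
    for strain in strains:
        for t in times:
            ln_col = f"{strain}_LN_{t:02d}h"
            hn_col = f"{strain}_HN_{t:02d}h"
            if ln_col not in avg_matrix.columns or hn_col not in avg_matrix.columns:
                raise ValueError(f"missing regime column for {strain} at {t}h")
            responses[f"{strain}_{t:02d}h"] = (
                avg_matrix[ln_col] - avg_matrix[hn_col]
            ).to_numpy()
    prof = pd.DataFrame(responses).T
    return pearson_similarity(prof)


@dataclasses.dataclass
class SignaturePanel:
    """Candidate (>= 3-fold) and final (>= 4-fold) biomarker panels."""

    candidate_up: set
    candidate_down: set
    final_up: set
    final_down: set
    fold_ln_over_hn: pd.Series  # linear LN/HN for every gene
    rp_up: set
    rp_down: set
    hn_responders: set
    ln_induced: set

    def fold_table(self) -> pd.DataFrame:
        """Candidate genes with direction and fold magnitude, largest first."""
        rows = []
        for g in self.candidate_up:
            rows.append(
                {
                    "gene_id": g,
                    "direction": "up",
                    "fold": float(self.fold_ln_over_hn[g]),
                    "final": g in self.final_up,
                }
            )
        for g in self.candidate_down:
            rows.append(
                {
                    "gene_id": g,
                    "direction": "down",
                    "fold": float(1.0 / self.fold_ln_over_hn[g]),
                    "final": g in self.final_down,
                }
            )
        return (
            pd.DataFrame(rows, columns=["gene_id", "direction", "fold", "final"])
            .sort_values(["direction", "fold"], ascending=[False, False])
            .reset_index(drop=True)
        )


def nitrogen_signature(
    rp: RPResult,
    hn_responders: Iterable,
    ln_induced: Iterable,
    folds: pd.Series,
    thresholds: tuple[float, float] = (3.0, 4.0),
    alpha: float = 0.05,
) -> SignaturePanel:
    """Apply the cascade to a pooled LN-vs-HN Rank Product result.

    ``folds`` is the per-gene linear LN/HN fold over the pooled classes;
    ``thresholds`` are the candidate and final fold cutoffs.
    """
    cand_thr, final_thr = thresholds
    if not 1.0 < cand_thr <= final_thr:
        raise ValueError("thresholds must satisfy 1 < candidate <= final")
    hn_responders = set(hn_responders)
    ln_induced = set(ln_induced)
    up, down = rp_significant(rp, alpha=alpha)
    specific_up = (up - hn_responders) & ln_induced
    candidate_up = {g for g in specific_up if folds[g] >= cand_thr}
    final_up = {g for g in candidate_up if folds[g] >= final_thr}
    candidate_down = {g for g in down if folds[g] <= 1.0 / cand_thr}
    final_down = {g for g in candidate_down if folds[g] <= 1.0 / final_thr}
    return SignaturePanel(
        candidate_up=candidate_up,
        candidate_down=candidate_down,
        final_up=final_up,
        final_down=final_down,
        fold_ln_over_hn=folds,
        rp_up=up,
        rp_down=down,
        hn_responders=hn_responders,
        ln_induced=ln_induced,
    )


def nitrogen_signature_pipeline(
    linear_matrix: pd.DataFrame,
    log_matrix: pd.DataFrame,
    design: pd.DataFrame,
    selected_time_h: Mapping[str, int] | None = None,
    baseline_time_h: int = 12,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    thresholds: tuple[float, float] = (3.0, 4.0),
    ln_induced_rule: str = "union",
) -> SignaturePanel:
    """The full biomarker cascade from replicate-level matrices.

    ``selected_time_h`` names each strain's nitrogen-limitation sampling
    time (default: 36 h for CEG if present in the design, else 24 h; 24 h
    for other strains).  ``ln_induced_rule`` is "union" (default: induced
    in at least one strain) or "intersection" (induced in every strain).

    Seeds for the internal Rank Product runs are derived from ``seed`` so
    the whole cascade is deterministic.
    """
    d = _design_indexed(design)
    strains = sorted(d["strain"].unique())
    times = set(d["time_h"].unique())
    if selected_time_h is None:
        selected_time_h = {
            s: (36 if s == "CEG" and 36 in times else 24) for s in strains
        }
    if ln_induced_rule not in ("union", "intersection"):
        raise ValueError("ln_induced_rule must be 'union' or 'intersection'")
    missing = [s for s in strains if s not in selected_time_h]
    if missing:
        raise ValueError(f"selected_time_h missing strains: {missing}")

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(1 + 2 * len(strains))]

    ln_cols: list[str] = []
    hn_cols: list[str] = []
    for s in strains:
        ln_cols += _cols(design, strain=s, regime="LN", time_h=selected_time_h[s])
        hn_cols += _cols(design, strain=s, regime="HN", time_h=selected_time_h[s])
    if not ln_cols or not hn_cols:
        raise ValueError("pooled class definitions resolve to no columns")

    rp = rp_permutation_p(
        log_matrix[ln_cols], log_matrix[hn_cols], n_perm=n_perm, seed=seeds[0]
    )

    hn_responders: set = set()
    ln_sets: list[set] = []
    for i, s in enumerate(strains):
        t_sel = selected_time_h[s]
        hn_late = _cols(design, strain=s, regime="HN", time_h=t_sel)
        hn_early = _cols(design, strain=s, regime="HN", time_h=baseline_time_h)
        # exclusion blacklist: false positives here erase genuine
        # biomarkers, so use the pfp (the method's expected-false-
        # positive measure) over all-pairs ranks for maximal evidence
        rp_hn = rp_permutation_p(
            log_matrix[hn_late], log_matrix[hn_early],
            n_perm=n_perm, seed=seeds[1 + i], pairing="all",
        )
        up_hn, _ = rp_significant(rp_hn, alpha=alpha, measure="pfp")
        hn_responders |= up_hn

        ln_late = _cols(design, strain=s, regime="LN", time_h=t_sel)
        ln_early = _cols(design, strain=s, regime="LN", time_h=baseline_time_h)
        # required whitelist: sensitivity matters, specificity is
        # restored by the intersection with the pooled RP up set
        rp_ln = rp_permutation_p(
            log_matrix[ln_late], log_matrix[ln_early],
            n_perm=n_perm, seed=seeds[1 + len(strains) + i],
        )
        up_ln, _ = rp_significant(rp_ln, alpha=alpha)
        ln_sets.append(up_ln)
    ln_induced = (
        set.union(*ln_sets) if ln_induced_rule == "union" else set.intersection(*ln_sets)
    )

    folds = fold_change(linear_matrix, ln_cols, hn_cols)
    return nitrogen_signature(
        rp, hn_responders, ln_induced, folds, thresholds=thresholds, alpha=alpha
    )
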