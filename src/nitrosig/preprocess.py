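"""Expression-matrix correction: normalisation, presence filter, imputation.

The fixed preprocessing order for macroarray intensity tables is

    normalize_global_median -> filter_presence -> to_log2 -> knn_impute

(enforced by :func:`run`).  Matrices are pandas DataFrames, genes as rows
and samples as columns; NaN marks a missing spot.  The ``attrs["scale"]``
tag ("linear" or "log2") travels with each matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_global_median",
    "filter_presence",
    "to_log2",
    "knn_impute",
    "average_replicates",
    "run",
]


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene IDs")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample IDs")


def normalize_global_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalise per-sample medians at the grand median (linear scale).

    Each sample's present values are divided by that sample's median and
    multiplied by the grand median of all present values; afterwards every
    per-sample median equals the grand median.  Targeting the grand median
    (instead of 1.0) keeps intensities on their original magnitude, which
    matters for the linear fold changes reported downstream.
    """
    _check_matrix(matrix)
    if matrix.attrs.get("scale", "linear") != "linear":
        raise ValueError("global-median normalization expects linear intensities")
    medians = matrix.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no present values: {bad}")
    grand = float(np.nanmedian(matrix.to_numpy()))
    out = matrix.div(medians, axis=1) * grand
    out.attrs["scale"] = "linear"
    return out


def filter_presence(matrix: pd.DataFrame, min_fraction: float = 0.75) -> pd.DataFrame:
    """Drop genes present in fewer than ``min_fraction`` of samples.

    A gene present in exactly 75% of samples is retained (strictly-less-than
    eliminates).
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.empty:
        raise ValueError("empty expression matrix")
    frac_present = matrix.notna().mean(axis=1)
    out = matrix.loc[frac_present >= min_fraction].copy()
    out.attrs["scale"] = matrix.attrs.get("scale", "linear")
    return out


def to_log2(matrix: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """Linear -> log2 with flooring at half the smallest positive value.

    Macroarray background subtraction can leave near-zero (or, in corrupt
    inputs, nonpositive) intensities whose log would dominate every screen;
    values below the floor are clipped to it before the transform.
    """
    if matrix.attrs.get("scale", "linear") == "log2":
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    if floor is None:
        positive = vals[np.isfinite(vals) & (vals > 0)]
        if positive.size == 0:
            raise ValueError("no positive values to anchor the log floor")
        floor = float(positive.min()) / 2.0
    out = pd.DataFrame(
        np.log2(np.where(np.isnan(vals), np.nan, np.maximum(vals, floor))),
        index=matrix.index,
        columns=matrix.columns,
    )
    out.attrs["scale"] = "log2"
    return out


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Gene-wise K-nearest-neighbour imputation (inverse-distance weights).

    For a gene missing in sample j, the k nearest genes (Euclidean distance
    over pairwise-complete samples, rescaled by sqrt(n_total/n_shared) so
    sparse overlaps are not spuriously close) that do have a value in j
    contribute a 1/distance-weighted average.  Zero-distance neighbours
    take over with equal weights.  If no candidate neighbour has a value
    in j the gene's own row mean is used and the event is logged.

    Expects a presence-filtered log2 matrix; present values pass through
    bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_matrix(matrix)
    X = matrix.to_numpy(dtype=float)
    missing = np.isnan(X)
    if not missing.any():
        out = matrix.copy()
        out.attrs["scale"] = matrix.attrs.get("scale", "log2")
        return out
    if missing.all(axis=1).any():
        raise ValueError("gene with no present values; run filter_presence first")

    rows_with_missing = np.flatnonzero(missing.any(axis=1))
    # nan_euclidean implements exactly the sqrt(n_total/n_shared) rescaling
    dist = nan_euclidean_distances(X[rows_with_missing], X)
    filled = X.copy()
    n_fallback = 0
    for ri, gi in enumerate(rows_with_missing):
        d = dist[ri].copy()
        d[gi] = np.inf  # not its own neighbour
        for j in np.flatnonzero(missing[gi]):
            has_value = ~np.isnan(X[:, j])
            cand = np.flatnonzero(has_value & np.isfinite(d))
            if cand.size == 0:
                filled[gi, j] = np.nanmean(X[gi])
                n_fallback += 1
                continue
            order = cand[np.argsort(d[cand], kind="stable")][:k]
            dn = d[order]
            if dn[0] == 0.0:
                zero = order[dn == 0.0]
                filled[gi, j] = X[zero, j].mean()
            else:
                w = 1.0 / dn
                filled[gi, j] = float(np.dot(w, X[order, j]) / w.sum())
    if n_fallback:
        logger.warning(
            "knn_impute: %d entries fell back to the gene's own row mean", n_fallback
        )
    out = pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)
    out.attrs["scale"] = matrix.attrs.get("scale", "log2")
    return out


def average_replicates(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Collapse membrane replicates: one column per (strain, regime, time).

    Only for clustering, correlation screens, fold changes and response
    matrices — the ANOVA and Rank Product stages consume replicate-level
    columns.  Requires a balanced design (equal replicate count per cell).
    """
    _check_matrix(matrix)
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")
    sub = design.loc[matrix.columns]
    counts = sub.groupby(["strain", "regime", "time_h"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced replicate counts across condition cells")
    cols = {}
    for (strain, regime, t), grp in sub.groupby(["strain", "regime", "time_h"]):
        cols[f"{strain}_{regime}_{t:02d}h"] = matrix[grp.index].mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.index)
    out.attrs["scale"] = matrix.attrs.get("scale", "log2")
    return out


def run(
    raw: pd.DataFrame,
    min_fraction: float = 0.75,
    k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full correction stage in its fixed order.

    Returns ``(linear_normalized_filtered, log2_imputed)``: the first for
    linear fold-change computation, the second for every statistical
    screen.
    """
    norm = normalize_global_median(raw)
    kept = filter_presence(norm, min_fraction=min_fraction)
    logged = to_log2(kept)
    imputed = knn_impute(logged, k=k)
    return kept, imputed
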