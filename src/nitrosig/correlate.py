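"""Phenotype–expression Spearman screen with the dual threshold.

Each gene's replicate-level expression across the strain x regime samples
of one time point is rank-correlated with a phenotype value (specific
growth rate mu or nitrogen uptake rate at the growth-phase time point;
maximum fermentation rate at the late time point).  A gene is called
positively (negatively) phenotype-associated when rho > 0.6 (< -0.6) and
its BH-adjusted p-value is below 0.05.

For n <= 8 samples the two-sided p-value is exact, by full enumeration of
the n! rank permutations; above that the usual t approximation
t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df is used (with tie-corrected rho).
"""

from __future__ import annotations

import functools
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .anova import bh_adjust

__all__ = [
    "spearman_rho",
    "spearman_p",
    "correlation_screen",
    "EXACT_P_MAX_N",
]

EXACT_P_MAX_N = 8


def spearman_rho(x, y) -> float:
    """Spearman coefficient: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@functools.lru_cache(maxsize=16)
def _null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    ident = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    ic = ident - ident.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    rho = (pc @ ic) / (np.sqrt((pc**2).sum(axis=1)) * math.sqrt((ic**2).sum()))
    return np.sort(np.abs(rho))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p-value for an observed Spearman rho on n samples.

    Exact permutation enumeration for n <= 8 (40320 orderings at most,
    cached per n); t approximation with n-2 df otherwise.
    """
    if abs(rho) > 1 + 1e-12:
        raise ValueError("|rho| cannot exceed 1")
    if n < 3:
        raise ValueError("need n >= 3")
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= EXACT_P_MAX_N:
        null = _null_abs_rho(n)
        # P(|rho_null| >= |rho_obs|) with a float-safety margin
        idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
        return float((null.size - idx) / null.size)
    if abs(rho) == 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_screen(
    matrix: pd.DataFrame,
    phenotype: pd.Series,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen every gene against one phenotype across aligned samples.

    ``phenotype`` must be indexed by the matrix's sample columns (exact
    set match; order follows the matrix).  Returns a per-gene table with
    rho, p, BH q and direction in {positive, negative, none}.  Genes with
    constant expression across the screened samples cannot carry rank
    information and are reported with rho = NaN, p = 1, direction none.
    """
    if set(phenotype.index) != set(matrix.columns):
        extra = set(phenotype.index) ^ set(matrix.columns)
        raise ValueError(f"phenotype/sample misalignment: {sorted(extra)}")
    y = phenotype.loc[matrix.columns].to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if np.unique(y).size == 1:
        raise ValueError("constant phenotype vector")

    X = matrix.to_numpy(dtype=float)
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum(axis=1)) * math.sqrt((ryc**2).sum())
    constant = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rxc @ ryc) / denom
    rho[constant] = np.nan

    p = np.ones(len(matrix))
    for i in range(len(matrix)):
        if not constant[i]:
            p[i] = spearman_p(rho[i], n)
    q = bh_adjust(p)

    direction = np.full(len(matrix), "none", dtype=object)
    direction[(rho > rho_threshold) & (q < p_threshold)] = "positive"
    direction[(rho < -rho_threshold) & (q < p_threshold)] = "negative"
    return pd.DataFrame(
        {"rho": rho, "p": p, "q": q, "direction": direction}, index=matrix.index
    )
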