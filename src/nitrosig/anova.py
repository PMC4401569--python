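"""Per-gene two-way factorial ANOVA with BH false-discovery control.

For each nitrogen regime separately, every gene's log2 expression is
decomposed over strain (genotype, G), fermentation stage (environment, E)
and their interaction (GEI) in a balanced a x b design with n >= 2
replicate membranes per cell:

    SS_G   = b*r * sum_s (m_s.. - m...)^2
    SS_E   = a*r * sum_t (m_.t. - m...)^2
    SS_GEI = r   * sum_st (m_st. - m_s.. - m_.t. + m...)^2
    SS_err = sum (x - m_st.)^2

F = MS_factor / MS_err with the classical degrees of freedom; in a
balanced design Type I/II/III sums of squares coincide, so the closed
form is exact.  Unbalanced input is rejected rather than silently refit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fit_two_way_anova", "bh_adjust", "classify_effects"]

_ZERO_TOL = 1e-12


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_two_way_anova(
    matrix: pd.DataFrame, design: pd.DataFrame, regime: str
) -> pd.DataFrame:
    """Strain x stage ANOVA for every gene within one nitrogen regime.

    ``matrix`` is the replicate-level log2 expression table; ``design``
    must cover its columns.  Returns a per-gene table with F, p and BH q
    for each factor plus the degrees of freedom.

    Degenerate genes: when the within-cell error variance is zero, a
    factor with positive sum of squares gets p = 0 (the signal is exact),
    and a factor with zero sum of squares gets F = 0, p = 1 (covers the
    all-constant gene).
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    sub = design[design["regime"] == regime]
    cols = [c for c in matrix.columns if c in sub.index]
    if not cols:
        raise ValueError(f"no samples for regime {regime!r}")
    sub = sub.loc[cols]
    strains = sorted(sub["strain"].unique())
    times = sorted(sub["time_h"].unique())
    a, b = len(strains), len(times)
    counts = sub.groupby(["strain", "time_h"]).size()
    if len(counts) != a * b or counts.nunique() != 1:
        raise ValueError("unbalanced strain x stage design")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell to estimate the interaction")

    # data cube (genes, a, b, r) in a fixed factor order
    order = []
    for s in strains:
        for t in times:
            cell = sub[(sub["strain"] == s) & (sub["time_h"] == t)]
            order.extend(cell.index.tolist())
    X = matrix[order].to_numpy(dtype=float).reshape(len(matrix), a, b, r)

    grand = X.mean(axis=(1, 2, 3))
    m_ab = X.mean(axis=3)
    m_a = X.mean(axis=(2, 3))
    m_b = X.mean(axis=(1, 3))
    ss_g = b * r * ((m_a - grand[:, None]) ** 2).sum(axis=1)
    ss_e = a * r * ((m_b - grand[:, None]) ** 2).sum(axis=1)
    inter = m_ab - m_a[:, :, None] - m_b[:, None, :] + grand[:, None, None]
    ss_gei = r * (inter**2).sum(axis=(1, 2))
    ss_err = ((X - m_ab[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))

    df_g, df_e, df_gei = a - 1, b - 1, (a - 1) * (b - 1)
    df_err = a * b * (r - 1)
    ms_err = ss_err / df_err

    # scale-aware zero test for degenerate variance
    scale = np.maximum(np.abs(grand), 1.0)
    err_zero = ms_err <= _ZERO_TOL * scale**2

    out = pd.DataFrame(index=matrix.index)
    for name, ss, df in (("G", ss_g, df_g), ("E", ss_e, df_e), ("GEI", ss_gei, df_gei)):
        ms = ss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ms / ms_err
        p = stats.f.sf(F, df, df_err)
        factor_zero = ss <= _ZERO_TOL * scale**2
        F = np.where(err_zero, np.where(factor_zero, 0.0, np.inf), F)
        p = np.where(err_zero, np.where(factor_zero, 1.0, 0.0), p)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = p
    for name in ("G", "E", "GEI"):
        out[f"q_{name}"] = bh_adjust(out[f"p_{name}"].to_numpy())
    out["df_G"], out["df_E"], out["df_GEI"], out["df_error"] = df_g, df_e, df_gei, df_err
    return out


def classify_effects(table: pd.DataFrame, fdr: float = 0.05) -> dict[str, set]:
    """Factor-wise significant gene sets at BH FDR <= ``fdr`` (may overlap)."""
    return {
        name: set(table.index[table[f"q_{name}"] <= fdr])
        for name in ("G", "E", "GEI")
    }
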