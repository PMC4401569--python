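"""Hypergeometric functional-category enrichment over GMT gene sets.

For a query of n genes drawn from a universe of N, a category covering K
universe genes and overlapping the query in k genes is scored by the
hypergeometric upper tail

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

computed in log space (scipy's survival function).  Categories are
intersected with the universe before testing; significance uses the raw
p < 0.001 cutoff with no multiple-testing correction, matching the
conventional web-interpreter practice for annotation screening.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["hypergeometric_upper_tail", "enrich"]


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable,
    categories: Mapping[str, Iterable],
    universe: Iterable,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """One hypergeometric test per category, sorted ascending by p.

    ``query`` must be a subset of ``universe``.  Returns a table with
    columns category, k, K, n, N, p, significant.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in categories.items():
        cat = set(members) & universe
        k = len(query & cat)
        p = hypergeometric_upper_tail(k, len(cat), n, N)
        rows.append(
            {
                "category": name,
                "k": k,
                "K": len(cat),
                "n": n,
                "N": N,
                "p": p,
                "significant": p < p_threshold,
            }
        )
    return (
        pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p", "significant"])
        .sort_values(["p", "category"], kind="stable")
        .reset_index(drop=True)
    )
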