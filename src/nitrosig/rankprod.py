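"""Two-class Rank Product differential expression with a permutation null.

For classes A and B of replicate log2 columns, each of K column pairs
yields per-gene log-ratios a - b.  Genes are ranked within each pair
(rank 1 = most up-regulated in A for the up statistic; most down for the
down statistic; ties get average ranks) and the Rank Product is the
geometric mean of a gene's K ranks.  Small RP_up means consistently up
in A.

The null is the original Rank Product reference distribution: L draws of
K independent uniform-random permutations of 1..n (not label
permutations — with three replicates per class there are too few).  For
gene g, with x_g the count of null RP values <= observed RP_g pooled over
all L*n draws,

    p_g = (x_g + 1) / (L*n + 1)

(+1 smoothing, so p is never 0), and the percentage-of-false-prediction
estimate is pfp_g = (x_g / L) / rank(RP_g).  Significance calls use the
permutation p at the 0.05 cutoff; pfp is reported alongside.

Pairing matters for validity.  With the all-pairs scheme (K = |A|*|B|)
the rank columns share replicates, are positively correlated, and the
independent-rank null is anticonservative (roughly three times the
nominal rate at alpha = 0.05 for 3-vs-3 classes).  The default scheme
therefore pairs the i-th column of A with the i-th column of B
(K = |A| = |B|): disjoint replicate sets make the K rankings genuinely
independent under an i.i.d.-noise null, so the reference distribution is
exact.  Order the class columns consistently (e.g. by strain) so the
pairing is meaningful; ``pairing="all"`` selects the all-pairs variant.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_fold_ranks",
    "rank_product_statistic",
    "rp_permutation_p",
    "rp_significant",
    "RPResult",
]


@dataclasses.dataclass
class RPResult:
    """Per-gene up/down Rank Products with permutation p-values."""

    table: pd.DataFrame  # rp_up, rp_down, p_up, p_down, pfp_up, pfp_down
    n_comparisons: int
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def _as_array(frame) -> np.ndarray:
    return (
        frame.to_numpy(dtype=float)
        if isinstance(frame, pd.DataFrame)
        else np.asarray(frame, dtype=float)
    )


def pairwise_fold_ranks(
    class_a, class_b, pairing: str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """(up, down) rank matrices, one column per compared A/B pair.

    ``pairing="all"`` compares every A column with every B column
    (K = |A|*|B|); ``pairing="disjoint"`` pairs columns positionally
    (K = |A| = |B|, required equal sizes).  up[:, k] ranks genes
    descending by the k-th pair's log-ratio (rank 1 = most up in A);
    down ranks ascending; average ranks on ties.
    """
    A = _as_array(class_a)
    B = _as_array(class_b)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("both classes need at least one replicate column")
    if A.shape[0] != B.shape[0]:
        raise ValueError("classes must share the gene set")
    if pairing == "all":
        ratios = A[:, :, None] - B[:, None, :]  # (n, |A|, |B|)
        ratios = ratios.reshape(A.shape[0], -1)
    elif pairing == "disjoint":
        if A.shape[1] != B.shape[1]:
            raise ValueError("disjoint pairing requires equal class sizes")
        ratios = A - B
    else:
        raise ValueError("pairing must be 'all' or 'disjoint'")
    up = stats.rankdata(-ratios, axis=0)
    down = stats.rankdata(ratios, axis=0)
    return up, down


def rank_product_statistic(ranks: np.ndarray) -> np.ndarray:
    """Geometric mean of per-comparison ranks, computed in the log domain."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim == 1:
        ranks = ranks[:, None]
    if np.any(ranks <= 0):
        raise ValueError("ranks must be positive")
    return np.exp(np.log(ranks).mean(axis=1))


def _null_rp_sorted(n: int, K: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted pool of L*n null RP values from random rank matrices."""
    out = np.empty(L * n)
    # keep each chunk's scratch arrays around ~2e6 entries
    chunk = int(max(1, min(L, 2_000_000 // max(1, n * K))))
    done = 0
    while done < L:
        m = min(chunk, L - done)
        u = rng.random((n, m * K))
        order = np.argsort(u, axis=0, kind="stable")
        ranks = np.empty_like(order)
        ranks[order, np.arange(m * K)[None, :]] = np.arange(1, n + 1)[:, None]
        logs = np.log(ranks.reshape(n, m, K)).mean(axis=2)
        out[done * n : (done + m) * n] = np.exp(logs).T.ravel()
        done += m
    out.sort()
    return out


def _exhaustive_null_sorted(n: int, K: int) -> tuple[np.ndarray, int]:
    total = math.factorial(n) ** K
    if total * n > 5_000_000:
        raise ValueError("exhaustive null too large; use the sampled null")
    perms = list(itertools.permutations(range(1, n + 1)))
    vals = []
    for combo in itertools.product(perms, repeat=K):
        ranks = np.array(combo, dtype=float).T  # (n, K)
        vals.append(np.exp(np.log(ranks).mean(axis=1)))
    return np.sort(np.concatenate(vals)), total


def rp_permutation_p(
    class_a,
    class_b,
    n_perm: int = 1000,
    seed: int | None = 0,
    exhaustive: bool = False,
    pairing: str = "disjoint",
) -> RPResult:
    """Rank Product analysis of class A vs class B replicate columns.

    The default disjoint pairing keeps the independent-rank null exact
    (see the module docstring); with unequal class sizes pass
    ``pairing="all"`` and interpret p-values as anticonservative.  With
    ``exhaustive=True`` the null enumerates all (n!)**K rank matrices
    instead of sampling L = ``n_perm`` of them (only feasible for tiny n).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    up, down = pairwise_fold_ranks(class_a, class_b, pairing=pairing)
    n, K = up.shape
    rp_up = rank_product_statistic(up)
    rp_down = rank_product_statistic(down)

    if exhaustive:
        null_sorted, L = _exhaustive_null_sorted(n, K)
    else:
        rng = np.random.default_rng(seed)
        L = n_perm
        null_sorted = _null_rp_sorted(n, K, L, rng)

    def _p_and_pfp(rp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.searchsorted(null_sorted, rp, side="right")
        p = (x + 1) / (null_sorted.size + 1)
        obs_rank = stats.rankdata(rp)  # rank 1 = smallest (most significant)
        pfp = (x / L) / obs_rank
        return p, pfp

    p_up, pfp_up = _p_and_pfp(rp_up)
    p_down, pfp_down = _p_and_pfp(rp_down)

    index = (
        class_a.index if isinstance(class_a, pd.DataFrame) else pd.RangeIndex(n)
    )
    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
        },
        index=index,
    )
    return RPResult(
        table=table,
        n_comparisons=K,
        n_permutations=int(L),
        seed=None if exhaustive else seed,
        exhaustive=exhaustive,
    )


def rp_significant(
    result: RPResult, alpha: float = 0.05, measure: str = "p"
) -> tuple[set, set]:
    """(up set, down set) at cutoff ``alpha`` on the chosen measure.

    ``measure="p"`` (default) thresholds the permutation p-value — the
    primary differential-expression cutoff.  ``measure="pfp"`` thresholds
    the percentage-of-false-prediction estimate instead; under a global
    null it admits almost nothing, which suits screens whose hits are
    used to *exclude* genes downstream.
    """
    if measure not in ("p", "pfp"):
        raise ValueError("measure must be 'p' or 'pfp'")
    t = result.table
    up = set(t.index[t[f"{measure}_up"] <= alpha])
    down = set(t.index[t[f"{measure}_down"] <= alpha])
    overlap = up & down
    if overlap:
        warnings.warn(
            f"{len(overlap)} genes significant in both directions at alpha={alpha}",
            stacklevel=2,
        )
    return up, down
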