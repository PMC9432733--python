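"""Nonparametric group comparison layer.

Kruskal-Wallis omnibus test (ties-corrected, chi-square reference),
Conover-Iman all-pairs post-hoc on ranks with pooled variance and a t
reference, epsilon-squared effect size, and compact-letter display of
the significance pattern.  Post-hoc p values are unadjusted by default
(matching common reporting of the Conover test after a significant
omnibus); Holm adjustment is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "conover_posthoc",
    "epsilon_squared",
    "compact_letters",
    "compare_groups",
]


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Rank-based omnibus H statistic and its chi-square p value.

    All-identical data yields H = 0, p = 1 rather than an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with at least 2 values each")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def conover_posthoc(groups: dict[str, np.ndarray], adjust: str | None = None) -> pd.DataFrame:
    """Conover-Iman all-pairs comparisons on the pooled ranks.

    The statistic for a pair (i, j) is
    ``t = (Rbar_i - Rbar_j) / sqrt(S^2 (N-1-H)/(N-g) (1/n_i + 1/n_j))``
    with ``S^2`` the ties-corrected variance of all ranks and two-sided p
    from Student's t with ``N - g`` degrees of freedom.  ``adjust="holm"``
    applies Holm step-down correction; the default reports unadjusted p.
    Returns a symmetric DataFrame with unit diagonal.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    N, g = pooled.size, len(arrays)
    if N <= g:
        raise ValueError("need more observations than groups")
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]:bounds[i + 1]].mean() for i in range(g)])
    h, _ = kruskal_wallis(groups)
    s2 = (np.sum(ranks ** 2) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    if s2 <= 0:  # all values tied
        mat = pd.DataFrame(np.ones((g, g)), index=names, columns=names)
        return mat
    factor = s2 * (N - 1 - h) / (N - g)
    factor = max(factor, 1e-12)
    pvals, pairs = [], []
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            t = (mean_ranks[i] - mean_ranks[j]) / se
            pvals.append(2.0 * sps.t.sf(abs(t), df=N - g))
            pairs.append((i, j))
    pvals = np.minimum(np.asarray(pvals), 1.0)
    if adjust == "holm":
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        m = pvals.size
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * pvals[k])
            adj[k] = min(running, 1.0)
        pvals = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment '{adjust}'")
    mat = np.ones((g, g))
    for (i, j), p in zip(pairs, pvals):
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=names, columns=names)


def epsilon_squared(h: float, n: int) -> float:
    """Effect size for the Kruskal-Wallis H: ``H / ((n^2 - 1)/(n + 1))``,
    i.e. H / (n - 1); ranges from 0 (no effect) to 1 (complete ordering)."""
    if n < 2:
        raise ValueError("need at least 2 observations")
    return float(h) / (n - 1)


def compact_letters(pmatrix: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different at ``alpha``.
    Starts from one set holding every group; each significant pair splits
    the sets containing both members; subset sets are absorbed; letters
    are assigned in group order.
    """
    names = list(pmatrix.index)
    sets: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if pmatrix.loc[a, b] >= alpha:
                continue
            new_sets: list[set[str]] = []
            for s in sets:
                if a in s and b in s:
                    new_sets.extend([s - {a}, s - {b}])
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            sets = [s for s in new_sets if s and not any(
                s < t for t in new_sets if s is not t)]
            # drop duplicates
            uniq = []
            for s in sets:
                if s not in uniq:
                    uniq.append(s)
            sets = uniq
    sets.sort(key=lambda s: min(names.index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for letter, s in zip(alphabet, sets):
        for name in s:
            letters[name] += letter
    return letters


@dataclass
class GroupComparison:
    """Bundle of the full comparison: omnibus, post-hoc, effect size, letters."""

    groups: dict[str, np.ndarray]
    h: float
    p: float
    pairwise: pd.DataFrame
    eps_squared: float
    letters: dict[str, str]


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05,
                   adjust: str | None = None) -> GroupComparison:
    """Kruskal-Wallis + Conover post-hoc + epsilon-squared + letters."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    h, p = kruskal_wallis(groups)
    pairwise = conover_posthoc(groups, adjust=adjust)
    n = int(sum(v.size for v in groups.values()))
    letters = compact_letters(pairwise, alpha=alpha)
    return GroupComparison(groups, h, p, pairwise, epsilon_squared(h, n), letters)
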