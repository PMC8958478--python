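"""Independent brute-force oracles used by the test suite.

These deliberately work from raw adjacency matrices / rank vectors and never
call the package's own metric implementations.
"""

from __future__ import annotations

import numpy as np


def density_oracle(adj: np.ndarray) -> float:
    """Undirected density from a symmetric 0/1 adjacency matrix."""
    n = adj.shape[0]
    return float(adj.sum()) / (n * (n - 1))


def centralization_oracle(adj: np.ndarray) -> float:
    """Freeman degree centralization from a symmetric adjacency matrix."""
    n = adj.shape[0]
    degrees = adj.sum(axis=1)
    return float((degrees.max() - degrees).sum()) / ((n - 1) * (n - 2))


def midrank(values: np.ndarray) -> np.ndarray:
    """Mid-ranks computed by pairwise comparison counts (O(n^2))."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(values < values[i])
        equal = np.sum(values == values[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""
    rx, ry = midrank(np.asarray(x)), midrank(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def friedman_oracle(values: np.ndarray) -> float:
    """Tie-corrected Friedman statistic recomputed from first principles."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.vstack([midrank(row) for row in values])
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    return chi2 / correction if correction > 0 else 0.0


def assessable_reciprocity_oracle(
    ties: set[tuple[str, str]], responded: set[str]
) -> float | None:
    """Edge-wise reciprocity by enumerating all assessable ordered pairs."""
    assessable = [(s, t) for (s, t) in ties if s in responded and t in responded]
    if not assessable:
        return None
    return sum((t, s) in ties for (s, t) in assessable) / len(assessable)
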