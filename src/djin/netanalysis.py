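"""Posterior interaction-network extraction.

Each directed edge W_ij has an independent Laplace posterior with location
W_bar_ij and scale b_ij.  Robust edges are those whose central 99% credible
interval excludes zero; the pruned signed network is the model's
interpretable output.  Hierarchical structure is summarized by average-
linkage agglomeration on a dissimilarity built from the symmetrized
absolute robust weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "InteractionPosterior",
    "credible_interval",
    "prune",
    "cluster",
]


def credible_interval(m, b, level=0.99):
    """Central Laplace credible interval(s).

    With tail mass q = (1 - level)/2 the Laplace quantile offset is
    b * ln(2q), giving [m + b ln(2q), m - b ln(2q)] — symmetric about m and
    degenerating to {m} as b -> 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m = np.asarray(m, float)
    b = np.asarray(b, float)
    q = (1.0 - level) / 2.0
    half = -b * np.log(2.0 * q)
    return m - half, m + half


@dataclass
class InteractionPosterior:
    """Posterior mean/scale per directed edge with a robustness mask."""

    W_bar: np.ndarray
    b: np.ndarray
    pruned_mask: np.ndarray = None
    level: float = 0.99
    names: list = None

    def __post_init__(self):
        if np.any(self.b <= 0):
            raise ValueError("Laplace scales must be positive")
        if self.pruned_mask is None:
            self.pruned_mask = prune_mask(self.W_bar, self.b, self.level)
        if self.names is None:
            self.names = [f"x{i}" for i in range(self.W_bar.shape[0])]

    @property
    def robust_W(self) -> np.ndarray:
        """Posterior means of robust edges; pruned entries zero."""
        return self.W_bar * self.pruned_mask

    def edge_table(self) -> pd.DataFrame:
        """Long-format edge list (all off-diagonal edges, flagged)."""
        n = self.W_bar.shape[0]
        lo, hi = credible_interval(self.W_bar, self.b, self.level)
        rows = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                rows.append({
                    "source": self.names[j], "target": self.names[i],
                    "mean": self.W_bar[i, j], "scale": self.b[i, j],
                    "lo": lo[i, j], "hi": hi[i, j],
                    "sign": int(np.sign(self.W_bar[i, j])),
                    "robust": bool(self.pruned_mask[i, j]),
                })
        return pd.DataFrame(rows)


def prune_mask(W_bar, b, level=0.99):
    """1 where the credible interval lies entirely on one side of zero."""
    lo, hi = credible_interval(W_bar, b, level)
    mask = ((lo > 0) | (hi < 0)).astype(float)
    np.fill_diagonal(mask, 0.0)
    return mask


def prune(posterior: InteractionPosterior, level=0.99) -> InteractionPosterior:
    """Re-prune at a (possibly different) credible level."""
    return InteractionPosterior(
        W_bar=posterior.W_bar, b=posterior.b,
        pruned_mask=prune_mask(posterior.W_bar, posterior.b, level),
        level=level, names=posterior.names)


def cluster(W_bar):
    """Average-linkage agglomeration of the symmetrized weight matrix.

    omega = (W^T + W)/2 on the (absolute, robust) weights; dissimilarity
    D = max(omega) - omega.  Returns (linkage matrix, leaf order, newick
    string).  Merge ties break toward the lowest index (scipy's
    deterministic ordering).
    """
    W_bar = np.asarray(W_bar, float)
    n = W_bar.shape[0]
    if n < 2:
        raise ValueError("need at least 2 variables to cluster")
    omega = (W_bar.T + W_bar) / 2.0
    D = omega.max() - omega
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.average(squareform(D, checks=False))
    order = hierarchy.leaves_list(Z)
    return Z, order, _newick(Z, n)


def _newick(Z, n):
    """Render the merge tree as a nested-parentheses (newick) string."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return f"x{node.id}"
        left = walk(node.get_left())
        right = walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return walk(tree) + ";"
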