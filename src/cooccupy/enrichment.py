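"""Binding co-localization and chromatin-state enrichment statistics.

The pairwise binding enrichment compares the observed bp overlap of two
factors' peak sets with the overlap expected if both were placed
independently on the genome (binomial background):

    enrichment(A, B) = min( (100 + |A ∩ B|) / (100 + |A|·|B| / G), 500 )

where |A|, |B| are the total bp occupied by each (merged) peak set, |A ∩ B|
the shared bp, and G the genome size.  The 100 bp pseudocount regularizes
small sets and the value is capped at 500.  The factor-by-factor matrix is
ordered by complete-linkage hierarchical clustering with optimal leaf
ordering on distance = max(matrix) − matrix.

Chromatin-state enrichment is the observed/expected ratio of peak bp in each
state accounting for the state's genome fraction:
(peak bp in state / total peak bp) / (state bp / G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .genome_io import IntervalSet, Segmentation
from .occupancy import merge_intervals, shared_bp

__all__ = [
    "pairwise_enrichment",
    "enrichment_matrix",
    "EnrichmentMatrix",
    "cluster_olo",
    "ordering_cost",
    "state_enrichment",
]

PSEUDOCOUNT_BP = 100.0
ENRICHMENT_CAP = 500.0


def pairwise_enrichment(a: IntervalSet, b: IntervalSet, G: int | None = None) -> float:
    """Observed/expected bp overlap of two merged peak sets, capped at 500."""
    if a.genome != b.genome:
        raise ValueError("interval sets on different genomes")
    G = a.genome.G if G is None else G
    if G <= 0:
        raise ValueError("genome size must be positive")
    am, bm = merge_intervals(a), merge_intervals(b)
    observed = shared_bp(am, bm)
    expected = am.total_bp * bm.total_bp / G
    value = (PSEUDOCOUNT_BP + observed) / (PSEUDOCOUNT_BP + expected)
    return float(min(value, ENRICHMENT_CAP))


@dataclass
class EnrichmentMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric (n, n)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("enrichment matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def enrichment_matrix(
    sets: dict[str, IntervalSet], G: int | None = None
) -> EnrichmentMatrix:
    """Symmetric factor-by-factor pairwise enrichment matrix."""
    labels = list(sets)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate factor labels")
    if len(labels) < 2:
        raise ValueError("need at least two factors")
    n = len(labels)
    vals = np.zeros((n, n))
    merged = {lab: merge_intervals(s) for lab, s in sets.items()}
    for i in range(n):
        for j in range(i, n):
            e = pairwise_enrichment(merged[labels[i]], merged[labels[j]], G)
            vals[i, j] = vals[j, i] = e
    return EnrichmentMatrix(labels, vals)


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:g},{right}:{node.dist / 2:g})"


def _bar_joseph_order(root, dist: np.ndarray) -> tuple[list[int], float]:
    """Exact optimal leaf ordering by the Bar-Joseph dynamic program.

    For every subtree, tabulates the minimal ordering cost for each
    (leftmost leaf, rightmost leaf) pair; parents join child orderings over
    the boundary distance.  Ties break on the first candidate in sorted
    (u, w) iteration so the result is deterministic.
    """

    def solve(node) -> dict[tuple[int, int], tuple[float, list[int]]]:
        if node.is_leaf():
            return {(node.id, node.id): (0.0, [node.id])}
        left = solve(node.get_left())
        right = solve(node.get_right())
        table: dict[tuple[int, int], tuple[float, list[int]]] = {}
        for first, second in ((left, right), (right, left)):
            for (u, m), (c1, o1) in sorted(first.items()):
                for (k, w), (c2, o2) in sorted(second.items()):
                    c = c1 + dist[m, k] + c2
                    prev = table.get((u, w))
                    if prev is None or c < prev[0] - 1e-12:
                        table[(u, w)] = (c, o1 + o2)
        return table

    table = solve(root)
    (_uw, (cost, order)) = min(
        sorted(table.items()), key=lambda item: (item[1][0], item[0])
    )
    return order, cost


def cluster_olo(matrix: EnrichmentMatrix) -> tuple[list[int], np.ndarray, str]:
    """Complete-linkage tree + optimal leaf order on max − enrichment distance.

    Returns (leaf order as indices into matrix.labels, linkage matrix,
    Newick string of the dendrogram).  The leaf order minimizes the sum of
    adjacent-leaf distances over all orders consistent with the tree
    (exact Bar-Joseph dynamic program).  Input rows are pre-sorted by label
    so ties break deterministically; the order is canonicalized so its first
    leaf index is smaller than its last (reflection-invariant output).
    """
    # canonicalize label order for deterministic tie-breaking
    perm = np.argsort(np.asarray(matrix.labels, dtype=object), kind="stable")
    labels = [matrix.labels[i] for i in perm]
    vals = matrix.values[np.ix_(perm, perm)]
    dist = vals.max() - vals
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="complete")
    order_local, _cost = _bar_joseph_order(to_tree(Z), dist)
    if order_local[0] > order_local[-1]:
        order_local = order_local[::-1]
    order = [int(perm[i]) for i in order_local]
    newick = _to_newick(to_tree(Z), labels) + ";"
    return order, Z, newick


def ordering_cost(dist: np.ndarray, order: list[int] | np.ndarray) -> float:
    """Sum of distances between adjacent leaves in the given order."""
    order = np.asarray(order)
    return float(dist[order[:-1], order[1:]].sum())


def state_enrichment(peaks: IntervalSet, seg: Segmentation) -> pd.Series:
    """Per-state observed/expected fold enrichment of peak bp.

    For state s: (peak bp in s / total peak bp) / (state bp / G).  The
    state-fraction-weighted mean over states is exactly 1 (conservation),
    because the segmentation tiles the genome.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if peaks.genome != seg.genome:
        raise ValueError("peaks and segmentation on different genomes")
    merged = merge_intervals(peaks)
    total_peak_bp = merged.total_bp
    G = seg.genome.G
    bp_per_state = seg.state_bp()
    out = {}
    for state in seg.state_names:
        sbp = bp_per_state.get(state, 0)
        if sbp == 0:
            continue  # states absent from the genome are excluded
        ov = shared_bp(merged, seg.to_interval_set(state))
        out[state] = (ov / total_peak_bp) / (sbp / G)
    return pd.Series(out, name=peaks.label or "enrichment")
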