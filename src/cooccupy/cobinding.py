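"""Combinatorial-binding analysis: genome binarization and k-means clustering.

The genome is tiled into fixed-width windows (default 500 bp, trailing
partial windows included) and each window is scored 0/1 per factor for the
presence of any peak overlapping it by >=1 bp.  Windows bound by no factor
are dropped — clustering is over binding events, not empty genome.  The
retained windows are clustered with Hartigan-Wong k-means (the update rule
behind R's default ``kmeans``): after a Lloyd-style initialization, single
points are moved between clusters whenever the move lowers the within-cluster
sum of squares, using the exact size-corrected cost change

    gain = n_src/(n_src-1) * d(x, c_src)^2  -  n_dst/(n_dst+1) * d(x, c_dst)^2

until no improving move exists.  Multiple random starts are scored by WCSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout, IntervalSet

__all__ = [
    "BinaryBindingMatrix",
    "binarize",
    "kmeans_hartigan_wong",
    "wcss",
    "cluster_summary",
]


@dataclass
class BinaryBindingMatrix:
    """Bound windows × factors, 0/1; windows with no bound factor removed."""

    window_chrom: np.ndarray  # (n,)
    window_start: np.ndarray  # (n,)
    window_end: np.ndarray
    factor_labels: list[str]
    values: np.ndarray  # (n, n_factors) uint8

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.factor_labels):
            raise ValueError("values shape does not match factor labels")
        if len(self.values) and not (self.values.sum(axis=1) > 0).all():
            raise ValueError("all-zero window rows must be dropped")

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.window_chrom,
                "start": self.window_start,
                "end": self.window_end,
            }
        )
        for j, lab in enumerate(self.factor_labels):
            df[lab] = self.values[:, j]
        return df


def binarize(sets: dict[str, IntervalSet], window: int = 500) -> BinaryBindingMatrix:
    """0/1 occupancy of genome-tiling windows per factor.

    A window scores 1 for a factor iff any of its peaks overlaps the window
    by >=1 bp.  Trailing partial windows are included; windows bound by no
    factor are dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not sets:
        raise ValueError("need at least one factor")
    first = next(iter(sets.values())).genome
    for s in sets.values():
        if s.genome != first:
            raise ValueError("factors on different genomes")
    genome: GenomeLayout = first
    labels = list(sets)
    # global window index: per chromosome, ceil(L / window) windows
    n_windows_per_chrom = {
        c: -(-genome.length_of(c) // window) for c in genome.chrom_names
    }
    offsets = {}
    total = 0
    for c in genome.chrom_names:
        offsets[c] = total
        total += n_windows_per_chrom[c]
    occupancy = np.zeros((total, len(labels)), dtype=np.uint8)
    for j, lab in enumerate(labels):
        for iv in sets[lab]:
            w0 = iv.start // window
            w1 = (iv.end - 1) // window  # last bp covered
            occupancy[offsets[iv.chrom] + w0 : offsets[iv.chrom] + w1 + 1, j] = 1
    keep = occupancy.sum(axis=1) > 0
    idx = np.nonzero(keep)[0]
    chroms = np.empty(len(idx), dtype=object)
    starts = np.zeros(len(idx), dtype=np.int64)
    ends = np.zeros(len(idx), dtype=np.int64)
    bounds = [(c, offsets[c], offsets[c] + n_windows_per_chrom[c]) for c in genome.chrom_names]
    for k, gi in enumerate(idx):
        for c, lo, hi in bounds:
            if lo <= gi < hi:
                w = gi - lo
                chroms[k] = c
                starts[k] = w * window
                ends[k] = min((w + 1) * window, genome.length_of(c))
                break
    return BinaryBindingMatrix(chroms, starts, ends, labels, occupancy[keep])


def wcss(X: np.ndarray, assignment: np.ndarray, k: int) -> float:
    """Within-cluster sum of squared Euclidean distances to centroids."""
    total = 0.0
    for c in range(k):
        pts = X[assignment == c]
        if len(pts):
            total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def _hartigan_sweeps(X: np.ndarray, assign: np.ndarray, k: int, rng: np.random.Generator,
                     max_sweeps: int = 100) -> np.ndarray:
    n = len(X)
    counts = np.bincount(assign, minlength=k).astype(float)
    sums = np.zeros((k, X.shape[1]))
    for c in range(k):
        sums[c] = X[assign == c].sum(axis=0)
    for _ in range(max_sweeps):
        # re-seed empty clusters from the point farthest from its centroid
        for c in range(k):
            if counts[c] == 0:
                centers = sums / np.maximum(counts, 1)[:, None]
                d = ((X - centers[assign]) ** 2).sum(axis=1)
                far = int(np.argmax(d))
                src = assign[far]
                counts[src] -= 1
                sums[src] -= X[far]
                assign[far] = c
                counts[c] = 1
                sums[c] = X[far].copy()
        moved = 0
        for i in range(n):
            src = assign[i]
            if counts[src] <= 1:
                continue
            centers = sums / counts[:, None]
            d2 = ((centers - X[i]) ** 2).sum(axis=1)
            loss_src = counts[src] / (counts[src] - 1) * d2[src]
            gain_dst = counts / (counts + 1) * d2
            gain_dst[src] = np.inf
            dst = int(np.argmin(gain_dst))
            if gain_dst[dst] < loss_src - 1e-12:
                assign[i] = dst
                counts[src] -= 1
                sums[src] -= X[i]
                counts[dst] += 1
                sums[dst] += X[i]
                moved += 1
        if moved == 0:
            break
    return assign


def kmeans_hartigan_wong(
    matrix: BinaryBindingMatrix | np.ndarray,
    k: int,
    seed: int,
    n_starts: int = 10,
) -> tuple[np.ndarray, float]:
    """Hartigan-Wong k-means on window occupancy vectors.

    Returns (assignment, wcss) of the best of ``n_starts`` random starts.
    Deterministic given ``seed``.  Empty clusters are re-seeded from the
    point farthest from its centroid.
    """
    X = matrix.values.astype(float) if isinstance(matrix, BinaryBindingMatrix) else np.asarray(matrix, dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in [1, n_rows={n}]")
    if k == 1:
        return np.zeros(n, dtype=np.int64), wcss(X, np.zeros(n, dtype=np.int64), 1)
    rng = np.random.default_rng(seed)
    best_assign: np.ndarray | None = None
    best_cost = np.inf
    for _ in range(n_starts):
        centers_idx = rng.choice(n, size=k, replace=False)
        d2 = ((X[:, None, :] - X[centers_idx][None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1).astype(np.int64)
        assign = _hartigan_sweeps(X, assign, k, rng)
        cost = wcss(X, assign, k)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_assign = assign.copy()
    # relabel clusters by first occurrence so output is start-order independent
    relabel = {}
    out = np.empty_like(best_assign)
    nxt = 0
    for i, c in enumerate(best_assign):
        if c not in relabel:
            relabel[c] = nxt
            nxt += 1
        out[i] = relabel[c]
    return out, float(best_cost)


def cluster_summary(
    assignment: np.ndarray, matrix: BinaryBindingMatrix
) -> pd.DataFrame:
    """Per-cluster window count and per-factor bound fraction."""
    if len(assignment) != len(matrix):
        raise ValueError("assignment length does not match matrix")
    rows = []
    for c in sorted(np.unique(assignment)):
        mask = assignment == c
        row = {"cluster": int(c), "n_windows": int(mask.sum())}
        fracs = matrix.values[mask].mean(axis=0)
        for lab, f in zip(matrix.factor_labels, fracs):
            row[f"frac_{lab}"] = float(f)
        rows.append(row)
    return pd.DataFrame(rows)
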