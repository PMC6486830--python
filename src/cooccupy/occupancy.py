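"""Peak-level interval algebra and occupancy filters.

Implements the peak-processing conventions used throughout the pipeline:

* two intervals "overlap" iff they share at least 1 bp (touching half-open
  intervals do not overlap);
* replicate consistency keeps peaks present in both replicates;
* differential occupancy is a pure fold rule on depth-normalized tag counts
  over the wild-type/knockout union peak set (default threshold 2-fold);
* 4C contacts are retained iff supported by at least ``min_reads`` read
  pairs (default 16) in **both** replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, IntervalSet, TagCollection

__all__ = [
    "merge_intervals",
    "overlap_pairs",
    "shared_bp",
    "replicate_consistent",
    "union_peaks",
    "count_tags",
    "normalize_by_depth",
    "call_differential",
    "filter_4c",
]


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise ValueError("interval sets are on different genomes")


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Merge intervals sharing >=1 bp; touching intervals stay separate.

    Idempotent; preserves the union of bp coverage. Summits and scores are
    dropped on merged output (a merged span has no single summit).
    """
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in iset:  # already sorted by (chrom, start)
        if iv.chrom != cur_chrom or iv.start >= cur_end:
            if cur_chrom is not None:
                merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(iset.genome, merged, label=iset.label)


def overlap_pairs(
    a: IntervalSet, b: IntervalSet
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (iv_a, iv_b) sharing >=1 bp, with the shared bp count."""
    _check_same_genome(a, b)
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    pairs = []
    for iv_a in a:
        cands = b_by_chrom.get(iv_a.chrom, [])
        starts = np.asarray([c.start for c in cands], dtype=np.int64)
        # candidates with start < a.end; then filter end > a.start
        hi = int(np.searchsorted(starts, iv_a.end, side="left")) if len(cands) else 0
        for iv_b in cands[:hi]:
            ov = min(iv_a.end, iv_b.end) - max(iv_a.start, iv_b.start)
            if ov > 0:
                pairs.append((iv_a, iv_b, ov))
    return pairs


def shared_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Total bp in the intersection of the (merged) coverage of a and b."""
    _check_same_genome(a, b)
    am, bm = merge_intervals(a).by_chrom(), merge_intervals(b).by_chrom()
    total = 0
    for chrom, arr_a in am.items():
        arr_b = bm.get(chrom)
        if arr_b is None:
            continue
        i = j = 0
        while i < len(arr_a) and j < len(arr_b):
            lo = max(arr_a[i, 0], arr_b[j, 0])
            hi = min(arr_a[i, 1], arr_b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if arr_a[i, 1] <= arr_b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def replicate_consistent(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Peaks of rep1 with >=1 bp overlap with any rep2 peak (rep1 coordinates)."""
    _check_same_genome(rep1, rep2)
    r2 = rep2.by_chrom()
    kept = []
    for iv in rep1:
        arr = r2.get(iv.chrom)
        if arr is None or len(arr) == 0:
            continue
        # any rep2 interval with start < iv.end and end > iv.start
        idx = np.searchsorted(arr[:, 0], iv.end, side="left")
        if idx > 0 and (arr[:idx, 1] > iv.start).any():
            kept.append(iv)
    return IntervalSet(rep1.genome, kept, label=rep1.label)


def union_peaks(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Merged union of two peak sets (the wild-type/knockout union peak set)."""
    _check_same_genome(a, b)
    combined = IntervalSet(
        a.genome, list(a) + list(b), label=f"{a.label}|{b.label}".strip("|")
    )
    return merge_intervals(combined)


def _footprints(tags: TagCollection, read_extension: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directional footprints: [p, p+ext) on '+', [p-ext+1, p+1) on '-'."""
    pos = tags.positions
    plus = tags.strands == "+"
    starts = np.where(plus, pos, pos - read_extension + 1)
    ends = np.where(plus, pos + read_extension, pos + 1)
    return tags.chroms, starts.astype(np.int64), ends.astype(np.int64)


def count_tags(
    tags: TagCollection, intervals: IntervalSet, read_extension: int = 50
) -> np.ndarray:
    """Per-interval counts of tags whose directional footprint overlaps >=1 bp.

    A '+' tag at 5' position p has footprint [p, p+ext); a '-' tag covers
    [p-ext+1, p+1).  ``read_extension=1`` counts bare 5' positions.
    """
    if read_extension < 1:
        raise ValueError("read_extension must be >= 1")
    chroms, fs, fe = _footprints(tags, read_extension)
    counts = np.zeros(len(intervals), dtype=np.int64)
    order = np.argsort(chroms, kind="stable")
    chroms_s, fs_s, fe_s = chroms[order], fs[order], fe[order]
    # contiguous blocks per chromosome
    uniq, block_start = np.unique(chroms_s, return_index=True)
    block_end = np.append(block_start[1:], len(chroms_s))
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
        str(c): (np.sort(fs_s[s:e]), np.sort(fe_s[s:e]))
        for c, s, e in zip(uniq, block_start, block_end)
    }
    for i, iv in enumerate(intervals):
        got = per_chrom.get(iv.chrom)
        if got is None:
            continue
        starts_sorted, ends_sorted = got
        # overlap iff footprint start < iv.end AND footprint end > iv.start
        n_start_ok = np.searchsorted(starts_sorted, iv.end, side="left")
        n_end_bad = np.searchsorted(ends_sorted, iv.start, side="right")
        counts[i] = int(n_start_ok - n_end_bad)
    return counts


def normalize_by_depth(raw_counts: np.ndarray, library_size: int) -> np.ndarray:
    """Counts per million mapped reads: raw * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(raw_counts, dtype=float) * (1e6 / library_size)


def call_differential(
    union: IntervalSet,
    tags_a: TagCollection,
    tags_b: TagCollection,
    read_extension: int = 50,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Fold-rule differential occupancy over a union peak set.

    fold = (cpm_a + pc) / (cpm_b + pc); a site is called ``reduced`` (lower in
    condition B) when fold >= threshold, ``gained`` when 1/fold >= threshold,
    else ``unchanged``.  Condition A is conventionally the wild type.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    raw_a = count_tags(tags_a, union, read_extension)
    raw_b = count_tags(tags_b, union, read_extension)
    norm_a = normalize_by_depth(raw_a, tags_a.library_size)
    norm_b = normalize_by_depth(raw_b, tags_b.library_size)
    fold = (norm_a + pseudocount) / (norm_b + pseudocount)
    call = np.where(
        fold >= fold_threshold,
        "reduced",
        np.where(1.0 / fold >= fold_threshold, "gained", "unchanged"),
    )
    df = union.to_dataframe()[["chrom", "start", "end"]].copy()
    df["raw_a"] = raw_a
    df["raw_b"] = raw_b
    df["norm_a"] = norm_a
    df["norm_b"] = norm_b
    df["fold"] = fold
    df["call"] = call
    return df


def filter_4c(counts: pd.DataFrame, min_reads: int = 16) -> pd.DataFrame:
    """Retain 4C fragments supported by >= min_reads in both replicates."""
    for col in ("rep1", "rep2"):
        if col not in counts.columns:
            raise ValueError(f"4C table missing replicate column {col!r}")
    if (counts[["rep1", "rep2"]] < 0).to_numpy().any():
        raise ValueError("negative 4C counts")
    out = counts.copy()
    out["retained"] = (out["rep1"] >= min_reads) & (out["rep2"] >= min_reads)
    return out
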