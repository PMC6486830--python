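"""Peak-to-gene assignment and binding/expression association statistics.

A gene is "bound" by a peak class when any peak overlaps the closed window
[TSS − w, TSS + w] (strand ignored).  Association between differential
expression and binding is tested with the Pearson chi-square on the 2×2
(DE vs not) × (bound vs not) table, without continuity correction.  The
fold enrichment of binding near up-/down-regulated genes is

    fold_up = P(bound | upregulated) / P(bound | all genes)

and analogously for downregulated genes, where "bound" means a region of
interest within ±w of the TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneTable, IntervalSet

__all__ = [
    "assign_peaks_to_genes",
    "de_binding_chisq",
    "fold_enrichment_near_de",
]


def assign_peaks_to_genes(
    peaks: IntervalSet, genes: GeneTable, window: int
) -> pd.DataFrame:
    """Per-gene bound flag: any peak overlapping [tss-w, tss+w] by >=1 bp.

    The window is inclusive on both ends; strand is ignored.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom = peaks.by_chrom()
    df = genes.df.copy()
    bound = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom"):
        arr = by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        for idx, tss in zip(sub.index, sub["tss"].to_numpy()):
            lo, hi = tss - window, tss + window + 1  # closed window, half-open form
            j = np.searchsorted(starts, hi, side="left")
            bound[idx] = j > 0 and bool((ends[:j] > lo).any())
    df["bound"] = bound
    df["window_bp"] = window
    return df


def de_binding_chisq(table: pd.DataFrame) -> dict:
    """Pearson chi-square (1 df, no continuity correction) of DE × bound.

    DE means de_status in {up, down}.  Returns the 2×2 counts, statistic,
    p-value, and the bound fraction among DE genes.  A zero margin is an
    error rather than a NaN statistic.
    """
    de = table["de_status"].isin(["up", "down"]).to_numpy()
    bound = table["bound"].to_numpy(dtype=bool)
    counts = np.array(
        [
            [int((de & bound).sum()), int((de & ~bound).sum())],
            [int((~de & bound).sum()), int((~de & ~bound).sum())],
        ]
    )
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return {
        "table": counts,
        "statistic": float(stat),
        "p_value": float(p),
        "dof": int(dof),
        "n_de": int(de.sum()),
        "n_de_bound": int((de & bound).sum()),
    }


def fold_enrichment_near_de(
    regions_of_interest: IntervalSet, genes: GeneTable, window: int = 20000
) -> dict[str, float]:
    """Binding fold enrichment near up- and downregulated genes.

    fold_up = (% up genes with a region within ±window of the TSS) /
              (% of all genes with one); analogously fold_down.
    """
    df = assign_peaks_to_genes(regions_of_interest, genes, window)
    frac_all = df["bound"].mean()
    if frac_all == 0:
        raise ValueError("no gene has a region of interest within the window")
    out = {}
    for status, key in (("up", "fold_up"), ("down", "fold_down")):
        sub = df[df["de_status"] == status]
        if len(sub) == 0:
            raise ValueError(f"no {status}-regulated genes in table")
        out[key] = float(sub["bound"].mean() / frac_all)
    return out
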