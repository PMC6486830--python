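#!/usr/bin/env python
"""Differential occupancy: recover planted 4-fold reductions.

A quarter of factor-A peaks carry 4-fold higher ChIP signal in "WT" than in
"KO" tags; the pure >=2-fold rule on depth-normalized union-peak counts
should call exactly those as reduced.  Prints recall and false-call rate and
writes the full call table.
"""

import argparse
from pathlib import Path

import numpy as np

from cooccupy import occupancy, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/differential"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = synthetic.SimulationConfig(seed=args.seed)
    genome = synthetic.make_genome(cfg)
    peaks = synthetic.simulate_factor_peaks(cfg, genome)["A"]
    n = len(peaks)
    n_planted = n // 4
    folds = np.ones(n)
    folds[:n_planted] = 4.0
    wt = synthetic.simulate_tags(cfg, genome, peaks, "WT", folds=folds)
    ko = synthetic.simulate_tags(cfg, genome, peaks, "KO", folds=1.0)
    union = occupancy.merge_intervals(peaks)
    diff = occupancy.call_differential(union, wt, ko)
    diff["planted_reduced"] = diff.index < n_planted
    diff.to_csv(args.outdir / "calls.tsv", sep="\t", index=False, float_format="%.6g")

    recall = (diff.loc[diff["planted_reduced"], "call"] == "reduced").mean()
    false_rate = (diff.loc[~diff["planted_reduced"], "call"] != "unchanged").mean()
    print(f"union peaks: {len(diff)} (WT library {wt.library_size}, KO {ko.library_size})")
    print(f"planted 4-fold sites recalled as reduced: {100 * recall:.1f}%")
    print(f"fold-1 sites miscalled: {100 * false_rate:.2f}%")


if __name__ == "__main__":
    main()
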