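#!/usr/bin/env python
"""Generate the synthetic study dataset with planted structure.

Writes the genome layout, three factor peak sets (A/B co-bound at 50%,
C independent), the AP-MS spectral-count table, and the 4C fragment counts
under results/dataset/.  Everything downstream (02-07) regenerates what it
needs from the same seed, so this script is a convenience for inspection.
"""

import argparse
from pathlib import Path

from cooccupy import genome_io, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/dataset"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = synthetic.SimulationConfig(
        seed=args.seed,
        factors=(
            ("A", synthetic.FactorSpec(n_peaks=2000)),
            ("B", synthetic.FactorSpec(n_peaks=2000)),
            ("C", synthetic.FactorSpec(n_peaks=1000)),
        ),
        cobinding=(("A", "B", 0.5),),
    )
    genome = synthetic.make_genome(cfg)
    genome_io.write_genome_layout(genome, args.outdir / "genome.tsv")
    peaks = synthetic.simulate_factor_peaks(cfg, genome)
    for name, iset in peaks.items():
        genome_io.write_intervals(iset, args.outdir / f"peaks_{name}.narrowPeak", "narrowPeak")
        print(f"factor {name}: {len(iset)} peaks, {iset.total_bp} bp")
    genome_io.write_table(
        synthetic.simulate_spectral_counts(cfg), args.outdir / "spectral_counts.tsv"
    )
    genome_io.write_table(
        synthetic.simulate_4c_counts(cfg), args.outdir / "fourc_counts.tsv"
    )
    print(f"dataset written to {args.outdir}")


if __name__ == "__main__":
    main()
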