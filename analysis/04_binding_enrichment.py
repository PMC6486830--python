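#!/usr/bin/env python
"""Pairwise binding enrichment, clustering, and chromatin-state enrichment.

Builds the factor-by-factor enrichment matrix (A/B planted at 50% shared
peaks, C independent), orders it by complete-linkage clustering with optimal
leaf ordering, and measures factor-A enrichment across a simulated
segmentation with a 10x planted enhancer-state excess.
"""

import argparse
from pathlib import Path

from cooccupy import enrichment, synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
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
    peaks = synthetic.simulate_factor_peaks(cfg, genome)

    mat = enrichment.enrichment_matrix(peaks)
    order, _z, newick = enrichment.cluster_olo(mat)
    mat.to_dataframe().reset_index(names="factor").to_csv(
        args.outdir / "pairwise_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (args.outdir / "dendrogram.newick").write_text(newick + "\n")
    print("pairwise enrichment matrix:")
    print(mat.to_dataframe().round(3).to_string())
    print("leaf order:", " -> ".join(mat.labels[i] for i in order))

    seg = synthetic.simulate_segmentation(cfg, genome, peaks["A"])
    enr = enrichment.state_enrichment(peaks["A"], seg)
    enr.rename_axis("state").reset_index(name="enrichment").to_csv(
        args.outdir / "state_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    print("state enrichment (planted 10x in Enhancer):")
    print(enr.round(3).to_string())


if __name__ == "__main__":
    main()
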