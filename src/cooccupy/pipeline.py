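"""End-to-end orchestration of the synthetic reproduction recipe.

``run_pipeline`` wires every stage into a DAG of pure file transformations:
simulate -> replicate consistency -> differential occupancy -> summit
densities/metaplot -> pairwise-enrichment matrix with clustering -> state
enrichment -> co-binding clusters -> gene association -> interactor calling
-> 4C filtering.  Outputs are plain TSV/BED; the run configuration and a
SHA-256 manifest are embedded in the output directory so identical
(seed, config) runs are byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    cobinding,
    enrichment,
    gene_association,
    genome_io,
    interactome,
    occupancy,
    signal_density,
    synthetic,
)

__all__ = ["RunConfig", "run_pipeline"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Seed, output directory and stage parameters for a full synthetic run."""

    seed: int = 0
    outdir: str = "results/pipeline"
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    # co-binding design of the three simulated factors
    shared_fraction_ab: float = 0.5
    n_peaks: int = 2000
    n_independent_peaks: int = 1000
    # differential occupancy
    frac_reduced: float = 0.25
    planted_fold: float = 4.0
    fold_threshold: float = 2.0
    read_extension: int = 50
    pseudocount: float = 1.0
    # signal density
    flank: int = 2000
    bin_size: int = 100
    n_density_features: int = 300
    # co-binding clustering
    window: int = 500
    k: int = 3
    n_starts: int = 10
    # gene association
    tss_window: int = 20_000
    n_gene_regions: int = 60


def _sim_config(cfg: RunConfig) -> synthetic.SimulationConfig:
    return synthetic.SimulationConfig(
        seed=cfg.seed,
        genome=synthetic.GenomeSpec(tuple(cfg.chrom_lengths)),
        factors=(
            ("A", synthetic.FactorSpec(n_peaks=cfg.n_peaks)),
            ("B", synthetic.FactorSpec(n_peaks=cfg.n_peaks)),
            ("C", synthetic.FactorSpec(n_peaks=cfg.n_independent_peaks)),
        ),
        cobinding=(("A", "B", cfg.shared_fraction_ab),),
        genes=synthetic.GeneSpec(window=cfg.tss_window),
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on synthetic data; returns the output directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(config)
    genome = synthetic.make_genome(sim)
    genome_io.write_genome_layout(genome, out / "genome.tsv")

    # --- peaks and replicate consistency -----------------------------------
    peak_sets = synthetic.simulate_factor_peaks(sim, genome)
    for name, iset in peak_sets.items():
        genome_io.write_intervals(iset, out / f"peaks_{name}.narrowPeak", "narrowPeak")
    a = peak_sets["A"]
    # a jittered second replicate of factor A: shift each peak by <= 1/4 width
    rng = np.random.default_rng([sim.seed, 101])
    rep2_ivs = []
    for iv in a:
        shift = int(rng.integers(-iv.width // 4, iv.width // 4 + 1))
        s = max(0, iv.start + shift)
        e = min(genome.length_of(iv.chrom), iv.end + shift)
        rep2_ivs.append(genome_io.GenomicInterval(iv.chrom, s, e))
    rep2 = genome_io.IntervalSet(genome, rep2_ivs, label="A_rep2")
    consistent = occupancy.replicate_consistent(a, rep2)
    genome_io.write_intervals(consistent, out / "peaks_A_consistent.bed", "bed")

    # --- differential occupancy --------------------------------------------
    n_a = len(a)
    n_reduced = int(round(config.frac_reduced * n_a))
    folds_wt = np.ones(n_a)
    folds_wt[:n_reduced] = config.planted_fold
    tags_wt = synthetic.simulate_tags(sim, genome, a, condition="WT", folds=folds_wt)
    tags_ko = synthetic.simulate_tags(sim, genome, a, condition="KO", folds=1.0)
    union = occupancy.merge_intervals(a)
    diff = occupancy.call_differential(
        union,
        tags_wt,
        tags_ko,
        read_extension=config.read_extension,
        fold_threshold=config.fold_threshold,
        pseudocount=config.pseudocount,
    )
    _write_tsv(diff, out / "differential_occupancy.tsv")

    # --- summit-centered densities ------------------------------------------
    subset = genome_io.IntervalSet(
        genome, list(a)[: config.n_density_features], label="A_subset"
    )
    bins = signal_density.make_bins(subset, flank=config.flank, bin_size=config.bin_size)
    fg = signal_density.binned_rpkm(tags_wt, bins, read_extension=config.read_extension)
    input_tags = synthetic.simulate_tags(sim, genome, a, condition="input", folds=0.0)
    bg = signal_density.binned_rpkm(input_tags, bins, read_extension=config.read_extension)
    norm = signal_density.input_normalize(fg, bg)
    profile = signal_density.metaplot(norm)
    mat_df = pd.DataFrame(norm.values, columns=[f"bin{j}" for j in range(norm.values.shape[1])])
    mat_df.insert(0, "feature_id", norm.feature_ids)
    _write_tsv(mat_df, out / "density_matrix.tsv")
    _write_tsv(
        pd.DataFrame({"bin_center": norm.bin_centers, "mean_log2_ratio": profile}),
        out / "metaplot.tsv",
    )

    # --- pairwise enrichment + clustering -----------------------------------
    mat = enrichment.enrichment_matrix(peak_sets)
    order, _Z, newick = enrichment.cluster_olo(mat)
    _write_tsv(mat.to_dataframe().reset_index(names="factor"), out / "enrichment_matrix.tsv")
    (out / "dendrogram.newick").write_text(newick + "\n")
    (out / "leaf_order.txt").write_text(
        "\n".join(mat.labels[i] for i in order) + "\n"
    )

    # --- state enrichment ----------------------------------------------------
    seg = synthetic.simulate_segmentation(sim, genome, a)
    state_enr = enrichment.state_enrichment(a, seg)
    _write_tsv(
        state_enr.rename_axis("state").reset_index(name="enrichment"),
        out / "state_enrichment.tsv",
    )

    # --- co-binding clusters -------------------------------------------------
    bmat = cobinding.binarize(peak_sets, window=config.window)
    assign, cost = cobinding.kmeans_hartigan_wong(
        bmat, k=config.k, seed=sim.seed, n_starts=config.n_starts
    )
    summary = cobinding.cluster_summary(assign, bmat)
    _write_tsv(summary, out / "cobinding_clusters.tsv")
    assign_df = bmat.to_dataframe()
    assign_df["cluster"] = assign
    _write_tsv(assign_df, out / "cobinding_assignment.tsv")

    # --- gene association ----------------------------------------------------
    regions = genome_io.IntervalSet(
        genome, list(a)[: config.n_gene_regions], label="A_sparse"
    )
    genes = synthetic.simulate_expression_genes(sim, genome, regions)
    gtable = gene_association.assign_peaks_to_genes(regions, genes, config.tss_window)
    chisq = gene_association.de_binding_chisq(gtable)
    folds = gene_association.fold_enrichment_near_de(regions, genes, config.tss_window)
    _write_tsv(gtable, out / "gene_binding.tsv")
    stats_json = {
        "chi_square": chisq["statistic"],
        "p_value": chisq["p_value"],
        "n_de": chisq["n_de"],
        "n_de_bound": chisq["n_de_bound"],
        **folds,
    }
    (out / "gene_association.json").write_text(json.dumps(stats_json, indent=2) + "\n")

    # --- interactome ---------------------------------------------------------
    spectral = synthetic.simulate_spectral_counts(sim)
    called = interactome.call_interactors(interactome.remove_contaminants(spectral))
    _write_tsv(called, out / "interactors.tsv")

    # --- 4C filter -----------------------------------------------------------
    fourc = synthetic.simulate_4c_counts(sim)
    filtered = occupancy.filter_4c(fourc)
    _write_tsv(filtered, out / "fourc_filtered.tsv")

    # --- provenance ----------------------------------------------------------
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    # manifest covers the data outputs; run_config.json embeds the output
    # path itself, so it is provenance, not data
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name in ("manifest.json", "run_config.json") or not p.is_file():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
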