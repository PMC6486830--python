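"""Generator determinism, config validation, and planted-parameter recovery."""

import numpy as np
import pytest

from cooccupy import occupancy, synthetic
from cooccupy.synthetic import (
    ApmsSpec,
    FactorSpec,
    FourCSpec,
    GeneSpec,
    GenomeSpec,
    SegmentationSpec,
    SimulationConfig,
    make_genome,
    simulate_4c_counts,
    simulate_expression_genes,
    simulate_factor_peaks,
    simulate_segmentation,
    simulate_spectral_counts,
    simulate_tags,
)


SMALL = SimulationConfig(
    seed=1,
    genome=GenomeSpec((1_000_000, 1_000_000)),
    factors=(("A", FactorSpec(n_peaks=300)), ("B", FactorSpec(n_peaks=300))),
)


class TestConfigValidation:
    def test_genome_size_is_sum(self):
        g = make_genome(SimulationConfig(genome=GenomeSpec((500_000, 500_000))))
        assert g.G == 1_000_000

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec((500_000, 0))

    def test_infeasible_cobinding_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            SimulationConfig(
                factors=(("A", FactorSpec()), ("B", FactorSpec()), ("C", FactorSpec())),
                cobinding=(("A", "B", 0.7), ("A", "C", 0.6)),
            )

    def test_state_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SegmentationSpec(proportions=(("a", 0.5), ("b", 0.4)), enriched_state="a")

    def test_infeasible_state_enrichment_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SegmentationSpec(
                proportions=(("a", 0.5), ("b", 0.5)), enriched_state="a", enrichment=3.0
            )

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            GeneSpec(n_genes=0)

    def test_zero_fragments_rejected(self):
        with pytest.raises(ValueError):
            FourCSpec(n_fragments=0)

    def test_interactor_construction_guarantees_3x(self):
        with pytest.raises(ValueError, match="3x"):
            ApmsSpec(bait_mean=2.0, control_mean_max=1.0)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        g = make_genome(SMALL)
        p1 = simulate_factor_peaks(SMALL, g)
        p2 = simulate_factor_peaks(SMALL, g)
        for name in p1:
            assert [(i.chrom, i.start, i.end) for i in p1[name]] == [
                (i.chrom, i.start, i.end) for i in p2[name]
            ]
        t1 = simulate_tags(SMALL, g, p1["A"], "WT")
        t2 = simulate_tags(SMALL, g, p2["A"], "WT")
        assert np.array_equal(t1.positions, t2.positions)
        assert simulate_spectral_counts(SMALL).equals(simulate_spectral_counts(SMALL))
        assert simulate_4c_counts(SMALL).equals(simulate_4c_counts(SMALL))

    def test_different_seed_different_realization(self):
        other = SimulationConfig(
            seed=2, genome=SMALL.genome, factors=SMALL.factors
        )
        g = make_genome(SMALL)
        p1 = simulate_factor_peaks(SMALL, g)["A"]
        p2 = simulate_factor_peaks(other, g)["A"]
        assert [(i.start) for i in p1] != [(i.start) for i in p2]

    def test_condition_label_changes_tag_stream(self):
        g = make_genome(SMALL)
        peaks = simulate_factor_peaks(SMALL, g)["A"]
        t_wt = simulate_tags(SMALL, g, peaks, "WT")
        t_ko = simulate_tags(SMALL, g, peaks, "KO")
        assert len(t_wt) != len(t_ko) or not np.array_equal(
            t_wt.positions, t_ko.positions
        )


class TestPeaks:
    def test_peaks_nonoverlapping_within_factor(self):
        g = make_genome(SMALL)
        for iset in simulate_factor_peaks(SMALL, g).values():
            merged = occupancy.merge_intervals(iset)
            assert len(merged) == len(iset)

    def test_target_shared_fraction_realized(self):
        cfg = SimulationConfig(
            seed=4,
            factors=(("A", FactorSpec(n_peaks=2000)), ("B", FactorSpec(n_peaks=2000))),
            cobinding=(("A", "B", 0.5),),
        )
        g = make_genome(cfg)
        ps = simulate_factor_peaks(cfg, g)
        pairs = occupancy.overlap_pairs(ps["A"], ps["B"])
        frac = len({(p.chrom, p.start) for p, _q, _o in pairs}) / 2000
        assert 0.45 <= frac <= 0.55

    def test_full_sharing_means_every_peak_overlaps(self):
        cfg = SimulationConfig(
            seed=5,
            factors=(("A", FactorSpec(n_peaks=200)), ("B", FactorSpec(n_peaks=200))),
            cobinding=(("A", "B", 1.0),),
        )
        g = make_genome(cfg)
        ps = simulate_factor_peaks(cfg, g)
        kept = occupancy.replicate_consistent(ps["A"], ps["B"])
        assert len(kept) == len(ps["A"])


class TestTags:
    def test_equal_folds_give_equal_mean_counts(self):
        g = make_genome(SMALL)
        peaks = simulate_factor_peaks(SMALL, g)["A"]
        t1 = simulate_tags(SMALL, g, peaks, "c1", folds=1.0)
        t2 = simulate_tags(SMALL, g, peaks, "c2", folds=1.0)
        c1 = occupancy.count_tags(t1, peaks)
        c2 = occupancy.count_tags(t2, peaks)
        assert abs(c1.mean() - c2.mean()) < 3 * np.sqrt(
            c1.var() / len(peaks) + c2.var() / len(peaks)
        )

    def test_planted_fold_recovered_in_peak_signal_ratio(self):
        g = make_genome(SMALL)
        peaks = simulate_factor_peaks(SMALL, g)["A"]
        n = len(peaks)
        folds = np.ones(n)
        folds[:100] = 4.0
        wt = simulate_tags(SMALL, g, peaks, "WT", folds=folds)
        ko = simulate_tags(SMALL, g, peaks, "KO", folds=1.0)
        ext = 50
        cw = occupancy.count_tags(wt, peaks, ext)
        ck = occupancy.count_tags(ko, peaks, ext)
        widths = np.array([iv.width for iv in peaks])
        # expected background reads whose extended footprint reaches the peak
        bg = SMALL.tags.background_rate * (widths + 2 * ext - 1)
        ratio = (cw[:100] - bg[:100]).mean() / (ck[:100] - bg[:100]).mean()
        assert 3.7 < ratio < 4.3

    def test_empty_model_rejected(self):
        cfg = SimulationConfig(
            seed=1,
            genome=GenomeSpec((100_000,)),
            factors=(("A", FactorSpec(n_peaks=5)),),
            tags=synthetic.TagSpec(background_rate=0.0, peak_lambda=0.0),
        )
        g = make_genome(cfg)
        peaks = simulate_factor_peaks(cfg, g)["A"]
        with pytest.raises(ValueError):
            simulate_tags(cfg, g, peaks, "x")


class TestSegmentation:
    def test_state_fractions_match_proportions(self):
        cfg = SimulationConfig(
            seed=3,
            segmentation=SegmentationSpec(
                proportions=(("s1", 0.1), ("s2", 0.3), ("s3", 0.6)),
                enriched_state="s1",
                enrichment=5.0,
            ),
        )
        g = make_genome(cfg)
        peaks = simulate_factor_peaks(cfg, g)["A"]
        seg = simulate_segmentation(cfg, g, peaks)
        bp = seg.state_bp()
        for state, target in (("s1", 0.1), ("s2", 0.3), ("s3", 0.6)):
            assert abs(bp[state] / g.G - target) < 0.02

    def test_single_state_gives_unit_enrichment(self):
        from cooccupy.enrichment import state_enrichment

        cfg = SimulationConfig(
            seed=3,
            genome=GenomeSpec((1_000_000,)),
            factors=(("A", FactorSpec(n_peaks=100)),),
            segmentation=SegmentationSpec(
                proportions=(("only", 1.0),), enriched_state="only", enrichment=1.0
            ),
        )
        g = make_genome(cfg)
        peaks = simulate_factor_peaks(cfg, g)["A"]
        seg = simulate_segmentation(cfg, g, peaks)
        assert state_enrichment(peaks, seg)["only"] == pytest.approx(1.0)


class TestGenes:
    def test_bound_probabilities_follow_config(self):
        from cooccupy.gene_association import assign_peaks_to_genes
        from cooccupy.genome_io import IntervalSet

        cfg = SimulationConfig(
            seed=6,
            genes=GeneSpec(n_genes=2000, p_bound_up=0.8, p_bound_unchanged=0.2),
        )
        g = make_genome(cfg)
        peaks = simulate_factor_peaks(cfg, g)["A"]
        regions = IntervalSet(g, list(peaks)[:60], label="sparse")
        genes = simulate_expression_genes(cfg, g, regions)
        table = assign_peaks_to_genes(regions, genes, cfg.genes.window)
        up = table[table["de_status"] == "up"]["bound"].mean()
        unch = table[table["de_status"] == "unchanged"]["bound"].mean()
        assert up == pytest.approx(0.8, abs=0.1)
        assert unch == pytest.approx(0.2, abs=0.1)


class TestApmsAnd4C:
    def test_interactor_construction(self):
        t = simulate_spectral_counts(SimulationConfig(seed=9))
        inter = t[t["is_true_interactor"]]
        non = t[~t["is_true_interactor"] & ~t["is_contaminant"]]
        assert (inter["bait_sequences"].mean()
                > 3 * inter["control_sequences"].mean())
        assert abs(non["bait_sequences"].mean() - non["control_sequences"].mean()) < 2.0
        assert t["is_contaminant"].sum() == 10

    def test_4c_contact_and_background_separation(self):
        t = simulate_4c_counts(SimulationConfig(seed=9))
        from cooccupy.occupancy import filter_4c

        out = filter_4c(t)
        contacts = out[out["is_true_contact"]]
        background = out[~out["is_true_contact"]]
        assert contacts["retained"].all()
        assert not background["retained"].any()
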