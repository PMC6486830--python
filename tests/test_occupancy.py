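"""Interval algebra, tag counting, differential calls, 4C filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cooccupy.genome_io import GenomeLayout, GenomicInterval, IntervalSet
from cooccupy.occupancy import (
    call_differential,
    count_tags,
    filter_4c,
    merge_intervals,
    normalize_by_depth,
    overlap_pairs,
    replicate_consistent,
    shared_bp,
    union_peaks,
)

from conftest import make_iset, make_tags, random_intervals


# -- merge -------------------------------------------------------------------


class TestMerge:
    def test_overlapping_intervals_merge(self, toy_genome):
        s = make_iset(toy_genome, [("chr1", 0, 100), ("chr1", 50, 150)])
        out = merge_intervals(s)
        assert [(i.start, i.end) for i in out] == [(0, 150)]

    def test_touching_intervals_do_not_merge(self, toy_genome):
        s = make_iset(toy_genome, [("chr1", 0, 100), ("chr1", 100, 200)])
        assert len(merge_intervals(s)) == 2

    def test_idempotent_on_disjoint(self, toy_genome):
        s = make_iset(toy_genome, [("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 5, 9)])
        out = merge_intervals(s)
        assert [(i.chrom, i.start, i.end) for i in out] == [
            (i.chrom, i.start, i.end) for i in s
        ]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=1, max_size=30))
    def test_merge_conserves_coverage_and_is_idempotent(self, spans):
        g = GenomeLayout(("chr1",), (1000,))
        s = make_iset(g, [("chr1", a, a + w) for a, w in spans])
        merged = merge_intervals(s)
        # bp coverage conserved
        cov = np.zeros(1000, dtype=bool)
        for a, w in spans:
            cov[a : a + w] = True
        assert merged.total_bp == int(cov.sum())
        # pairwise non-overlapping and idempotent
        ivs = merged.intervals
        assert all(x.end <= y.start or x.chrom != y.chrom for x, y in zip(ivs, ivs[1:]))
        again = merge_intervals(merged)
        assert [(i.start, i.end) for i in again] == [(i.start, i.end) for i in ivs]


# -- overlap pairs -----------------------------------------------------------


def brute_force_pairs(a, b):
    out = []
    for iv_a in a:
        for iv_b in b:
            if iv_a.chrom != iv_b.chrom:
                continue
            ov = min(iv_a.end, iv_b.end) - max(iv_a.start, iv_b.start)
            if ov > 0:
                out.append((iv_a.chrom, iv_a.start, iv_b.start, ov))
    return sorted(out)


class TestOverlapPairs:
    def test_single_bp_overlap_counts(self, toy_genome):
        a = make_iset(toy_genome, [("chr1", 0, 100)])
        b = make_iset(toy_genome, [("chr1", 99, 200)])
        pairs = overlap_pairs(a, b)
        assert len(pairs) == 1 and pairs[0][2] == 1

    def test_touching_is_not_overlap(self, toy_genome):
        a = make_iset(toy_genome, [("chr1", 0, 100)])
        b = make_iset(toy_genome, [("chr1", 100, 200)])
        assert overlap_pairs(a, b) == []

    def test_genome_mismatch_rejected(self, toy_genome):
        other = GenomeLayout(("chr1",), (1000,))
        with pytest.raises(ValueError, match="different genomes"):
            overlap_pairs(make_iset(toy_genome, []), make_iset(other, []))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sets(self, toy_genome, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, toy_genome, 200)
        b = random_intervals(rng, toy_genome, 200)
        fast = sorted(
            (pa.chrom, pa.start, pb.start, ov) for pa, pb, ov in overlap_pairs(a, b)
        )
        assert fast == brute_force_pairs(a, b)


# -- replicate consistency / union ------------------------------------------


class TestReplicateConsistency:
    def test_one_bp_overlap_kept_none_dropped(self, toy_genome):
        r1 = make_iset(toy_genome, [("chr1", 0, 100), ("chr1", 500, 600)])
        r2 = make_iset(toy_genome, [("chr1", 99, 150)])
        out = replicate_consistent(r1, r2)
        assert [(i.start, i.end) for i in out] == [(0, 100)]

    def test_identical_replicates_keep_everything(self, toy_genome):
        r1 = make_iset(toy_genome, [("chr1", 0, 100), ("chr2", 5, 50)])
        out = replicate_consistent(r1, r1)
        assert len(out) == len(r1)


class TestUnionPeaks:
    def test_union_merges_across_conditions(self, toy_genome):
        a = make_iset(toy_genome, [("chr1", 0, 100)])
        b = make_iset(toy_genome, [("chr1", 50, 150)])
        out = union_peaks(a, b)
        assert [(i.start, i.end) for i in out] == [(0, 150)]

    def test_union_is_commutative_on_random_sets(self, toy_genome):
        rng = np.random.default_rng(0)
        a = random_intervals(rng, toy_genome, 100)
        b = random_intervals(rng, toy_genome, 100)
        ab = [(i.chrom, i.start, i.end) for i in union_peaks(a, b)]
        ba = [(i.chrom, i.start, i.end) for i in union_peaks(b, a)]
        assert ab == ba

    def test_union_with_empty_is_merge(self, toy_genome):
        b = make_iset(toy_genome, [("chr1", 0, 100), ("chr1", 50, 120)])
        out = union_peaks(make_iset(toy_genome, []), b)
        assert [(i.start, i.end) for i in out] == [(0, 120)]


# -- tag counting ------------------------------------------------------------


def brute_force_counts(tags, intervals, ext):
    counts = np.zeros(len(intervals), dtype=int)
    for chrom, pos, strand in zip(tags.chroms, tags.positions, tags.strands):
        if strand == "+":
            fs, fe = pos, pos + ext
        else:
            fs, fe = pos - ext + 1, pos + 1
        for i, iv in enumerate(intervals):
            if iv.chrom == chrom and fs < iv.end and fe > iv.start:
                counts[i] += 1
    return counts


class TestCountTags:
    def test_plus_strand_extension_reaches_interval(self, toy_genome):
        tags = make_tags(toy_genome, [("chr1", 90, "+")])
        iv = make_iset(toy_genome, [("chr1", 100, 200)])
        assert count_tags(tags, iv, read_extension=50).tolist() == [1]

    def test_minus_strand_extends_leftward(self, toy_genome):
        tags = make_tags(toy_genome, [("chr1", 99, "-")])
        iv = make_iset(toy_genome, [("chr1", 100, 200)])
        # '-' footprint [50, 100) does not touch [100, 200)
        assert count_tags(tags, iv, read_extension=50).tolist() == [0]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_tags(self, toy_genome, seed):
        rng = np.random.default_rng(seed)
        n = 1000
        chroms = rng.choice(toy_genome.chrom_names, size=n)
        pos = np.array(
            [rng.integers(60, toy_genome.lengths[c] - 60) for c in chroms]
        )
        strands = rng.choice(["+", "-"], size=n)
        tags = make_tags(toy_genome, list(zip(chroms, pos, strands)))
        intervals = random_intervals(rng, toy_genome, 50)
        fast = count_tags(tags, intervals, read_extension=50)
        assert fast.tolist() == brute_force_counts(tags, intervals, 50).tolist()


class TestNormalizeByDepth:
    def test_counts_per_million(self):
        assert normalize_by_depth(np.array([40]), 2_000_000).tolist() == [20.0]
        assert normalize_by_depth(np.array([0]), 10).tolist() == [0.0]

    def test_linear_in_library_size(self):
        raw = np.array([10, 20, 30])
        assert np.allclose(
            normalize_by_depth(raw, 2_000_000), normalize_by_depth(raw, 1_000_000) / 2
        )

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_by_depth(np.array([1]), 0)


# -- differential calls ------------------------------------------------------


class TestCallDifferential:
    @pytest.fixture
    def setup(self, toy_genome):
        union = make_iset(toy_genome, [("chr1", 1000, 1400), ("chr1", 5000, 5400)])
        return union

    def test_fold_rule_and_antisymmetry(self, toy_genome, setup):
        union = setup
        # 40 tags in first peak of A, 10 in B; second peak equal
        tags_a = make_tags(
            toy_genome,
            [("chr1", 1200, "+")] * 40 + [("chr1", 5200, "+")] * 10,
            library_size=1_000_000,
        )
        tags_b = make_tags(
            toy_genome,
            [("chr1", 1200, "+")] * 10 + [("chr1", 5200, "+")] * 10,
            library_size=1_000_000,
        )
        fwd = call_differential(union, tags_a, tags_b, pseudocount=0.0)
        rev = call_differential(union, tags_b, tags_a, pseudocount=0.0)
        assert fwd["call"].tolist() == ["reduced", "unchanged"]
        assert rev["call"].tolist() == ["gained", "unchanged"]
        assert fwd.loc[0, "fold"] == pytest.approx(4.0)

    def test_equal_counts_unchanged_for_any_threshold(self, toy_genome, setup):
        tags = make_tags(toy_genome, [("chr1", 1100, "+")] * 5 + [("chr1", 5100, "+")] * 5)
        for thr in (1.5, 2.0, 10.0):
            out = call_differential(setup, tags, tags, fold_threshold=thr)
            assert (out["call"] == "unchanged").all()

    def test_threshold_must_exceed_one(self, toy_genome, setup):
        tags = make_tags(toy_genome, [("chr1", 1100, "+")])
        with pytest.raises(ValueError):
            call_differential(setup, tags, tags, fold_threshold=1.0)


# -- 4C filter ---------------------------------------------------------------


class TestFilter4C:
    @pytest.mark.parametrize(
        "rep1,rep2,kept",
        [(20, 15, False), (16, 16, True), (0, 100, False), (100, 100, True)],
    )
    def test_both_replicates_must_reach_threshold(self, rep1, rep2, kept):
        df = pd.DataFrame({"fragment_id": ["f1"], "rep1": [rep1], "rep2": [rep2]})
        assert filter_4c(df)["retained"].tolist() == [kept]

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"fragment_id": ["f1"], "rep1": [-1], "rep2": [5]})
        with pytest.raises(ValueError, match="negative"):
            filter_4c(df)
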