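import numpy as np
import pytest

from cooccupy.genome_io import GenomeLayout, GenomicInterval, IntervalSet, TagCollection


@pytest.fixture
def toy_genome():
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


def make_iset(genome, triples, label=""):
    """Build an IntervalSet from (chrom, start, end[, summit]) tuples."""
    ivs = []
    for t in triples:
        chrom, start, end = t[:3]
        summit = t[3] if len(t) > 3 else None
        ivs.append(GenomicInterval(chrom, start, end, summit=summit))
    return IntervalSet(genome, ivs, label=label)


def make_tags(genome, triples, library_size=None):
    """Build a TagCollection from (chrom, pos, strand) tuples."""
    return TagCollection.from_lists(genome, triples, library_size)


def random_intervals(rng, genome, n, max_width=500):
    triples = []
    for _ in range(n):
        ci = rng.integers(len(genome.chrom_names))
        chrom = genome.chrom_names[ci]
        L = genome.chrom_lengths[ci]
        w = int(rng.integers(1, max_width))
        s = int(rng.integers(0, L - w))
        triples.append((chrom, s, s + w))
    return make_iset(genome, triples)
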