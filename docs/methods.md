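# Methods

This note documents the models, conventions, and numerical choices behind
`cooccupy`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate and counting conventions

All intervals are 0-based, half-open (BED-native); widths are `end − start`.
Two intervals *overlap* iff they share ≥1 bp, so touching half-open
intervals (`[0,100)`, `[100,200)`) do not overlap. Replicate-consistent
peak sets keep the first replicate's coordinates (the choice of surviving
coordinates is conventional; the filter itself is symmetric in what it
tests). Aligned reads are reduced to strand-aware 5′ positions plus a
library size; a tag counts toward an interval iff its directional footprint
— `[p, p+ext)` on `+`, `[p−ext+1, p+1)` on `-`, with `ext` = 50 bp by
default — overlaps the interval by ≥1 bp. Unknown chromosomes are a hard
error everywhere, so assembly mix-ups fail loudly instead of silently
dropping data.

## Differential occupancy

Counts on the WT/KO union peak set are scaled to counts per million
(the specific depth-normalization scale cancels in the fold ratio), then

    fold = (cpm_A + c) / (cpm_B + c),  c = 1.0 by default,

with a site called *reduced* when `fold ≥ t`, *gained* when `1/fold ≥ t`
(t = 2 by default). The pseudocount guards zero-count peaks and is
flag-exposed; there is deliberately no dispersion model or p-value — the
method is a pure fold rule, and the call is anti-symmetric under swapping
conditions. Tag counting on union peaks applies the 50 bp directional
extension by default (extension is unambiguously specified only for binned
densities; both modes are supported via `read_extension`).

## Pairwise binding enrichment

`min((100 + |A∩B|) / (100 + |A|·|B|/G), 500)` on *merged* peak sets —
merging is required (and applied defensively) because |A| and |B| are
"total bp occupied", which double-counts overlapping raw peaks. The 100 bp
pseudocount appears in both numerator and denominator; the cap at 500 binds
only for very large self-enrichments on large genomes. G defaults to the
genome layout's total size rather than a hard-coded constant.

For the factor-by-factor matrix, rows are clustered with complete linkage
on `distance = max(matrix) − enrichment`. The distance is a fixed,
documented choice — any monotone-decreasing transform of enrichment would
order similarly, but fixing one makes outputs reproducible. Leaf order is
the exact optimum of the sum of adjacent-leaf distances over all orders
consistent with the tree, computed by the Bar-Joseph dynamic program
implemented in-package (each subtree tabulates minimal cost per
leftmost/rightmost-leaf pair). SciPy's `optimal_leaf_ordering` was found
to return measurably suboptimal orders on random instances (verified
against exhaustive enumeration of all 2^(n−1) consistent orders), so the
DP is ours and the exhaustive search remains the test oracle for ≤7
leaves. Rows are pre-sorted by label and the final order is canonicalized
(first leaf index < last) so ties and reflections resolve
deterministically.

## Chromatin-state enrichment

For a genome-tiling segmentation, `enrichment(s) = (peak bp in s / peak bp)
/ (state bp / G)`. States with zero genome bp are excluded. Conservation
holds exactly: the state-fraction-weighted mean of enrichments is 1,
because every peak bp lies in exactly one state.

## Summit-centered densities

Features align at their summit; the interval midpoint is used when no
summit is recorded (narrowPeak column 10 = −1). ±2 kb flanks are tiled in
100 bp bins; per bin, `RPKM = count / (bin_kb × library/10⁶)`. Input
normalization is `log2(RPKM_fg + c) − log2(RPKM_input + c)` with c = 1
RPKM, which keeps values finite at empty bins and gives exactly zero when
foreground equals input. Bins truncated at chromosome edges are flagged and
excluded from metaplot means (zero-filling would fabricate depletion at the
boundary). Heatmap row order is descending central-bin signal with ties
broken by feature id — a stated, reproducible key.

## Co-binding clusters

The genome is tiled into 500 bp windows (trailing partial windows
included); a window scores 1 for a factor iff any peak overlaps it by ≥1
bp. Windows bound by no factor are dropped before clustering: the object
of interest is the combinatorial pattern of binding events, and the empty
genome would otherwise dominate every distance. Clustering is k-means with
Hartigan-style single-point moves (the update rule behind R's default
`kmeans`): after nearest-center initialization, point i moves from cluster
c₁ (size n₁) to c₂ when

    n₂/(n₂+1)·d(i,c₂)² < n₁/(n₁−1)·d(i,c₁)²,

which strictly lowers the within-cluster sum of squares; sweeps repeat to
convergence, empty clusters are re-seeded from the farthest point, and the
best of `n_starts` random starts (by WCSS) wins. The implementation is
in-package because no installed Python library provides the Hartigan–Wong
update; it is cross-checked against scikit-learn's Lloyd k-means (WCSS
within a few percent on noisy data, identical partitions on separated
data). k is a user parameter; the reproduction recipe uses k matching the
number of planted patterns, and k=7 is the CLI default for real
three-sample data where stage-specific/constitutive splits are expected.

## Gene association

A gene is bound when any peak overlaps the closed window [TSS−w, TSS+w]
(strand ignored; w = 20 kb default, 10 kb for promoter-proximal claims).
The DE×bound association is the Pearson chi-square on the 2×2 table without
continuity correction (Yates' correction available behind a flag); a zero
margin raises rather than returning NaN. Fold enrichment near up-regulated
genes is `P(bound | up) / P(bound | all genes)` (ditto down); the "all
genes" denominator is whatever gene table the caller supplies, which keeps
the formula agnostic about annotated-vs-expressed universes.

## AP-MS interactor calling

After removing flagged external contaminants, a protein is a
high-confidence interactor iff (control = 0 and bait > 0) or bait ≥ 3×
control — computed on sequence (spectral) counts pooled across replicates,
since the rule compares experiments, with exactly 3× passing — and some
replicate identified it with ≥2 high-confidence peptides. The "sequences"
unit is the summed matched-sequence count per experiment arm; a
per-replicate ratio variant is available via the table columns but pooled
totals are the default.

## 4C filtering

A fragment's interaction is retained iff both replicates supply ≥
`min_reads` read pairs (default 16). The FDR calibration behind the
default is not re-derived; the threshold is a parameter.

## Synthetic data: what it emulates

The generator is fully deterministic under (seed, config); per-stage
streams derive from the global seed. Defaults define the benchmark
conditions:

- **Genome**: two 5 Mb chromosomes (20 Mb for the null-enrichment
  benchmark) — small enough for second-scale runs, large enough that
  thousands of peaks stay uncrowded.
- **Peaks**: 2,000 per factor, widths uniform in [150, 400] bp,
  non-overlapping within a factor, summit at the center. Co-binding is
  planted at the peak level: a pair with shared fraction f draws that
  fraction of common centers, so shared peaks always overlap; unshared
  peaks place independently, leaving realized sharing ≈ f plus a small
  chance excess.
- **Tags**: Poisson everywhere (ChIP counts are discrete count data well
  described by Poisson/negative-binomial noise, and Poisson makes every
  operating point analytically checkable). Background 0.075 tags/bp ≈ 30
  expected background reads per 400 bp peak; each peak adds
  Poisson(120 × fold) reads placed as a clipped normal (σ = width/4) around
  the summit, so summit-centered profiles peak centrally. Planted
  reductions use fold 4 vs 1.
- **Segmentation**: four states (Enhancer 5%, Promoter 5%, Transcribed
  30%, Heterochromatin 60%) with a 10× planted peak enrichment in the
  enhancer state. Peak segments take the enriched state with probability
  e·p (fixed composition, randomly permuted across peaks); gap segments
  have exponential lengths (mean 20 kb) with states assigned by
  largest-deficit allocation so genome fractions track targets within
  ~0.2%. Both allocations trade realism of state run-lengths for low
  variance of the planted quantity.
- **Genes**: 2,000 genes, 10% up / 10% down; P(bound within 20 kb | status)
  = 0.8/0.8/0.15. Bound genes draw a TSS inside a random region's window;
  unbound genes rejection-sample away from all regions, which requires a
  sparse region set (the drivers use 60 regions on 10 Mb).
- **AP-MS**: 500 proteins, 50 true interactors, 10 contaminants, 3
  replicates. Means are per replicate (bait 10, control uniform in [0,1]
  for interactors; 5/5 for non-interactors; peptides Poisson(4)); totals
  pool replicates. At these means the caller's recall >0.9 and false-call
  rate <0.05 follow from Poisson tails.
- **4C**: 2,000 fragments, 100 true contacts at mean 40 reads/replicate,
  background mean 2. P(retain contact) = (1 − F_Pois(15; 40))² > 0.99;
  P(retain background) < 10⁻⁶.

What passing these benchmarks does **not** show: robustness to real-data
features the generator omits — mappability and GC bias, fragment-length
structure, copy-number variation, peak-width/summit miscalling, correlated
replicates, overdispersion beyond Poisson, and annotation errors. The
benchmarks certify the *statistics* (formulas, filters, clustering, and
their operating points), not an end-to-end ChIP-seq caller.

## Problem sizes and determinism

The test suite and acceptance script run the benchmarks at 300–6,000 peaks,
2,000 genes/fragments, and 500 proteins — sizes chosen so each planted
quantity is estimated well inside its tolerance while whole runs take
seconds. The end-to-end recipe writes plain TSV/BED with fixed float
formatting and a SHA-256 manifest; identical (seed, config) runs are
byte-identical (the run-config provenance file embeds the output path and
is excluded from the manifest).
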