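"""Synthetic regulatory-genomics data with planted, recoverable structure.

Every downstream stage of the pipeline is exercised on data generated here:
multi-factor peak sets with controlled pairwise co-binding, Poisson ChIP
tags with planted per-peak fold changes between two conditions, chromatin
segmentations with a planted enhancer-state enrichment, genes whose
differential-expression status is linked to nearby binding, AP-MS
spectral-count tables with planted true interactors, and 4C fragment counts
with planted reproducible contacts.

Generation is fully deterministic under (seed, config); per-stage random
streams are derived from the global seed so stages can be re-run
independently.  The tag model is Poisson throughout: ChIP-seq counts are
discrete count data well described by Poisson/negative-binomial noise, and
the Poisson choice makes planted fold changes and filter operating points
analytically checkable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeLayout,
    GenomicInterval,
    GeneTable,
    IntervalSet,
    Segmentation,
    TagCollection,
)

__all__ = [
    "GenomeSpec",
    "FactorSpec",
    "TagSpec",
    "SegmentationSpec",
    "GeneSpec",
    "ApmsSpec",
    "FourCSpec",
    "SimulationConfig",
    "make_genome",
    "simulate_factor_peaks",
    "simulate_tags",
    "simulate_segmentation",
    "simulate_expression_genes",
    "simulate_spectral_counts",
    "simulate_4c_counts",
]

# per-stage stream ids (mixed with the global seed)
_STAGE_PEAKS, _STAGE_TAGS, _STAGE_SEG, _STAGE_GENES, _STAGE_APMS, _STAGE_4C = range(1, 7)


def _stage_rng(seed: int, stage: int, extra: str = "") -> np.random.Generator:
    key = [int(seed), stage]
    if extra:
        key.append(zlib.crc32(extra.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


@dataclass(frozen=True)
class GenomeSpec:
    """Synthetic genome: two 5 Mb chromosomes by default — large enough for
    >=2,000 non-crowded peaks per factor, small enough for second-scale runs."""

    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")


@dataclass(frozen=True)
class FactorSpec:
    """Peak count and width range (uniform draw) for one factor."""

    n_peaks: int = 2000
    width_min: int = 150
    width_max: int = 400

    def __post_init__(self) -> None:
        if self.n_peaks < 1 or self.width_min < 1 or self.width_max < self.width_min:
            raise ValueError("invalid factor spec")


@dataclass(frozen=True)
class TagSpec:
    """Poisson tag model.

    background_rate 0.075 tags/bp puts ~30 expected background reads on a
    400 bp peak; peak_lambda is the mean number of extra reads per peak at
    fold 1.
    """

    background_rate: float = 0.075
    peak_lambda: float = 120.0

    def __post_init__(self) -> None:
        if self.background_rate < 0 or self.peak_lambda < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SegmentationSpec:
    """State genome proportions plus a planted peak enrichment in one state."""

    proportions: tuple[tuple[str, float], ...] = (
        ("Enhancer", 0.05),
        ("Promoter", 0.05),
        ("Transcribed", 0.30),
        ("Heterochromatin", 0.60),
    )
    enriched_state: str = "Enhancer"
    enrichment: float = 10.0
    mean_segment_length: int = 20_000

    def __post_init__(self) -> None:
        total = sum(p for _s, p in self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state proportions must sum to 1, got {total}")
        states = [s for s, _p in self.proportions]
        if self.enriched_state not in states:
            raise ValueError("enriched_state not among states")
        p_enh = dict(self.proportions)[self.enriched_state]
        if self.enrichment * p_enh > 1.0 + 1e-12:
            raise ValueError("planted enrichment infeasible for state proportion")


@dataclass(frozen=True)
class GeneSpec:
    """Genes with DE status linked to nearby binding."""

    n_genes: int = 2000
    frac_up: float = 0.10
    frac_down: float = 0.10
    p_bound_up: float = 0.80
    p_bound_down: float = 0.80
    p_bound_unchanged: float = 0.15
    window: int = 20_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in (
            self.frac_up,
            self.frac_down,
            self.p_bound_up,
            self.p_bound_down,
            self.p_bound_unchanged,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must be <= 1")


@dataclass(frozen=True)
class ApmsSpec:
    """Bait/control AP-MS spectral counts, Poisson per replicate.

    Means are per replicate; experiment totals pool n_replicates draws.
    True interactors have bait mean >= 3x control mean by construction.
    """

    n_proteins: int = 500
    n_interactors: int = 50
    n_contaminants: int = 10
    bait_mean: float = 10.0
    control_mean_max: float = 1.0
    noninteractor_mean: float = 5.0
    peptide_mean: float = 4.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_interactors + self.n_contaminants > self.n_proteins:
            raise ValueError("interactors + contaminants exceed protein count")
        if self.bait_mean < 3.0 * self.control_mean_max:
            raise ValueError("planted interactors must have bait mean >= 3x control")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")


@dataclass(frozen=True)
class FourCSpec:
    """4C per-fragment replicate counts with planted reproducible contacts."""

    n_fragments: int = 2000
    n_contacts: int = 100
    contact_mean: float = 40.0
    background_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if self.n_contacts > self.n_fragments:
            raise ValueError("more contacts than fragments")


@dataclass(frozen=True)
class SimulationConfig:
    """Global seed plus per-stage specifications (defaults are the study
    conditions used throughout the test-suite and analysis drivers)."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    factors: tuple[tuple[str, FactorSpec], ...] = (
        ("A", FactorSpec()),
        ("B", FactorSpec()),
    )
    cobinding: tuple[tuple[str, str, float], ...] = ()  # (factor_a, factor_b, shared fraction)
    tags: TagSpec = field(default_factory=TagSpec)
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    apms: ApmsSpec = field(default_factory=ApmsSpec)
    fourc: FourCSpec = field(default_factory=FourCSpec)

    def __post_init__(self) -> None:
        names = [n for n, _s in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        shared_per_factor: dict[str, float] = {}
        for a, b, f in self.cobinding:
            if a not in names or b not in names or a == b:
                raise ValueError(f"bad co-binding pair ({a}, {b})")
            if not 0.0 <= f <= 1.0:
                raise ValueError("shared fraction must be in [0, 1]")
            shared_per_factor[a] = shared_per_factor.get(a, 0.0) + f
            shared_per_factor[b] = shared_per_factor.get(b, 0.0) + f
        for name, tot in shared_per_factor.items():
            if tot > 1.0 + 1e-12:
                raise ValueError(f"total shared fraction for {name} exceeds 1")


def make_genome(config: SimulationConfig) -> GenomeLayout:
    names = tuple(f"chr{i + 1}" for i in range(len(config.genome.chrom_lengths)))
    return GenomeLayout(names, tuple(config.genome.chrom_lengths))


# ---------------------------------------------------------------------------
# peaks


def _draw_nonoverlapping_centers(
    rng: np.random.Generator,
    genome: GenomeLayout,
    n: int,
    min_sep: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> list[tuple[str, int]]:
    """Centers with pairwise separation >= min_sep, avoiding occupied spans."""
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    taken: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    if occupied:
        for c, spans in occupied.items():
            for s, e in spans:
                taken[c].append((s + e) // 2)
    out: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("cannot place peaks: genome too crowded for config")
        ci = rng.choice(len(probs), p=probs)
        chrom = genome.chrom_names[ci]
        L = genome.chrom_lengths[ci]
        pos = int(rng.integers(min_sep, L - min_sep))
        near = taken[chrom]
        ok = all(abs(pos - q) >= min_sep for q in near) if len(near) < 64 else True
        if len(near) >= 64:
            arr = np.asarray(near)
            ok = bool((np.abs(arr - pos) >= min_sep).all())
        if ok:
            taken[chrom].append(pos)
            out.append((chrom, pos))
    return out


def simulate_factor_peaks(
    config: SimulationConfig, genome: GenomeLayout
) -> dict[str, IntervalSet]:
    """Per-factor peak sets with controlled pairwise co-binding.

    Co-bound peaks of a pair share a common center (so they always overlap);
    remaining peaks are placed independently and uniformly, non-overlapping
    within each factor.  With shared fraction f on a pair of equal-size
    factors, the realized shared-peak fraction is f plus a small chance-
    overlap excess.
    """
    rng = _stage_rng(config.seed, _STAGE_PEAKS)
    specs = dict(config.factors)
    max_width = max(s.width_max for s in specs.values())
    centers: dict[str, list[tuple[str, int]]] = {name: [] for name in specs}

    # shared centers per co-binding pair
    for a, b, f in config.cobinding:
        n_shared = int(round(f * min(specs[a].n_peaks, specs[b].n_peaks)))
        pts = _draw_nonoverlapping_centers(rng, genome, n_shared, 2 * max_width)
        centers[a].extend(pts)
        centers[b].extend(pts)

    sets: dict[str, IntervalSet] = {}
    for name, spec in specs.items():
        n_unique = spec.n_peaks - len(centers[name])
        if n_unique < 0:
            raise ValueError(f"co-binding design allocates >n_peaks for {name}")
        occupied = {c: [] for c in genome.chrom_names}
        for chrom, pos in centers[name]:
            occupied[chrom].append((pos, pos))
        pts = _draw_nonoverlapping_centers(
            rng, genome, n_unique, 2 * max_width, occupied=occupied
        )
        all_centers = centers[name] + pts
        widths = rng.integers(spec.width_min, spec.width_max + 1, size=len(all_centers))
        ivs = []
        for (chrom, pos), w in zip(all_centers, widths):
            start = max(0, pos - int(w) // 2)
            end = min(genome.length_of(chrom), start + int(w))
            ivs.append(
                GenomicInterval(chrom, start, end, summit=(end - start) // 2)
            )
        sets[name] = IntervalSet(genome, ivs, label=name)
    return sets


# ---------------------------------------------------------------------------
# tags


def simulate_tags(
    config: SimulationConfig,
    genome: GenomeLayout,
    peaks: IntervalSet,
    condition: str = "",
    folds: np.ndarray | float = 1.0,
) -> TagCollection:
    """Poisson background tags plus per-peak enrichment tags.

    Background tag counts per chromosome are Poisson(background_rate x L)
    with uniform positions; each peak additionally receives
    Poisson(peak_lambda x fold) tags placed around the summit (clipped
    normal, sd = width/4) so summit-centered profiles peak at the center.
    Strands are uniform; library_size is the realized tag count.
    """
    rng = _stage_rng(config.seed, _STAGE_TAGS, condition)
    folds_arr = np.broadcast_to(np.asarray(folds, dtype=float), (len(peaks),))
    if (folds_arr < 0).any():
        raise ValueError("folds must be >= 0")
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for ci, chrom in enumerate(genome.chrom_names):
        L = genome.chrom_lengths[ci]
        n_bg = rng.poisson(config.tags.background_rate * L)
        if n_bg:
            positions.append(rng.integers(0, L, size=n_bg))
            chroms.append(np.full(n_bg, chrom, dtype=object))
    for iv, fold in zip(peaks, folds_arr):
        n = rng.poisson(config.tags.peak_lambda * fold)
        if n:
            center = iv.summit_pos
            offs = rng.normal(0.0, iv.width / 4.0, size=n)
            pos = np.clip(np.round(center + offs), iv.start, iv.end - 1).astype(np.int64)
            positions.append(pos)
            chroms.append(np.full(n, iv.chrom, dtype=object))
    if not positions:
        raise ValueError("simulated zero tags; raise background_rate or peak_lambda")
    pos_all = np.concatenate(positions)
    chrom_all = np.concatenate(chroms)
    strands = np.where(rng.random(len(pos_all)) < 0.5, "+", "-").astype(object)
    return TagCollection(genome, chrom_all, pos_all, strands, len(pos_all))


# ---------------------------------------------------------------------------
# segmentation


def simulate_segmentation(
    config: SimulationConfig, genome: GenomeLayout, peaks: IntervalSet
) -> Segmentation:
    """Genome-tiling segmentation with a planted peak enrichment.

    Each (merged) peak becomes its own segment whose state is the enriched
    state with probability q = enrichment x p_state, so the realized
    observed/expected enrichment of that state is the planted value.  Gaps
    are tiled with exponential-length segments whose state probabilities are
    adjusted so overall genome proportions still match the spec.
    """
    from .occupancy import merge_intervals

    rng = _stage_rng(config.seed, _STAGE_SEG)
    spec = config.segmentation
    props = dict(spec.proportions)
    states = [s for s, _p in spec.proportions]
    q = spec.enrichment * props[spec.enriched_state]
    other_states = [s for s in states if s != spec.enriched_state]
    other_total = sum(props[s] for s in other_states)
    merged = merge_intervals(peaks)
    peak_bp = merged.total_bp
    G = genome.G

    # expected peak bp per state -> background proportions that compensate
    exp_peak_bp = {spec.enriched_state: q * peak_bp}
    for s in other_states:
        share = props[s] / other_total if other_total > 0 else 0.0
        exp_peak_bp[s] = (1.0 - q) * peak_bp * share
    bg_props = np.array(
        [max(props[s] * G - exp_peak_bp[s], 0.0) for s in states], dtype=float
    )
    bg_props /= bg_props.sum()

    # peak-segment states: fixed composition (largest-remainder rounding of
    # the target distribution), randomly permuted across peaks — keeps the
    # realized enrichment tight around the planted value
    n_peak_segs = sum(len(v) for v in merged.by_chrom().values())
    peak_state_probs = np.array(
        [q if s == spec.enriched_state else (1.0 - q) * props[s] / other_total if other_total > 0 else 0.0 for s in states]
    )
    peak_state_probs /= peak_state_probs.sum()
    base = np.floor(peak_state_probs * n_peak_segs).astype(int)
    remainder = peak_state_probs * n_peak_segs - base
    for si in np.argsort(-remainder)[: n_peak_segs - base.sum()]:
        base[si] += 1
    peak_state_pool = rng.permutation(np.repeat(np.arange(len(states)), base))
    peak_state_iter = iter(peak_state_pool)

    def draw_peak_state() -> str:
        return states[int(next(peak_state_iter))]

    # background states by largest-deficit allocation: segment lengths are
    # random but bp shares track bg_props tightly, so the planted enrichment
    # is recovered with low variance
    bg_assigned = np.zeros(len(states))

    def draw_bg_state(length: int) -> str:
        total_after = bg_assigned.sum() + length
        deficit = bg_props * total_after - bg_assigned
        si = int(np.argmax(deficit))
        bg_assigned[si] += length
        return states[si]

    by_chrom = merged.by_chrom()
    segments: list[tuple[str, int, int, str]] = []
    for ci, chrom in enumerate(genome.chrom_names):
        L = genome.chrom_lengths[ci]
        spans = by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
        cursor = 0
        for s, e in spans:
            if s > cursor:
                segments.extend(_tile_gap(rng, chrom, cursor, int(s), spec, draw_bg_state))
            segments.append((chrom, int(s), int(e), draw_peak_state()))
            cursor = int(e)
        if cursor < L:
            segments.extend(_tile_gap(rng, chrom, cursor, L, spec, draw_bg_state))
    return Segmentation(genome, segments, state_names=states)


def _tile_gap(rng, chrom, start, end, spec, draw_bg_state):
    out = []
    cursor = start
    while cursor < end:
        length = max(200, int(rng.exponential(spec.mean_segment_length)))
        seg_end = min(cursor + length, end)
        out.append((chrom, cursor, seg_end, draw_bg_state(seg_end - cursor)))
        cursor = seg_end
    return out


# ---------------------------------------------------------------------------
# genes


def simulate_expression_genes(
    config: SimulationConfig, genome: GenomeLayout, bound_regions: IntervalSet
) -> GeneTable:
    """Genes with DE status and binding-linked TSS placement.

    P(bound site within +/-window of TSS | status) follows the config.  Bound
    genes get a TSS uniform in the window of a random region; unbound genes
    are rejection-sampled away from every region.  The region set must be
    sparse enough that unbound placement is possible.
    """
    rng = _stage_rng(config.seed, _STAGE_GENES)
    spec = config.genes
    from .occupancy import merge_intervals

    merged = merge_intervals(bound_regions).by_chrom()
    w = spec.window
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    chrom_probs = lengths / lengths.sum()

    regions_flat: list[tuple[str, int, int]] = []
    for chrom, arr in merged.items():
        for s, e in arr:
            regions_flat.append((chrom, int(s), int(e)))
    if not regions_flat:
        raise ValueError("no bound regions supplied")

    def near_region(chrom: str, tss: int) -> bool:
        arr = merged.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        starts, ends = arr[:, 0], arr[:, 1]
        j = np.searchsorted(starts, tss + w + 1, side="left")
        return j > 0 and bool((ends[:j] > tss - w).any())

    p_bound = {
        "up": spec.p_bound_up,
        "down": spec.p_bound_down,
        "unchanged": spec.p_bound_unchanged,
    }
    statuses = rng.choice(
        ["up", "down", "unchanged"],
        size=spec.n_genes,
        p=[spec.frac_up, spec.frac_down, 1.0 - spec.frac_up - spec.frac_down],
    )
    rows = []
    for i, status in enumerate(statuses):
        bound = rng.random() < p_bound[status]
        if bound:
            chrom, s, e = regions_flat[rng.integers(len(regions_flat))]
            L = genome.length_of(chrom)
            lo = max(0, s - w)
            hi = min(L - 1, e - 1 + w)
            tss = int(rng.integers(lo, hi + 1))
        else:
            for _try in range(10_000):
                ci = rng.choice(len(chrom_probs), p=chrom_probs)
                chrom = genome.chrom_names[ci]
                tss = int(rng.integers(0, genome.chrom_lengths[ci]))
                if not near_region(chrom, tss):
                    break
            else:
                raise ValueError(
                    "cannot place unbound gene: regions too dense for window"
                )
        rows.append(
            {
                "gene_id": f"gene{i:05d}",
                "chrom": chrom,
                "tss": tss,
                "strand": "+" if rng.random() < 0.5 else "-",
                "de_status": status,
            }
        )
    return GeneTable(pd.DataFrame(rows), genome=genome)


# ---------------------------------------------------------------------------
# AP-MS


def simulate_spectral_counts(config: SimulationConfig) -> pd.DataFrame:
    """Bait/control spectral-count table with planted true interactors.

    Sequence counts are per-replicate Poisson draws pooled over replicates.
    Ground truth is recorded in ``is_true_interactor``; contaminant rows
    (always removed downstream) carry high counts in both arms.
    """
    rng = _stage_rng(config.seed, _STAGE_APMS)
    spec = config.apms
    n = spec.n_proteins
    reps = spec.n_replicates
    is_inter = np.zeros(n, dtype=bool)
    is_inter[: spec.n_interactors] = True
    is_contam = np.zeros(n, dtype=bool)
    is_contam[spec.n_interactors : spec.n_interactors + spec.n_contaminants] = True

    bait_mean = np.where(is_inter, spec.bait_mean, spec.noninteractor_mean)
    ctrl_mean = np.where(
        is_inter,
        rng.uniform(0.0, spec.control_mean_max, size=n),
        spec.noninteractor_mean,
    )
    bait_mean = np.where(is_contam, 4 * spec.noninteractor_mean, bait_mean)
    ctrl_mean = np.where(is_contam, 4 * spec.noninteractor_mean, ctrl_mean)

    bait = rng.poisson(np.tile(bait_mean, (reps, 1))).sum(axis=0)
    ctrl = rng.poisson(np.tile(ctrl_mean, (reps, 1))).sum(axis=0)
    peptides = rng.poisson(spec.peptide_mean, size=(reps, n))

    df = pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(n)],
            "is_contaminant": is_contam,
            "is_true_interactor": is_inter & ~is_contam,
            "bait_sequences": bait,
            "control_sequences": ctrl,
        }
    )
    for r in range(reps):
        df[f"peptides_rep{r + 1}"] = peptides[r]
    return df


# ---------------------------------------------------------------------------
# 4C


def simulate_4c_counts(config: SimulationConfig, viewpoint: str = "VP") -> pd.DataFrame:
    """Per-fragment two-replicate 4C counts with planted true contacts."""
    rng = _stage_rng(config.seed, _STAGE_4C)
    spec = config.fourc
    n = spec.n_fragments
    is_contact = np.zeros(n, dtype=bool)
    is_contact[: spec.n_contacts] = True
    mean = np.where(is_contact, spec.contact_mean, spec.background_mean)
    rep1 = rng.poisson(mean)
    rep2 = rng.poisson(mean)
    return pd.DataFrame(
        {
            "fragment_id": [f"frag{i:05d}" for i in range(n)],
            "viewpoint": viewpoint,
            "rep1": rep1,
            "rep2": rep2,
            "is_true_contact": is_contact,
        }
    )
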