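"""Genomic data model and plain-text readers/writers.

All coordinates are 0-based half-open (BED-native); widths are ``end - start``.
Aligned reads are carried as strand-aware 5' positions plus a library size
(``TagCollection``) — full alignments are never stored.  Every reader rejects
intervals on chromosomes absent from the supplied :class:`GenomeLayout` so
that mixing incompatible assemblies fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "TagCollection",
    "Segmentation",
    "GeneTable",
    "read_intervals",
    "write_intervals",
    "read_table",
    "write_table",
]

DE_STATUSES = ("up", "down", "unchanged", "NA")


class FormatError(ValueError):
    """A file did not parse in the declared dialect."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; ``G`` is the genome size in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def G(self) -> int:
        return int(sum(self.chrom_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored span with optional summit offset and score.

    ``summit`` is an offset from ``start`` (narrowPeak column 10 convention);
    ``None`` means no summit was recorded and consumers fall back to the
    interval midpoint.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside interval of width "
                f"{self.end - self.start}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit_pos(self) -> int:
        """Absolute summit position; midpoint when no summit was recorded."""
        if self.summit is not None:
            return self.start + self.summit
        return self.start + self.width // 2


class IntervalSet:
    """A labelled collection of intervals on one genome (peaks of one factor)."""

    def __init__(
        self,
        genome: GenomeLayout,
        intervals: Iterable[GenomicInterval],
        label: str = "",
    ) -> None:
        self.genome = genome
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self.label = label
        lengths = genome.lengths
        for iv in self.intervals:
            if iv.chrom not in lengths:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
                    f"end {lengths[iv.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def total_bp(self) -> int:
        """Sum of interval widths (bp occupied, counting overlaps twice)."""
        return sum(iv.width for iv in self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of start/end, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in out.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )


@dataclass
class TagCollection:
    """Strand-aware 5' read positions plus the library size.

    ``library_size`` may exceed the number of stored tags when the collection
    was subsampled; it is the denominator of all depth normalization.
    """

    genome: GenomeLayout
    chroms: np.ndarray  # object/str array
    positions: np.ndarray  # int64 5' positions
    strands: np.ndarray  # '+'/'-'
    library_size: int

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.chroms) == len(self.strands) == n):
            raise ValueError("tag arrays must be equal length")
        if n == 0:
            raise ValueError("TagCollection requires at least one tag")
        if self.library_size < n:
            raise ValueError("library_size smaller than stored tag count")
        bad = set(np.unique(self.chroms)) - set(self.genome.chrom_names)
        if bad:
            raise ValueError(f"tags on unknown chromosomes: {sorted(bad)}")
        lengths = self.genome.lengths
        for c in np.unique(self.chroms):
            m = self.chroms == c
            pos = self.positions[m]
            if pos.min() < 0 or pos.max() >= lengths[str(c)]:
                raise ValueError(f"tag position out of bounds on {c}")
        if not set(np.unique(self.strands)) <= {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_lists(
        cls,
        genome: GenomeLayout,
        tags: Sequence[tuple[str, int, str]],
        library_size: int | None = None,
    ) -> "TagCollection":
        chroms = np.asarray([t[0] for t in tags], dtype=object)
        pos = np.asarray([t[1] for t in tags], dtype=np.int64)
        strands = np.asarray([t[2] for t in tags], dtype=object)
        return cls(genome, chroms, pos, strands, library_size or len(tags))


class Segmentation:
    """A genome-tiling labelled segmentation (chromatin states).

    Segments must cover every chromosome without gaps or overlaps; this is
    checked on construction.
    """

    def __init__(
        self,
        genome: GenomeLayout,
        segments: Sequence[tuple[str, int, int, str]],
        state_names: Sequence[str] | None = None,
    ) -> None:
        self.genome = genome
        self.segments = sorted(segments, key=lambda s: (s[0], s[1]))
        seen_states = sorted({s[3] for s in self.segments})
        self.state_names = list(state_names) if state_names else seen_states
        if not set(seen_states) <= set(self.state_names):
            raise ValueError("segment label not in state_names")
        self._validate_tiling()

    def _validate_tiling(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in self.genome.chrom_names}
        for chrom, start, end, _state in self.segments:
            if chrom not in by_chrom:
                raise ValueError(f"segment on unknown chromosome {chrom!r}")
            by_chrom[chrom].append((start, end))
        for chrom, spans in by_chrom.items():
            L = self.genome.length_of(chrom)
            spans.sort()
            if not spans:
                raise ValueError(f"chromosome {chrom} has no segments")
            if spans[0][0] != 0:
                raise ValueError(f"segmentation gap at start of {chrom}")
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 != e1:
                    raise ValueError(
                        f"segmentation gap/overlap on {chrom} at {e1}..{s2}"
                    )
            if spans[-1][1] != L:
                raise ValueError(f"segmentation does not reach end of {chrom}")

    def state_bp(self) -> dict[str, int]:
        out = {s: 0 for s in self.state_names}
        for _c, start, end, state in self.segments:
            out[state] += end - start
        return out

    def to_interval_set(self, state: str) -> IntervalSet:
        ivs = [
            GenomicInterval(c, s, e, name=st)
            for c, s, e, st in self.segments
            if st == state
        ]
        return IntervalSet(self.genome, ivs, label=state)


class GeneTable:
    """Genes with TSS positions and differential-expression status.

    Backed by a DataFrame with columns gene_id, chrom, tss, strand, de_status.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeLayout | None = None) -> None:
        required = ["gene_id", "chrom", "tss", "strand", "de_status"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"gene table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        bad = set(df["de_status"].unique()) - set(DE_STATUSES)
        if bad:
            raise FormatError(f"unknown de_status values: {sorted(bad)}")
        if genome is not None:
            lengths = genome.lengths
            for chrom, sub in df.groupby("chrom"):
                if chrom not in lengths:
                    raise ValueError(f"gene on unknown chromosome {chrom!r}")
                if (sub["tss"] < 0).any() or (sub["tss"] >= lengths[chrom]).any():
                    raise ValueError(f"TSS out of bounds on {chrom}")
        self.df = df.reset_index(drop=True)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# interval file I/O


def _parse_int(token: str, lineno: int, path: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: expected integer, got {token!r}") from None


def read_intervals(path: str | Path, format: str, genome: GenomeLayout) -> IntervalSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into an :class:`IntervalSet`.

    narrowPeak column 10 is the summit offset from start; ``-1`` means absent.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown interval format {format!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if format == "narrowPeak" and len(f) < 10:
                raise FormatError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = f[0]
            start = _parse_int(f[1], lineno, str(path))
            end = _parse_int(f[2], lineno, str(path))
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score: float | None = None
            if len(f) > 4 and f[4] != ".":
                score = float(f[4])
            summit: int | None = None
            if format == "narrowPeak":
                s = _parse_int(f[9], lineno, str(path))
                summit = None if s == -1 else s
                if len(f) > 6 and f[6] != ".":
                    score = float(f[6])  # signalValue is the informative score
            try:
                iv = GenomicInterval(chrom, start, end, summit=summit, score=score, name=name)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            intervals.append(iv)
    return IntervalSet(genome, intervals, label=path.stem)


def write_intervals(iset: IntervalSet, path: str | Path, format: str) -> None:
    """Write an interval set; ``read_intervals`` round-trips it exactly."""
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        for iv in iset:
            name = iv.name if iv.name is not None else "."
            score = repr(iv.score) if iv.score is not None else "."
            if format == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")
            else:
                summit = iv.summit if iv.summit is not None else -1
                sig = repr(iv.score) if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t{sig}\t-1\t-1\t{summit}\n"
                )


# ---------------------------------------------------------------------------
# tabular I/O

_TABLE_SCHEMAS = {
    "tags": ["chrom", "pos", "strand"],
    "genes": ["gene_id", "chrom", "tss", "strand", "de_status"],
    "spectral_counts": [
        "protein_id",
        "is_contaminant",
        "bait_sequences",
        "control_sequences",
    ],
    "fourc_counts": ["fragment_id", "viewpoint", "rep1", "rep2"],
    "segmentation_bed": None,  # headerless 4-column BED
}


def read_table(
    path: str | Path,
    schema: str,
    genome: GenomeLayout | None = None,
    library_size: int | None = None,
):
    """Read a header TSV (or 4-column segment BED) into the typed object."""
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)

    if schema == "segmentation_bed":
        if genome is None:
            raise ValueError("segmentation requires a genome")
        segs: list[tuple[str, int, int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise FormatError(f"{path}:{lineno}: segment BED needs 4 columns")
                segs.append((f[0], _parse_int(f[1], lineno, str(path)),
                             _parse_int(f[2], lineno, str(path)), f[3]))
        return Segmentation(genome, segs)

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TABLE_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    if schema == "tags":
        if genome is None:
            raise ValueError("tags require a genome")
        bad = set(df["strand"].unique()) - {"+", "-"}
        if bad:
            raise FormatError(f"{path}: invalid strand value(s) {sorted(bad)}")
        return TagCollection(
            genome,
            df["chrom"].to_numpy(dtype=object),
            df["pos"].to_numpy(dtype=np.int64),
            df["strand"].to_numpy(dtype=object),
            library_size or len(df),
        )
    if schema == "genes":
        return GeneTable(df, genome=genome)
    if schema == "fourc_counts":
        if (df[["rep1", "rep2"]] < 0).to_numpy().any():
            raise ValueError(f"{path}: negative 4C counts")
        return df
    # spectral_counts: keep peptides_rep* columns alongside the required ones
    pep_cols = [c for c in df.columns if c.startswith("peptides_rep")]
    if not pep_cols:
        raise FormatError(f"{path}: need at least one peptides_rep<i> column")
    df["is_contaminant"] = df["is_contaminant"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Read a chrom-sizes TSV (columns chrom, length)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "length") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return GenomeLayout(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))


def write_genome_layout(genome: GenomeLayout, path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": genome.chrom_names, "length": genome.chrom_lengths}
    ).to_csv(path, sep="\t", index=False)
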