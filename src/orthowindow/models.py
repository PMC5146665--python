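"""Domain types for cross-species comparable-region annotation.

Coordinates are 0-based half-open everywhere in memory; GTF I/O converts
to 1-based inclusive at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

Interval = tuple[int, int]

GAP = "-"


class OrthowindowError(Exception):
    """Base class for package errors."""


class InvalidInputError(OrthowindowError):
    """Malformed or out-of-contract input values."""


class FormatError(OrthowindowError):
    """Malformed file content; message names the offending record."""


class CoordinateError(OrthowindowError):
    """Coordinate outside the range of the model it addresses."""


class ConfigurationError(OrthowindowError):
    """Inconsistent run configuration (e.g. a species without samples)."""


class DegenerateDataError(OrthowindowError):
    """Data admits no defined answer (zero variance where variance is required)."""


def _check_intervals(ivals: Iterable[Interval]) -> tuple[Interval, ...]:
    ivals = tuple((int(s), int(e)) for s, e in ivals)
    prev_end = None
    for s, e in ivals:
        if s >= e:
            raise InvalidInputError(f"interval [{s},{e}) is empty or inverted")
        if prev_end is not None and s < prev_end:
            raise InvalidInputError("intervals overlap or are unsorted")
        prev_end = e
    return ivals


@dataclass(frozen=True)
class ExonModel:
    """Genomic exon structure of the designated transcript of one gene."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", _check_intervals(self.exons))
        if not self.exons:
            raise InvalidInputError(f"gene {self.gene_id}: no exons")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class OrthologPair:
    """One 1:1 ortholog gene pair with transcript sequences and exon models."""

    pair_id: str
    species_a: str
    gene_a: str
    sequence_a: str
    exon_model_a: ExonModel
    species_b: str
    gene_b: str
    sequence_b: str
    exon_model_b: ExonModel

    def __post_init__(self) -> None:
        for seq, model, which in (
            (self.sequence_a, self.exon_model_a, "a"),
            (self.sequence_b, self.exon_model_b, "b"),
        ):
            if len(seq) != model.transcript_length:
                raise InvalidInputError(
                    f"pair {self.pair_id}: sequence_{which} length {len(seq)} != "
                    f"exon model transcript length {model.transcript_length}"
                )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of the two transcripts of an ortholog pair."""

    pair_id: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise FormatError(
                f"pair {self.pair_id}: alignment rows have unequal length "
                f"({len(self.row_a)} vs {len(self.row_b)})"
            )
        for i, (ca, cb) in enumerate(zip(self.row_a, self.row_b)):
            if ca == GAP and cb == GAP:
                raise FormatError(f"pair {self.pair_id}: column {i} is gap in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def ungapped(self, row: str) -> str:
        return row.replace(GAP, "")


@dataclass(frozen=True)
class AlignmentWindow:
    """One fixed-length block of consecutive alignment columns.

    ``identity`` counts gap columns against the denominator: a window of
    25 columns with 20 matches has identity 0.80 no matter how the other
    5 columns split between mismatches and gaps.
    """

    pair_id: str
    window_index: int
    col_start: int
    col_end: int
    n_match: int
    n_mismatch: int
    n_gap_cols: int
    tx_interval_a: Interval
    tx_interval_b: Interval

    @property
    def window_len(self) -> int:
        return self.col_end - self.col_start

    @property
    def identity(self) -> float:
        return self.n_match / self.window_len


@dataclass(frozen=True)
class GenomicWindow:
    """An alignment window mapped to genomic segments in one species.

    A window spanning an exon junction maps to more than one segment;
    segments are ascending genomic intervals inside the gene's exons.
    """

    pair_id: str
    window_index: int
    species: str
    gene_id: str
    chrom: str
    strand: str
    segments: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", _check_intervals(self.segments))

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the comparability pipeline.

    Identity and gap bounds are strict, matching the ">70% identity, and
    <3 bp gaps" reading: identity must exceed ``min_identity`` and a window
    passes only with at most ``max_gap_cols - 1`` gap columns.
    """

    window_len: int = 25
    min_identity: float = 0.70
    max_gap_cols: int = 3
    min_r: float = 0.4
    sign_alpha: float = 0.001
    outlier_z: float = 2.5
    min_windows: int = 4

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise InvalidInputError("window_len must be >= 2")
        if not (0.0 <= self.min_identity <= 1.0):
            raise InvalidInputError("min_identity must be in [0, 1]")
        for name in ("max_gap_cols", "min_r", "sign_alpha", "outlier_z", "min_windows"):
            v = getattr(self, name)
            if v != v or v in (float("inf"), float("-inf")):
                raise InvalidInputError(f"{name} must be finite")


@dataclass
class ComparableWindow:
    """A retained window with its genomic footprint in both species."""

    window_index: int
    identity: float
    n_gap_cols: int
    genomic_a: GenomicWindow
    genomic_b: GenomicWindow


@dataclass
class PairAnnotation:
    """All retained windows of one ortholog pair."""

    pair_id: str
    gene_a: str
    gene_b: str
    windows: list[ComparableWindow] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def comparable_length(self, which: str) -> int:
        attr = "genomic_a" if which == "a" else "genomic_b"
        return sum(getattr(w, attr).total_length for w in self.windows)


@dataclass
class ComparableAnnotation:
    """The paired comparable-region annotation for a set of ortholog pairs."""

    species_a: str
    species_b: str
    pairs: dict[str, PairAnnotation] = field(default_factory=dict)

    def subset(self, retained: dict[str, list[int]]) -> "ComparableAnnotation":
        """Restrict to `retained` pair ids, keeping only listed window indices."""
        out = ComparableAnnotation(self.species_a, self.species_b)
        for pid, keep in retained.items():
            if pid not in self.pairs:
                raise InvalidInputError(f"pair {pid} not in annotation")
            src = self.pairs[pid]
            keep_set = set(keep)
            out.pairs[pid] = PairAnnotation(
                pair_id=pid,
                gene_a=src.gene_a,
                gene_b=src.gene_b,
                windows=[w for w in src.windows if w.window_index in keep_set],
            )
        return out


# Decision labels for GeneConcordance.
RETAIN = "retain"
RETAIN_RESCUED = "retain_rescued"
EXCLUDED_LOW_R = "excluded_low_r"
EXCLUDED_DEGENERATE = "excluded_degenerate"


@dataclass
class GeneConcordance:
    """Per-gene interspecies coverage concordance statistics and verdict."""

    gene_id: str
    n_windows: int
    pearson_r: float | None
    sign_k: int
    sign_n: int
    sign_p: float
    slope: float | None = None
    intercept: float | None = None
    outlier_windows: frozenset[int] = frozenset()
    decision: str = EXCLUDED_DEGENERATE
    retained_windows: frozenset[int] = frozenset()

    @property
    def retained(self) -> bool:
        return self.decision in (RETAIN, RETAIN_RESCUED)
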