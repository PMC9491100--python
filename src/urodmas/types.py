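"""Core domain types shared by every stage of the pipeline.

Coordinate conventions
----------------------
Capture regions and windows use 0-based half-open intervals (BED dialect).
Cytosine-report positions are 1-based (methylation-extractor dialect).
A 1-based position ``p`` lies inside the half-open window ``[s, e)``
iff ``s < p <= e``.

Matrix orientation is samples x windows throughout (one row per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

COHORTS = ("healthy", "primary", "recurrent", "non_recurrent", "benign")
CONTEXTS = ("CpG", "CHG", "CHH")


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: object = None, line: Optional[int] = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


@dataclass(frozen=True, order=True)
class CaptureRegion:
    """A targeted capture interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.region_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValidationError(f"region {self.region_id}: negative start")

    @property
    def length(self) -> int:
        return self.end - self.start


class CytosineRecord(NamedTuple):
    """One row of a genome-wide cytosine report (both strands, any context)."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    n_meth: int  # alignments supporting methylation
    n_unmeth: int  # alignments supporting unmethylation
    context: str  # CpG / CHG / CHH


@dataclass
class SampleSheetEntry:
    sample_id: str
    cohort: str
    patient_id: Optional[str] = None
    timepoint: Optional[int] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    smoking: Optional[str] = None
    stage: Optional[str] = None
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown cohort {self.cohort!r} "
                f"(expected one of {COHORTS})"
            )


@dataclass(frozen=True)
class Window:
    """One fixed-length tile of a capture region."""

    window_id: str
    region_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    index_in_region: int


@dataclass
class WindowCatalog:
    """Ordered collection of fixed-length windows; the coordinate backbone.

    Windows are globally ordered by (chrom, start); within a region they are
    consecutive, non-overlapping tiles anchored at the region start.
    """

    windows: list[Window]
    window_length: int

    def __post_init__(self) -> None:
        ids = [w.window_id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate window_id in catalog")
        for w in self.windows:
            if w.end - w.start != self.window_length:
                raise ValidationError(
                    f"window {w.window_id} has length {w.end - w.start}, "
                    f"expected {self.window_length}"
                )
        key = [(w.chrom, w.start) for w in self.windows]
        if key != sorted(key):
            raise ValidationError("catalog windows not sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def window_ids(self) -> list[str]:
        return [w.window_id for w in self.windows]

    def regions(self) -> dict[str, list[int]]:
        """Map region_id -> catalog column indices, in genomic order."""
        out: dict[str, list[int]] = {}
        for i, w in enumerate(self.windows):
            out.setdefault(w.region_id, []).append(i)
        return out


def _check_axes(sample_ids: Sequence[str], window_ids: Sequence[str], *mats: np.ndarray) -> None:
    shape = (len(sample_ids), len(window_ids))
    for m in mats:
        if m.shape != shape:
            raise ValidationError(f"matrix shape {m.shape} does not match axes {shape}")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample_id")
    if len(set(window_ids)) != len(window_ids):
        raise ValidationError("duplicate window_id")


@dataclass
class CountMatrix:
    """Per sample x window sums of alignments supporting (un)methylation."""

    sample_ids: list[str]
    window_ids: list[str]
    methyl: np.ndarray  # int, samples x windows
    unmethyl: np.ndarray

    def __post_init__(self) -> None:
        self.methyl = np.asarray(self.methyl)
        self.unmethyl = np.asarray(self.unmethyl)
        _check_axes(self.sample_ids, self.window_ids, self.methyl, self.unmethyl)
        if (self.methyl < 0).any() or (self.unmethyl < 0).any():
            raise ValidationError("negative counts")

    @property
    def coverage(self) -> np.ndarray:
        return self.methyl + self.unmethyl


@dataclass
class DMASMatrix:
    """Arctangent methylation scores, each entry in [0, pi/2] radians."""

    sample_ids: list[str]
    window_ids: list[str]
    values: np.ndarray  # float, samples x windows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_axes(self.sample_ids, self.window_ids, self.values)

    def subset_samples(self, sample_ids: Sequence[str]) -> "DMASMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        rows = [index[s] for s in sample_ids]
        return DMASMatrix(list(sample_ids), list(self.window_ids), self.values[rows])


@dataclass(frozen=True)
class TupleFeature:
    """k consecutive windows of one region, identified by their window ids."""

    region_id: str
    window_ids: tuple[str, ...]
    start_index: int  # index_in_region of the first window

    @property
    def k(self) -> int:
        return len(self.window_ids)


@dataclass(frozen=True)
class OrderingPattern:
    """A class-specific relative ordering of DMAS values on one tuple.

    ``permutation`` lists local window offsets (0..k-1) in ascending DMAS
    order, e.g. (2, 0, 1) means window 3 < window 1 < window 2.
    """

    feature: TupleFeature
    permutation: tuple[int, ...]
    class_label: str  # 'healthy' or 'cancer'
    weight: float
    freq_healthy: float
    freq_cancer: float


@dataclass
class PatternModel:
    """The trained classifier: weighted ordering patterns per class."""

    k: int
    delta_min: float
    max_patterns_per_class: int
    healthy_patterns: list[OrderingPattern] = field(default_factory=list)
    cancer_patterns: list[OrderingPattern] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.healthy_patterns) + len(self.cancer_patterns)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: end must exceed start")
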