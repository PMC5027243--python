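"""Core domain records shared by every analysis stage.

All coordinates are 1-based and closed, following VCF convention. BED and
BEDPE inputs are converted at the I/O boundary (:mod:`radsig.catalogue_io`)
and never leak 0-based half-open intervals into analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

Interval = tuple[int, int]

NUCLEOTIDES = frozenset("ACGT")

#: Rearrangement junction orientations. ``head_head``/``tail_tail`` are the
#: two inverted orientations a balanced inversion produces; everything else
#: (deletion-type, duplication-type, inter-chromosomal) is ``other``.
ORIENT_HEAD_HEAD = "head_head"
ORIENT_TAIL_TAIL = "tail_tail"
ORIENT_OTHER = "other"
ORIENTATIONS = (ORIENT_HEAD_HEAD, ORIENT_TAIL_TAIL, ORIENT_OTHER)

INDEL_DELETION = "deletion"
INDEL_INSERTION = "insertion"
INDEL_COMPLEX = "complex"
INDEL_CLASSES = (INDEL_DELETION, INDEL_INSERTION, INDEL_COMPLEX)

CLONAL = "clonal"
SUBCLONAL = "subclonal"
UNKNOWN = "unknown"
CLONALITY_CLASSES = (CLONAL, SUBCLONAL, UNKNOWN)

#: Default tumour group labels. A manifest may declare its own set.
DEFAULT_GROUPS = (
    "radiation",
    "naive_breast",
    "naive_osteosarcoma",
    "brca_breast",
    "other",
)


class ValidationError(ValueError):
    """A record or file violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed as the declared format."""


@dataclass
class SubstitutionRecord:
    """A somatic single-nucleotide substitution."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    sample_id: str = ""
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"substitution position must be >= 1, got {self.pos}")
        if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
            raise ValidationError(
                f"substitution alleles must be single A/C/G/T bases, got "
                f"{self.ref_base!r}>{self.alt_base!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_base == self.alt_base:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")


@dataclass
class IndelRecord:
    """A normalized small insertion/deletion.

    ``pos`` is the VCF anchor base (1-based). For a deletion of length L the
    deleted span is ``pos+1 .. pos+L`` and ``deleted_seq`` holds those bases.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    indel_class: str
    length: int
    deleted_seq: str | None = None
    vaf: float | None = None
    mh_len: int | None = None
    clonality: str = UNKNOWN
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.indel_class not in INDEL_CLASSES:
            raise ValidationError(f"unknown indel class {self.indel_class!r}")
        if self.clonality not in CLONALITY_CLASSES:
            raise ValidationError(f"unknown clonality class {self.clonality!r}")
        if self.length < 1:
            raise ValidationError(f"indel length must be >= 1, got {self.length}")
        if self.pos < 1:
            raise ValidationError(f"indel position must be >= 1, got {self.pos}")
        if self.indel_class == INDEL_DELETION:
            if len(self.ref_allele) <= len(self.alt_allele) or not self.ref_allele.startswith(
                self.alt_allele
            ):
                raise ValidationError(
                    f"deletion alleles malformed at {self.chrom}:{self.pos}: "
                    f"{self.ref_allele!r}>{self.alt_allele!r}"
                )
            if self.mh_len is not None and self.mh_len > self.length:
                raise ValidationError(
                    f"microhomology {self.mh_len} exceeds deletion length {self.length}"
                )

    @property
    def del_start(self) -> int:
        """First deleted base (deletions only)."""
        return self.pos + 1

    @property
    def del_end(self) -> int:
        """Last deleted base (deletions only)."""
        return self.pos + self.length


def _midpoint(ival: Interval) -> float:
    return (ival[0] + ival[1]) / 2.0


@dataclass
class RearrangementCall:
    """One rearrangement junction: two breakpoint intervals plus orientation."""

    call_id: str
    chrom_low: str
    chrom_high: str
    low_ival: Interval
    high_ival: Interval
    orient: str
    read_support: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.low_ival = (int(self.low_ival[0]), int(self.low_ival[1]))
        self.high_ival = (int(self.high_ival[0]), int(self.high_ival[1]))
        if self.orient not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orient!r} for {self.call_id}")
        if self.read_support < 0:
            raise ValidationError(f"negative read support for {self.call_id}")
        for ival in (self.low_ival, self.high_ival):
            if ival[0] > ival[1]:
                raise ValidationError(f"interval start > end in {self.call_id}: {ival}")
            if ival[0] < 1:
                raise ValidationError(f"non-positive coordinate in {self.call_id}: {ival}")
        if self.chrom_low == self.chrom_high and _midpoint(self.low_ival) > _midpoint(
            self.high_ival
        ):
            self.low_ival, self.high_ival = self.high_ival, self.low_ival

    @property
    def low_mid(self) -> float:
        return _midpoint(self.low_ival)

    @property
    def high_mid(self) -> float:
        return _midpoint(self.high_ival)

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom_low == self.chrom_high

    @property
    def span(self) -> float | None:
        """Distance between breakpoint midpoints (intrachromosomal only)."""
        if not self.is_intrachromosomal:
            return None
        return self.high_mid - self.low_mid


@dataclass
class BalancedInversion:
    """A reciprocal head-to-head + tail-to-tail junction pair."""

    head_call_id: str
    tail_call_id: str
    chrom: str
    size: float
    sample_id: str = ""
    mh_lens: tuple[int, int] | None = None
    nt_insert_lens: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValidationError(
                f"balanced inversion {self.head_call_id}/{self.tail_call_id} has size <= 0"
            )


class CallableRegions:
    """Sorted, merged, non-overlapping 1-based closed intervals per chromosome."""

    def __init__(self, intervals: Mapping[str, Iterable[Interval]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivals in intervals.items():
            merged = self._merge(list(ivals))
            if merged:
                self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
                self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    @staticmethod
    def _merge(ivals: list[Interval]) -> list[Interval]:
        for s, e in ivals:
            if s > e:
                raise ValidationError(f"interval start > end: ({s}, {e})")
            if s < 1:
                raise ValidationError(f"non-positive interval start: ({s}, {e})")
        ivals = sorted(ivals)
        merged: list[Interval] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:  # overlapping or adjacent
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def intervals(self, chrom: str) -> list[Interval]:
        if chrom not in self._starts:
            return []
        return list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))

    @property
    def total_bases(self) -> int:
        return int(
            sum((self._ends[c] - self._starts[c] + 1).sum() for c in self._starts)
        )

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom not in self._starts:
            return False
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return i >= 0 and pos <= int(self._ends[chrom][i])

    def span_inside(self, chrom: str, start: int, end: int) -> bool:
        """True when the whole closed span lies inside one callable interval."""
        if chrom not in self._starts or start > end:
            return False
        i = int(np.searchsorted(self._starts[chrom], start, side="right")) - 1
        return i >= 0 and end <= int(self._ends[chrom][i])

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self._starts:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] <= self._ends[chrom][idx[ok]]
        return out

    def cumulative(self) -> tuple[list[tuple[str, int, int]], np.ndarray]:
        """Flat interval list plus cumulative base offsets, for uniform sampling."""
        flat: list[tuple[str, int, int]] = []
        lengths: list[int] = []
        for chrom in self._starts:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                flat.append((chrom, int(s), int(e)))
                lengths.append(int(e - s + 1))
        return flat, np.cumsum([0] + lengths)


class FeatureTrack:
    """A genomic property queryable at any position.

    Backed by sorted non-overlapping 1-based closed intervals with one value
    each; positions outside every interval return ``default_value``.
    """

    def __init__(
        self,
        name: str,
        kind: str,
        intervals: Mapping[str, Iterable[tuple[int, int, Any]]],
        default_value: Any,
        labels: tuple[str, ...] | None = None,
    ):
        if kind not in ("quantitative", "binary", "categorical"):
            raise ValidationError(f"unknown track kind {kind!r} for {name}")
        if kind == "categorical" and labels is None:
            raise ValidationError(f"categorical track {name} must declare its label set")
        self.name = name
        self.kind = kind
        self.default_value = default_value
        self.labels = labels
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, rows in intervals.items():
            rows = sorted(rows, key=lambda r: (r[0], r[1]))
            starts, ends, values = [], [], []
            for s, e, v in rows:
                if s > e or s < 1:
                    raise ValidationError(f"bad interval ({s},{e}) in track {name}")
                if kind == "categorical" and v not in labels:  # type: ignore[operator]
                    raise ValidationError(f"label {v!r} not in declared set of {name}")
                if starts and s <= ends[-1]:
                    if values[-1] != v:
                        raise ValidationError(
                            f"overlapping intervals with conflicting values in track "
                            f"{name} at {chrom}:{s}"
                        )
                    ends[-1] = max(ends[-1], e)
                    continue
                starts.append(s)
                ends.append(e)
                values.append(v)
            if starts:
                self._starts[chrom] = np.array(starts, dtype=np.int64)
                self._ends[chrom] = np.array(ends, dtype=np.int64)
                self._values[chrom] = np.array(values)

    def value_at(self, chrom: str, pos: int) -> Any:
        values, covered = self.values_at(chrom, np.array([pos]))
        return values[0] if covered[0] else self.default_value

    def values_at(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized query; returns (values, covered mask)."""
        positions = np.asarray(positions)
        n = len(positions)
        covered = np.zeros(n, dtype=bool)
        if chrom not in self._starts:
            values = np.full(n, self.default_value)
            return values, covered
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        ok = idx >= 0
        covered[ok] = positions[ok] <= self._ends[chrom][idx[ok]]
        values = np.full(n, self.default_value, dtype=self._values[chrom].dtype)
        values[covered] = self._values[chrom][idx[covered]]
        return values, covered

    def intervals(self, chrom: str) -> list[tuple[int, int, Any]]:
        if chrom not in self._starts:
            return []
        return [
            (int(s), int(e), v)
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom])
        ]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)


@dataclass
class TumourCatalogue:
    """All somatic calls for one tumour, plus sample-level metadata."""

    sample_id: str
    group: str
    purity: float | None = None
    substitutions: list[SubstitutionRecord] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)
    rearrangements: list[RearrangementCall] = field(default_factory=list)
    #: optional (chrom, start, end, total copy number) segments
    copy_number: list[tuple[str, int, int, float]] | None = None
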