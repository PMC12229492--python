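"""Half-open interval arithmetic underlying every intersection in the pipeline.

Two deliberate semantic choices live here and are relied on everywhere else:

* ``overlaps_fraction(a, b, f)`` is **directional**: the fraction requirement
  applies to the *query* interval ``a`` (mirroring ``bedtools intersect -f``),
  so ``overlaps_fraction(a, b, f)`` and ``overlaps_fraction(b, a, f)`` can
  disagree when the intervals differ in length.
* The fraction boundary is inclusive (``>=``) and is evaluated in exact
  rational arithmetic, so an overlap of exactly ``f * len(a)`` bases passes
  bit-stably for any representable ``f``.

A brute-force all-pairs scan (:func:`brute_force_query`) is kept alongside the
indexed path as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Protocol, Sequence

from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "overlap_length",
    "overlaps_fraction",
    "contains_point",
    "IntervalIndex",
    "query_overlaps",
    "brute_force_query",
]


class Region(Protocol):
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: Region, b: Region) -> int:
    """Number of bases shared by two half-open intervals (0 if chroms differ)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps_fraction(a: Region, b: Region, f: float | Fraction) -> bool:
    """True iff the overlap covers at least fraction ``f`` of ``a``'s length.

    Directional: ``f`` applies to ``a`` (the query). The comparison
    ``overlap * q >= p * len(a)`` with ``f = p/q`` exact avoids float
    round-off exactly at the boundary; a float ``f`` is interpreted as the
    decimal it prints as (0.05 means exactly 1/20, not the nearest binary
    float).
    """
    frac = Fraction(str(f)) if isinstance(f, float) else Fraction(f)
    if not (0 < frac <= 1):
        raise ValueError(f"overlap fraction must lie in (0, 1], got {f}")
    ov = overlap_length(a, b)
    if ov == 0:
        return False
    return ov * frac.denominator >= frac.numerator * (a.end - a.start)


def contains_point(a: Region, pos: int, chrom: str | None = None) -> bool:
    """True iff ``pos`` (a 0-based base position) lies inside ``a``."""
    if chrom is not None and chrom != a.chrom:
        return False
    return a.start <= pos < a.end


class IntervalIndex:
    """Per-chromosome interval tree over an ordered subject collection.

    Queries return subjects in their original input order, so results are
    deterministic and match a brute-force scan over the same sequence.
    """

    def __init__(self, subjects: Sequence[Region]):
        self._subjects = list(subjects)
        self._trees: dict[str, IntervalTree] = {}
        for i, s in enumerate(self._subjects):
            self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, i)

    def __len__(self) -> int:
        return len(self._subjects)

    def query(self, query: Region, f: float | Fraction | None = None) -> list:
        """Subjects overlapping ``query`` (by >= 1 bp, or by fraction ``f``)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        idx = sorted(hit.data for hit in tree.overlap(query.start, query.end))
        out = [self._subjects[i] for i in idx]
        if f is not None:
            out = [s for s in out if overlaps_fraction(query, s, f)]
        return out

    def any_match(self, query: Region, f: float | Fraction | None = None) -> bool:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return False
        if f is None:
            return bool(tree.overlap(query.start, query.end))
        return any(
            overlaps_fraction(query, self._subjects[hit.data], f)
            for hit in tree.overlap(query.start, query.end)
        )


def query_overlaps(query: Region, subjects: Sequence[Region], f: float | Fraction) -> list:
    """One-shot fractional overlap query against a subject collection."""
    return IntervalIndex(subjects).query(query, f)


def brute_force_query(
    query: Region, subjects: Iterable[Region], f: float | Fraction | None = None
) -> list:
    """All-pairs scan with identical semantics to :meth:`IntervalIndex.query`.

    Independent oracle: kept free of any index machinery on purpose.
    """
    out = []
    for s in subjects:
        ov = overlap_length(query, s)
        if ov == 0:
            continue
        if f is None or overlaps_fraction(query, s, f):
            out.append(s)
    return out
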