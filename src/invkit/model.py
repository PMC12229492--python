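"""Core domain records shared across the pipeline.

All genomic coordinates inside the package are 0-based half-open
(``[start, end)``), regardless of the convention of the input dialect.
Readers convert at the boundary; writers convert back on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ACCEPTED_CONTIGS",
    "InversionCall",
    "Callset",
    "normalize_contig",
    "harmonize_calls",
]

#: the 24 nuclear contigs retained for analysis (autosomes + X + Y)
ACCEPTED_CONTIGS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + (
    "chrX",
    "chrY",
)
_ACCEPTED = frozenset(ACCEPTED_CONTIGS)

_CONTIG_RANK = {c: i for i, c in enumerate(ACCEPTED_CONTIGS)}


def normalize_contig(chrom: str) -> str | None:
    """Normalize a contig name to ``chr1..chr22, chrX, chrY``.

    Returns None for anything outside the 24 accepted nuclear contigs
    (alt/random/patch contigs, chrM, malformed names).
    """
    c = chrom.strip()
    if not c:
        return None
    if not c.lower().startswith("chr"):
        c = "chr" + c
    c = "chr" + c[3:].upper() if c[3:].upper() in ("X", "Y") else "chr" + c[3:]
    return c if c in _ACCEPTED else None


@dataclass(frozen=True)
class InversionCall:
    """One harmonized inversion record.

    ``start`` is the first inverted base (0-based); ``end`` is the half-open
    bound, so ``end - 1`` is the last inverted base and ``end - start`` the
    inverted length in bp.
    """

    id: str
    chrom: str
    start: int
    end: int
    dataset: str
    allele_frequency: float | None = None
    n_homalt: int | None = None
    svtype_raw: str = "INV"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"inversion {self.id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.chrom not in _ACCEPTED:
            raise ValueError(f"inversion {self.id}: contig {self.chrom!r} not accepted")
        af = self.allele_frequency
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"inversion {self.id}: allele frequency {af} outside [0,1]")
        if self.n_homalt is not None and self.n_homalt < 0:
            raise ValueError(f"inversion {self.id}: negative n_homalt")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[int, int, int]:
        return (_CONTIG_RANK[self.chrom], self.start, self.end)


@dataclass
class Callset:
    """A harmonized, sorted collection of inversion calls from one dataset."""

    dataset: str
    calls: list[InversionCall] = field(default_factory=list)
    genome_build: str = "GRCh38"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.calls]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"callset {self.dataset}: duplicate call id {dup!r}")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


def harmonize_calls(
    dataset: str,
    calls: list[InversionCall],
    counters: dict,
    *,
    genome_build: str = "GRCh38",
    provenance: dict | None = None,
) -> Callset:
    """Sort calls and collapse exact-coordinate duplicates into a Callset.

    Exact duplicates on (chrom, start, end) within one callset are collapsed
    to the first-seen record (set semantics for the redundancy analysis);
    the number collapsed is recorded under ``counters["dropped_duplicate"]``.
    """
    calls = sorted(calls, key=InversionCall.sort_key)
    kept: list[InversionCall] = []
    seen: set[tuple[str, int, int]] = set()
    dup = 0
    for c in calls:
        key = (c.chrom, c.start, c.end)
        if key in seen:
            dup += 1
            continue
        seen.add(key)
        kept.append(c)
    counters["dropped_duplicate"] = counters.get("dropped_duplicate", 0) + dup
    counters["kept"] = len(kept)
    prov = dict(provenance or {})
    prov["filter_counters"] = dict(counters)
    return Callset(dataset=dataset, calls=kept, genome_build=genome_build, provenance=prov)
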