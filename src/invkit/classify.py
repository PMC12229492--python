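"""Classification of inversion-gene intersections.

Every (inversion, gene) pair with at least one shared base falls into
exactly one of three categories, defined by where the inversion's two
breakpoints land relative to that gene's span:

* **gene_spanning** — neither breakpoint inside the gene; with a positive
  overlap this forces the gene to be fully contained in the inversion,
* **gene_disrupting** — exactly one breakpoint inside the gene (the
  mechanism behind splice-junction-disrupting pathogenic inversions),
* **intragenic** — both breakpoints inside the same gene, i.e. the
  inversion is contained in the gene; such events are further resolved
  against the canonical exon/intron structure, flagging those confined to
  a single intron.

Breakpoints are operationalized as the first and last inverted base
(``start`` and ``end - 1``), and a breakpoint equal to a gene's first or
last base counts as inside the gene. An inversion overlapping several genes
yields one record per gene, each classified independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gene_model import GeneModel
from .intervals import IntervalIndex, contains_point, overlap_length
from .model import Callset, InversionCall

__all__ = [
    "CATEGORIES",
    "IntersectionRecord",
    "classify_pair",
    "classify_callset",
    "classify_callset_bruteforce",
    "intron_context",
    "category_distribution",
    "records_to_frame",
]

CATEGORIES = ("gene_spanning", "gene_disrupting", "intragenic")


@dataclass(frozen=True)
class IntersectionRecord:
    """One overlapping (inversion, gene) pair with its category and context."""

    inversion_id: str
    gene_id: str
    dataset: str
    category: str
    breakpoints_in_gene: int
    introns_overlapped: int
    exons_overlapped: int
    single_intron: bool | None  # defined only for intragenic pairs
    disrupted_introns: tuple[int, ...]  # 1-based ordinals, 5'->3'

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "intragenic") != (self.single_intron is not None):
            raise ValueError("single_intron is defined exactly for intragenic pairs")


def _block_context(inv: InversionCall, gene: GeneModel):
    """Counts of exon/intron blocks overlapped plus strand-aware intron ordinals."""
    exons_hit = sum(
        1 for s, e in gene.exons if min(e, inv.end) - max(s, inv.start) > 0
    )
    intron_idx = [
        i
        for i, (s, e) in enumerate(gene.introns)
        if min(e, inv.end) - max(s, inv.start) > 0
    ]
    ordinals = tuple(sorted(gene.intron_ordinal(i) for i in intron_idx))
    return len(intron_idx), exons_hit, ordinals


def classify_pair(inv: InversionCall, gene: GeneModel) -> IntersectionRecord | None:
    """Classify one (inversion, gene) pair; None when they do not overlap."""
    if overlap_length(inv, gene) == 0:
        return None
    bp_first, bp_last = inv.start, inv.end - 1
    n_in = int(contains_point(gene, bp_first)) + int(contains_point(gene, bp_last))
    if n_in == 2:
        category = "intragenic"
    elif n_in == 1:
        category = "gene_disrupting"
    else:
        category = "gene_spanning"
    introns_n, exons_n, ordinals = _block_context(inv, gene)
    single = None
    if category == "intragenic":
        single = exons_n == 0 and introns_n == 1
    return IntersectionRecord(
        inversion_id=inv.id,
        gene_id=gene.gene_id,
        dataset=inv.dataset,
        category=category,
        breakpoints_in_gene=n_in,
        introns_overlapped=introns_n,
        exons_overlapped=exons_n,
        single_intron=single,
        disrupted_introns=ordinals,
    )


def intron_context(inv: InversionCall, gene: GeneModel):
    """Exon/intron context of an intragenic pair.

    Returns ``(introns_overlapped, exons_overlapped, single_intron,
    disrupted_introns)``; calling it on a non-intragenic pair is an error.
    """
    rec = classify_pair(inv, gene)
    if rec is None or rec.category != "intragenic":
        raise ValueError(
            f"intron_context requires an intragenic pair; "
            f"{inv.id} vs {gene.gene_id} is {rec.category if rec else 'non-overlapping'}"
        )
    return (
        rec.introns_overlapped,
        rec.exons_overlapped,
        rec.single_intron,
        rec.disrupted_introns,
    )


def classify_callset(cs: Callset, genes: list[GeneModel]) -> list[IntersectionRecord]:
    """Classify every overlapping (inversion, gene) pair in a callset.

    Uses an interval index over the genes; results are ordered by call
    order, then gene order, and match the brute-force all-pairs scan.
    """
    index = IntervalIndex(genes)
    out: list[IntersectionRecord] = []
    for inv in cs.calls:
        for gene in index.query(inv):
            rec = classify_pair(inv, gene)
            if rec is not None:
                out.append(rec)
    return out


def classify_callset_bruteforce(
    cs: Callset, genes: list[GeneModel]
) -> list[IntersectionRecord]:
    """All-pairs oracle for :func:`classify_callset` (no index involved)."""
    out = []
    for inv in cs.calls:
        for gene in genes:
            rec = classify_pair(inv, gene)
            if rec is not None:
                out.append(rec)
    return out


def records_to_frame(records: list[IntersectionRecord]) -> pd.DataFrame:
    """Tabular view of intersection records (one row per pair)."""
    return pd.DataFrame(
        [
            {
                "inversion_id": r.inversion_id,
                "gene_id": r.gene_id,
                "dataset": r.dataset,
                "category": r.category,
                "breakpoints_in_gene": r.breakpoints_in_gene,
                "introns_overlapped": r.introns_overlapped,
                "exons_overlapped": r.exons_overlapped,
                "single_intron": r.single_intron,
                "disrupted_introns": ",".join(map(str, r.disrupted_introns)),
            }
            for r in records
        ],
        columns=[
            "inversion_id",
            "gene_id",
            "dataset",
            "category",
            "breakpoints_in_gene",
            "introns_overlapped",
            "exons_overlapped",
            "single_intron",
            "disrupted_introns",
        ],
    )


def category_distribution(
    records: list[IntersectionRecord], per_dataset: bool = False
) -> pd.DataFrame:
    """Counts and percentages of intersection records per category.

    Percentages are over each dataset's own records when ``per_dataset``;
    within a dataset they sum to 100 up to rounding.
    """
    if not records:
        raise ValueError("no intersection records to summarize")
    df = records_to_frame(records)
    group = ["dataset", "category"] if per_dataset else ["category"]
    counts = df.groupby(group, sort=True).size().rename("n").reset_index()
    if per_dataset:
        totals = counts.groupby("dataset")["n"].transform("sum")
    else:
        totals = counts["n"].sum()
    counts["percent"] = 100.0 * counts["n"] / totals
    return counts
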