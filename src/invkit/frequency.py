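"""Allele-frequency stratification and the recessive-candidate funnel.

Inversions are split at an allele-frequency threshold (default 5%) into
rare (< threshold) and common (>= threshold); calls without a frequency form
a separate ``unknown`` stratum excluded from the rare/common percentages.

The candidate cascade mirrors how a potentially pathogenic recessive
inversion would be prioritized: keep pairs whose category can damage the
gene (gene_disrupting or intragenic), restrict to OMIM phenotype-linked
genes, restrict to rare inversions, flag those never observed homozygous,
and finally require an autosomal-recessive inheritance mode. The funnel is
reported at pair, distinct-inversion and distinct-gene granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import IntersectionRecord
from .gene_model import GeneAnnotation
from .model import Callset, InversionCall

__all__ = [
    "StratifyResult",
    "stratum_of",
    "stratify",
    "candidate_cascade",
    "omim_disruption_rates",
]

DAMAGING_CATEGORIES = ("gene_disrupting", "intragenic")


@dataclass(frozen=True)
class StratifyResult:
    threshold: float
    n_rare: int
    n_common: int
    n_unknown: int

    @property
    def n_known(self) -> int:
        return self.n_rare + self.n_common

    @property
    def pct_rare(self) -> float:
        """Percent rare over calls with a known frequency."""
        if self.n_known == 0:
            return float("nan")
        return 100.0 * self.n_rare / self.n_known

    @property
    def pct_common(self) -> float:
        if self.n_known == 0:
            return float("nan")
        return 100.0 * self.n_common / self.n_known


def stratum_of(call: InversionCall, threshold: float = 0.05) -> str:
    """'rare' (< threshold), 'common' (>= threshold) or 'unknown' (missing AF)."""
    af = call.allele_frequency
    if af is None:
        return "unknown"
    return "rare" if af < threshold else "common"


def stratify(cs: Callset, threshold: float = 0.05) -> StratifyResult:
    """Partition a callset into rare/common/unknown frequency strata."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    counts = {"rare": 0, "common": 0, "unknown": 0}
    for c in cs.calls:
        counts[stratum_of(c, threshold)] += 1
    return StratifyResult(
        threshold=threshold,
        n_rare=counts["rare"],
        n_common=counts["common"],
        n_unknown=counts["unknown"],
    )


def _funnel_row(stage: str, pairs: pd.DataFrame) -> dict:
    return {
        "stage": stage,
        "n_pairs": len(pairs),
        "n_inversions": pairs["inversion_id"].nunique(),
        "n_genes": pairs["gene_id"].nunique(),
    }


def candidate_cascade(
    records: list[IntersectionRecord],
    cs: Callset,
    annotations: dict[str, GeneAnnotation],
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive recessive-disease candidate inversions through a staged filter.

    Returns ``(candidates, funnel)``. ``candidates`` holds every pair
    surviving the rare stage, with ``never_homozygous`` True/False (or
    missing when the callset has no homozygote counts) and an
    ``ar_candidate`` flag for the final set (never homozygous AND the gene
    has an AR mode). ``funnel`` gives pair/inversion/gene counts per stage;
    the counts are non-increasing down the stages.
    """
    calls = {c.id: c for c in cs.calls}
    rows = []
    for r in records:
        inv = calls.get(r.inversion_id)
        if inv is None:
            continue
        ann = annotations.get(r.gene_id)
        rows.append(
            {
                "inversion_id": r.inversion_id,
                "gene_id": r.gene_id,
                "category": r.category,
                "omim_status": ann.omim_status if ann else "not_in_omim",
                "inheritance_modes": ";".join(sorted(ann.inheritance_modes)) if ann else "",
                "stratum": stratum_of(inv, threshold),
                "never_homozygous": (inv.n_homalt == 0) if inv.n_homalt is not None else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "inversion_id",
            "gene_id",
            "category",
            "omim_status",
            "inheritance_modes",
            "stratum",
            "never_homozygous",
        ],
    )
    funnel = [_funnel_row("all_pairs", df)]
    s1 = df[df["category"].isin(DAMAGING_CATEGORIES)]
    funnel.append(_funnel_row("disrupting_or_intragenic", s1))
    s2 = s1[s1["omim_status"] == "phenotype_linked"]
    funnel.append(_funnel_row("omim_phenotype_linked", s2))
    s3 = s2[s2["stratum"] == "rare"]
    funnel.append(_funnel_row("rare", s3))
    s4 = s3[s3["never_homozygous"] == True]  # noqa: E712 — None must not pass
    funnel.append(_funnel_row("never_homozygous", s4))
    is_ar = s4["inheritance_modes"].str.split(";").apply(lambda m: "AR" in m)
    s5 = s4[is_ar] if len(s4) else s4
    funnel.append(_funnel_row("ar_gene", s5))

    candidates = s3.copy()
    ar_keys = set(zip(s5["inversion_id"], s5["gene_id"])) if len(s5) else set()
    candidates["ar_candidate"] = [
        (i, g) in ar_keys
        for i, g in zip(candidates["inversion_id"], candidates["gene_id"])
    ]
    return candidates.reset_index(drop=True), pd.DataFrame(funnel)


def omim_disruption_rates(
    records: list[IntersectionRecord],
    annotations: dict[str, GeneAnnotation],
) -> pd.DataFrame:
    """Fraction of each OMIM class disrupted by at least one damaging record.

    For every OMIM status class the numerator is the number of distinct
    genes of that class carrying >= 1 gene_disrupting or intragenic record;
    the denominator is the class size in the annotation universe.
    """
    if not annotations:
        raise ValueError("empty gene universe")
    class_size: dict[str, int] = {}
    for a in annotations.values():
        class_size[a.omim_status] = class_size.get(a.omim_status, 0) + 1
    hit: dict[str, set[str]] = {}
    for r in records:
        if r.category not in DAMAGING_CATEGORIES:
            continue
        ann = annotations.get(r.gene_id)
        if ann is None:
            continue
        hit.setdefault(ann.omim_status, set()).add(r.gene_id)
    rows = []
    for status, size in sorted(class_size.items()):
        n_hit = len(hit.get(status, set()))
        rows.append(
            {
                "omim_status": status,
                "n_genes_hit": n_hit,
                "class_size": size,
                "percent_hit": 100.0 * n_hit / size,
            }
        )
    return pd.DataFrame(rows)
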