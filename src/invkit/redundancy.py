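"""Cross-dataset redundancy of inversion callsets.

Two matching criteria are supported:

* ``exact`` — stringent: identical (chrom, start, end),
* ``fraction`` — relaxed: the overlap must cover at least fraction ``f``
  (default 0.5) of the *query* inversion's length. Matching is directional,
  so the redundancy matrix is generally asymmetric — a short inversion can
  be half-covered by a long one whose own 50% requirement fails. A
  reciprocal mode (both directions must pass) is available behind a flag.

Matching is existential: an inversion is "matched in dataset B" when at
least one partner passes, with no one-to-one assignment. An inversion is
dataset-specific when it is unmatched in every other callset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalIndex, overlaps_fraction
from .model import Callset

__all__ = [
    "match_exact",
    "match_fraction",
    "match_fraction_bruteforce",
    "RedundancyMatrix",
    "redundancy_matrix",
]


def match_exact(a: Callset, b: Callset) -> list[bool]:
    """Per-inversion flags: does each call in ``a`` have an identical-coordinate
    partner in ``b``?"""
    keys = {(c.chrom, c.start, c.end) for c in b.calls}
    return [(c.chrom, c.start, c.end) in keys for c in a.calls]


def match_fraction(
    a: Callset, b: Callset, f: float = 0.5, *, reciprocal: bool = False
) -> list[bool]:
    """Per-inversion flags under the fractional-overlap criterion.

    Directional by default: call ``x`` in ``a`` matches when some ``y`` in
    ``b`` covers >= ``f`` of ``x``. With ``reciprocal=True`` the partner
    must also be covered to fraction ``f`` by ``x``.
    """
    index = IntervalIndex(b.calls)
    out = []
    for x in a.calls:
        if reciprocal:
            matched = any(
                overlaps_fraction(y, x, f) for y in index.query(x, f)
            )
        else:
            matched = index.any_match(x, f)
        out.append(matched)
    return out


def match_fraction_bruteforce(
    a: Callset, b: Callset, f: float = 0.5, *, reciprocal: bool = False
) -> list[bool]:
    """All-pairs oracle with semantics identical to :func:`match_fraction`."""
    out = []
    for x in a.calls:
        matched = False
        for y in b.calls:
            if overlaps_fraction(x, y, f) and (
                not reciprocal or overlaps_fraction(y, x, f)
            ):
                matched = True
                break
        out.append(matched)
    return out


@dataclass
class RedundancyMatrix:
    """Directional percent-shared matrix plus per-inversion membership profiles."""

    datasets: tuple[str, ...]
    percent: pd.DataFrame  # rows: query dataset a; cols: subject dataset b
    membership: pd.DataFrame  # one row per inversion with per-dataset match flags
    criterion: str

    def percent_of(self, a: str, b: str) -> float:
        return float(self.percent.loc[a, b])


def redundancy_matrix(
    callsets: list[Callset],
    criterion: str = "fraction",
    f: float = 0.5,
    *,
    reciprocal: bool = False,
) -> RedundancyMatrix:
    """Full directional redundancy matrix over >= 2 callsets.

    ``percent[a][b]`` is the percentage of a's inversions with at least one
    match in b (100 on the diagonal by construction). ``membership`` lists,
    for every inversion, which other datasets it matches, the number of such
    datasets, and whether it is dataset-specific — the upset-style counts.
    """
    if len(callsets) < 2:
        raise ValueError("redundancy requires at least two callsets")
    labels = tuple(cs.dataset for cs in callsets)
    if len(set(labels)) != len(labels):
        raise ValueError("callset dataset labels must be unique")
    if criterion not in ("exact", "fraction"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def matcher(a: Callset, b: Callset) -> list[bool]:
        if criterion == "exact":
            return match_exact(a, b)
        return match_fraction(a, b, f, reciprocal=reciprocal)

    pct = pd.DataFrame(
        np.zeros((len(labels), len(labels))), index=labels, columns=labels
    )
    flags: dict[tuple[str, str], list[bool]] = {}
    for a in callsets:
        for b in callsets:
            m = [True] * len(a) if a.dataset == b.dataset else matcher(a, b)
            flags[(a.dataset, b.dataset)] = m
            pct.loc[a.dataset, b.dataset] = (
                100.0 * sum(m) / len(a) if len(a) else float("nan")
            )

    rows = []
    for a in callsets:
        others = [b for b in labels if b != a.dataset]
        for i, call in enumerate(a.calls):
            matched_in = [b for b in others if flags[(a.dataset, b)][i]]
            rows.append(
                {
                    "dataset": a.dataset,
                    "inversion_id": call.id,
                    "n_other_datasets_matched": len(matched_in),
                    "matched_in": ";".join(matched_in),
                    "dataset_specific": not matched_in,
                }
            )
    membership = pd.DataFrame(
        rows,
        columns=[
            "dataset",
            "inversion_id",
            "n_other_datasets_matched",
            "matched_in",
            "dataset_specific",
        ],
    )
    crit_label = "exact" if criterion == "exact" else f"fraction({f})"
    return RedundancyMatrix(
        datasets=labels, percent=pct, membership=membership, criterion=crit_label
    )
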