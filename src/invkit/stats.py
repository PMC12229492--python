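"""Summary statistics and the hypothesis tests used in the inversion analysis.

The test statistics here are implemented from first principles — exact
rank-sum enumeration, exact binomial (minimum-likelihood two-sided rule),
hypergeometric/Fisher tails, Benjamini-Hochberg — and are cross-checked
against independent enumeration oracles in the test suite. Only the normal
CDF for the large-sample rank-sum approximation comes from scipy.

Quantiles default to linear interpolation (the "type 7" definition used by
the default quantile of mainstream statistical environments); "type 6" is
available behind a flag since published quartiles depend on the definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import IntersectionRecord
from .gene_model import GeneAnnotation, INHERITANCE_MODES, inheritance_background
from .model import Callset

__all__ = [
    "LengthSummary",
    "TestResult",
    "length_summary",
    "wilcoxon_rank_sum",
    "binomial_test",
    "fisher_exact",
    "benjamini_hochberg",
    "overrepresentation",
    "inheritance_distribution",
]

_QUANTILE_METHODS = {"type7": "linear", "type6": "weibull"}


@dataclass(frozen=True)
class LengthSummary:
    """Six-number length summary of a callset, in kb."""

    dataset: str
    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def length_summary(cs: Callset, quantile_type: str = "type7") -> LengthSummary:
    """Min / Q1 / median / mean / Q3 / max of inversion lengths, in kb."""
    if len(cs) == 0:
        raise ValueError(f"callset {cs.dataset} is empty")
    method = _QUANTILE_METHODS.get(quantile_type)
    if method is None:
        raise ValueError(f"unknown quantile type {quantile_type!r}")
    kb = np.array([c.length for c in cs.calls], dtype=float) / 1000.0
    q1, med, q3 = np.quantile(kb, [0.25, 0.5, 0.75], method=method)
    return LengthSummary(
        dataset=cs.dataset,
        n=len(cs),
        min=float(kb.min()),
        q1=float(q1),
        median=float(med),
        mean=float(kb.mean()),
        q3=float(q3),
        max=float(kb.max()),
    )


def _rank_sum_counts(n: int, N: int) -> np.ndarray:
    """counts[s] = number of n-subsets of ranks 1..N with rank sum s."""
    max_s = N * (N + 1) // 2
    dp = np.zeros((n + 1, max_s + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        # descending k: each rank used at most once
        for k in range(min(n, r), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    return dp[n]


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided two-sample rank-sum (Mann-Whitney / Wilcoxon) test.

    ``exact`` enumerates the null rank-sum distribution (valid without
    ties); ``normal`` uses the tie-corrected normal approximation with
    continuity correction; ``auto`` picks exact when there are no ties and
    n*m <= 10_000.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    N = n + m
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < N
    if mode == "auto":
        mode = "normal" if (has_ties or n * m > 10_000) else "exact"
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty(N)
    ranks[order] = np.arange(1, N + 1, dtype=float)
    # midranks for ties
    vals, inv, counts = np.unique(combined, return_inverse=True, return_counts=True)
    if has_ties:
        cum = np.cumsum(counts)
        mid = cum - (counts - 1) / 2.0
        ranks = mid[inv]
    W = float(ranks[:n].sum())

    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free samples")
        counts_s = _rank_sum_counts(n, N)
        total = math.comb(N, n)
        w = int(round(W))
        p_le = counts_s[: w + 1].sum() / total
        p_ge = counts_s[w:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(W, p, "wilcoxon_rank_sum_exact", (n, m))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n * (N + 1) / 2.0
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult(W, 1.0, "wilcoxon_rank_sum_normal", (n, m))
    z = (W - mu - math.copysign(0.5, W - mu)) / math.sqrt(var) if W != mu else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TestResult(W, p, "wilcoxon_rank_sum_normal", (n, m))


def _binom_logpmf(x: np.ndarray, n: int, p0: float) -> np.ndarray:
    x = np.asarray(x)
    logc = (
        np.vectorize(math.lgamma)(n + 1)
        - np.vectorize(math.lgamma)(x + 1)
        - np.vectorize(math.lgamma)(n - x + 1)
    )
    return logc + x * math.log(p0) + (n - x) * math.log1p(-p0)


def binomial_test(
    k: int, n: int, p0: float, alternative: str = "two-sided"
) -> TestResult:
    """Exact binomial test of k successes in n trials against probability p0.

    The two-sided p-value follows the minimum-likelihood ("small-P") rule:
    the sum of P(x) over all outcomes no more probable than the observed
    one. A ``central`` alternative (twice the smaller tail, capped at 1) is
    available, as are one-sided tails.
    """
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside 0..n={n}")
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must lie in (0,1), got {p0}")
    xs = np.arange(n + 1)
    pmf = np.exp(_binom_logpmf(xs, n, p0))
    p_le = float(pmf[: k + 1].sum())
    p_ge = float(pmf[k:].sum())
    if alternative == "less":
        p = p_le
    elif alternative == "greater":
        p = p_ge
    elif alternative == "central":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "two-sided":
        cutoff = pmf[k] * (1 + 1e-7)  # relative tolerance against float noise
        p = float(pmf[pmf <= cutoff].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(k), min(1.0, p), f"binomial_{alternative}", (n,))


def _hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P[X = k] drawing n from N with K marked, exact rational -> float."""
    if k < max(0, n - (N - K)) or k > min(n, K):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def fisher_exact(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    ``greater`` is the enrichment direction for a table laid out as
    [[in_set_and_hit, in_set_not_hit], [hit_not_in_set, neither]]; the
    two-sided p sums all tables no more probable than the observed one.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N = a + b + c + d
    if N == 0:
        raise ValueError("empty table")
    K, n = a + b, a + c
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = {x: _hypergeom_pmf(x, N, K, n) for x in range(lo, hi + 1)}
    if alternative == "greater":
        p = sum(v for x, v in pmf.items() if x >= a)
    elif alternative == "less":
        p = sum(v for x, v in pmf.items() if x <= a)
    elif alternative == "two-sided":
        cutoff = pmf[a] * (1 + 1e-7)
        p = sum(v for v in pmf.values() if v <= cutoff)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(a), min(1.0, p), f"fisher_exact_{alternative}", (N,))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def overrepresentation(
    gene_hits: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation analysis of a hit list against named gene sets.

    One-sided Fisher exact (hypergeometric upper tail) per gene set,
    Benjamini-Hochberg adjusted across the sets.
    """
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(gene_hits) & universe
    rows = []
    for name, gset in gene_sets.items():
        gset = set(gset) & universe
        k = len(hits & gset)
        res = fisher_exact(
            [
                [k, len(gset) - k],
                [len(hits) - k, len(universe) - len(gset) - len(hits) + k],
            ],
            alternative="greater",
        )
        rows.append(
            {
                "gene_set": name,
                "n_hits_in_set": k,
                "set_size": len(gset),
                "n_hits": len(hits),
                "universe_size": len(universe),
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    return df


def inheritance_distribution(
    records: list[IntersectionRecord],
    annotations: dict[str, GeneAnnotation],
    category: str,
) -> tuple[pd.DataFrame, TestResult]:
    """Inheritance-mode distribution of phenotype-linked genes hit in a category.

    Counts distinct phenotype-linked genes per mode among records of the
    given category (a gene with several modes counts once per mode), and
    tests the observed AR gene count against the AR proportion of the whole
    phenotype-linked OMIM background with an exact binomial test.
    """
    genes = {
        r.gene_id
        for r in records
        if r.category == category
        and annotations.get(r.gene_id) is not None
        and annotations[r.gene_id].omim_status == "phenotype_linked"
    }
    if not genes:
        raise ValueError(f"no phenotype-linked genes hit in category {category!r}")
    counts = {m: 0 for m in INHERITANCE_MODES}
    for g in genes:
        for m in annotations[g].inheritance_modes:
            counts[m] += 1
    n = len(genes)
    table = pd.DataFrame(
        {
            "mode": list(counts),
            "n_genes": list(counts.values()),
            "percent": [100.0 * c / n for c in counts.values()],
        }
    ).set_index("mode")
    background = inheritance_background(annotations)
    p_ar = float(background.loc["AR", "proportion"])
    if not (0 < p_ar < 1):
        # degenerate backgrounds (all or no AR) make the test vacuous
        result = TestResult(float(counts["AR"]), 1.0, "binomial_two-sided", (n,))
    else:
        result = binomial_test(counts["AR"], n, p_ar, alternative="two-sided")
    return table, result
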