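"""Length summaries and first-principles test statistics vs independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as scipy_stats

from invkit.gene_model import GeneAnnotation
from invkit.model import Callset
from invkit.stats import (
    benjamini_hochberg,
    binomial_test,
    fisher_exact,
    inheritance_distribution,
    length_summary,
    overrepresentation,
    wilcoxon_rank_sum,
)

from conftest import make_call, make_callset_from


def kb_callset(kbs, dataset="d"):
    coords = [("chr1", 10_000_000 * i, 10_000_000 * i + int(kb * 1000)) for i, kb in enumerate(kbs)]
    return make_callset_from(coords, dataset)


class TestLengthSummary:
    def test_type7_interpolation_on_four_points(self):
        s = length_summary(kb_callset([1, 2, 3, 4]))
        assert (s.q1, s.median, s.q3) == (1.75, 2.5, 3.25)
        assert s.mean == 2.5 and (s.min, s.max) == (1.0, 4.0)

    def test_single_inversion_collapses_all_statistics(self):
        s = length_summary(kb_callset([7.5]))
        assert s.min == s.q1 == s.median == s.mean == s.q3 == s.max == 7.5

    def test_constant_lengths(self):
        s = length_summary(kb_callset([5, 5, 5]))
        assert s.q1 == s.q3 == s.median == s.mean == 5.0

    def test_type6_flag_changes_quartiles(self):
        cs = kb_callset([1, 2, 3, 4])
        s6 = length_summary(cs, "type6")
        assert (s6.q1, s6.q3) == (1.25, 3.75)

    def test_empty_callset_is_hard_error(self):
        with pytest.raises(ValueError):
            length_summary(Callset("d", []))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(0)
        s = length_summary(kb_callset(rng.lognormal(2, 1, 50).round(3) + 0.001))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


def enumerate_rank_sum_pvalue(x, y):
    """Independent oracle: full enumeration over all C(n+m, n) rank splits."""
    n, m = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == n + m, "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    w_obs = sum(ranks[v] for v in x)
    sums = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    p_le = sum(s <= w_obs for s in sums) / len(sums)
    p_ge = sum(s >= w_obs for s in sums) / len(sums)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_minimal_exact_case(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert res.p_value == pytest.approx(1 / 3, abs=1e-15)

    def test_identical_samples_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="normal")
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_constant_samples_warn(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0], mode="normal")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        x = list(rng.permutation(np.arange(n + m) + 1.0)[:n])
        y = [v for v in np.arange(n + m) + 1.0 if v not in x]
        mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
        assert mine == pytest.approx(enumerate_rank_sum_pvalue(x, y), abs=1e-12)

    def test_exact_and_normal_agree_at_moderate_n(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(loc=0.5, size=7)
            pe = wilcoxon_rank_sum(x, y, mode="exact").p_value
            pn = wilcoxon_rank_sum(x, y, mode="normal").p_value
            assert abs(pe - pn) < 0.02

    def test_tied_data_falls_back_to_corrected_normal(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 6.0]
        res = wilcoxon_rank_sum(x, y)  # auto
        assert res.method == "wilcoxon_rank_sum_normal"
        ref = scipy_stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (2, 2, 0.5, 0.5),  # outcomes 0 and 2 are equally improbable
            (0, 10, 0.5, 2 / 1024),  # both extreme tails
            (5, 10, 0.5, 1.0),  # observing the mode
        ],
    )
    def test_closed_form_cases(self, k, n, p0, expected):
        assert binomial_test(k, n, p0).p_value == pytest.approx(expected, abs=1e-12)

    def test_one_sided_tails_sum_properly(self):
        r_less = binomial_test(3, 20, 0.4, "less").p_value
        ref = sum(math.comb(20, x) * 0.4**x * 0.6 ** (20 - x) for x in range(4))
        assert r_less == pytest.approx(ref, abs=1e-12)

    def test_matches_scipy_small_p_convention(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert binomial_test(k, n, p0).p_value == pytest.approx(
                scipy_stats.binomtest(k, n, p0).pvalue, abs=1e-10
            )

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            binomial_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_test(1, 4, 0.0)


class TestFisherAndOra:
    def test_two_sided_hand_case(self):
        assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2)).tolist()
            if sum(map(sum, t)) == 0:
                continue
            for alt in ("two-sided", "greater", "less"):
                assert fisher_exact(t, alt).p_value == pytest.approx(
                    scipy_stats.fisher_exact(t, alt)[1], abs=1e-10
                )

    def test_disjoint_hits_give_p_one_for_enrichment(self):
        universe = {f"g{i}" for i in range(40)}
        df = overrepresentation({"g0", "g1"}, {"set": {"g10", "g11"}}, universe)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_enriched_set_detected(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        sets = {"enriched": {f"g{i}" for i in range(8)}, "random": {f"g{i}" for i in range(50, 58)}}
        df = overrepresentation(hits, sets, universe).set_index("gene_set")
        assert df.loc["enriched", "p_value"] < 1e-6 < df.loc["random", "p_value"]

    def test_empty_universe_is_hard_error(self):
        with pytest.raises(ValueError):
            overrepresentation(set(), {"s": set()}, set())


class TestBenjaminiHochberg:
    def test_step_up_closed_form(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_general_closed_form(self):
        p = [0.005, 0.04, 0.03, 0.8]
        # sorted: 0.005*4/1=0.02, 0.03*4/3=0.04, 0.04*4/3... step-up from the top
        q = benjamini_hochberg(p)
        assert q == pytest.approx([0.02, 0.0533333333, 0.0533333333, 0.8])

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()


class TestInheritanceDistribution:
    def world(self, n_ar_hit, n_ad_hit, bg_ar=30, bg_ad=70):
        from invkit.classify import IntersectionRecord

        annotations = {}
        for i in range(bg_ar):
            annotations[f"R{i}"] = GeneAnnotation(f"R{i}", "phenotype_linked", frozenset({"AR"}))
        for i in range(bg_ad):
            annotations[f"D{i}"] = GeneAnnotation(f"D{i}", "phenotype_linked", frozenset({"AD"}))
        records = [
            IntersectionRecord(f"i{j}", gid, "d", "intragenic", 2, 1, 0, True, (1,))
            for j, gid in enumerate(
                [f"R{i}" for i in range(n_ar_hit)] + [f"D{i}" for i in range(n_ad_hit)]
            )
        ]
        return records, annotations

    def test_percentages_over_distinct_genes(self):
        records, annotations = self.world(5, 5)
        table, _ = inheritance_distribution(records, annotations, "intragenic")
        assert table.loc["AR", "percent"] == pytest.approx(50.0)
        assert table.loc["AR", "n_genes"] == 5

    def test_observed_equal_to_background_gives_large_p(self):
        records, annotations = self.world(6, 14)  # 30% AR matches the background
        _, res = inheritance_distribution(records, annotations, "intragenic")
        assert res.p_value > 0.5

    def test_planted_ar_enrichment_detected_in_most_replicates(self):
        """Sampling AR genes at twice their background rate yields p < 0.05
        in >= 95% of seeded replicates."""
        rng = np.random.default_rng(123)
        detected = 0
        n_replicates = 100
        for _ in range(n_replicates):
            n_hit = 80
            # background AR proportion is 40/200 = 0.2; hits drawn at 0.4
            ar = min(int(rng.binomial(n_hit, 0.4)), 40)
            records, annotations = self.world(ar, n_hit - ar, bg_ar=40, bg_ad=160)
            _, res = inheritance_distribution(records, annotations, "intragenic")
            detected += res.p_value < 0.05
        assert detected >= 95

    def test_no_linked_genes_hit_is_hard_error(self):
        records, annotations = self.world(1, 0)
        with pytest.raises(ValueError):
            inheritance_distribution(records, annotations, "gene_spanning")
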