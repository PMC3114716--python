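import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trailkit.categories import CategoryCollection, GeneCategory
from trailkit.gsea import exact_p, gsea_test, permutation_p, running_sum
from trailkit.preprocess import RankedGeneList


def ranked_list(n: int) -> RankedGeneList:
    return RankedGeneList(
        genes=[f"g{i:03d}" for i in range(n)],
        scores=np.arange(n, 0, -1, dtype=float),
        comparison="toy",
    )


def category(ranks: set[int], n: int, name: str = "cat") -> GeneCategory:
    """Category whose members sit at the given 1-based ranks of ranked_list(n)."""
    return GeneCategory(name, frozenset(f"g{r - 1:03d}" for r in ranks))


def brute_force_p(n: int, k: int, d: int) -> float:
    """Enumerate all C(n, k) member placements and count max |RS| >= d."""
    hits = 0
    for pos in itertools.combinations(range(n), k):
        members = set(pos)
        rs, peak = 0, 0
        for i in range(n):
            rs += (n - k) if i in members else -k
            peak = max(peak, abs(rs))
        if peak >= d:
            hits += 1
    return hits / math.comb(n, k)


class TestRunningSum:
    def test_top_concentrated_profile(self):
        prof = running_sum(ranked_list(6), category({1, 2}, 6))
        np.testing.assert_array_equal(prof.rs, [4, 8, 6, 4, 2, 0])
        assert prof.max_abs_deviation == 8
        assert prof.sign_at_max == "+"
        assert not prof.ambiguous

    def test_bottom_concentrated_profile(self):
        prof = running_sum(ranked_list(6), category({5, 6}, 6))
        np.testing.assert_array_equal(prof.rs, [-2, -4, -6, -8, -4, 0])
        assert prof.max_abs_deviation == 8
        assert prof.sign_at_max == "-"

    def test_category_equal_to_list_is_flat(self):
        prof = running_sum(ranked_list(5), category({1, 2, 3, 4, 5}, 5))
        np.testing.assert_array_equal(prof.rs, np.zeros(5, dtype=int))
        assert prof.max_abs_deviation == 0

    def test_disjoint_category_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            running_sum(ranked_list(4), GeneCategory("x", frozenset({"absent"})))

    def test_both_signs_attained_flags_ambiguous(self):
        # n=4, k=2, members at ranks {1, 4}: RS = [2, 0, -2, 0]
        prof = running_sum(ranked_list(4), category({1, 4}, 4))
        assert prof.max_abs_deviation == 2
        assert prof.ambiguous
        assert prof.sign_at_max == "+"  # first excursion decides


class TestExactP:
    def test_worked_example(self):
        assert exact_p(6, 2, 8) == pytest.approx(2 / 15, abs=1e-12)

    @pytest.mark.parametrize("n,k", [(5, 1), (6, 2), (7, 3), (9, 4)])
    def test_zero_threshold_is_certain(self, n, k):
        assert exact_p(n, k, 0) == 1.0

    def test_unattainable_deviation_has_probability_zero(self):
        assert exact_p(6, 2, 9) == 0.0

    @pytest.mark.parametrize("n,k", [(8, 3), (10, 4), (12, 5)])
    def test_matches_enumeration(self, n, k):
        deviations = sorted({abs(j * n - i * k) for i in range(1, n + 1) for j in range(k + 1)})
        for d in deviations:
            assert exact_p(n, k, d) == pytest.approx(brute_force_p(n, k, d), abs=1e-12)

    @given(st.integers(2, 40), st.data())
    def test_monotone_non_increasing_in_d(self, n, data):
        k = data.draw(st.integers(1, n))
        dmax = k * (n - k)
        ds = sorted(data.draw(st.lists(st.integers(0, dmax + 1), min_size=2, max_size=6)))
        ps = [exact_p(n, k, d) for d in ds]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_non_integer_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_p(6.5, 2, 3)
        with pytest.raises(ValueError):
            exact_p(6, 2, 3.3)

    def test_large_list_small_category_is_finite_and_sane(self):
        p = exact_p(5000, 8, 3000 * 8)
        assert 0.0 <= p <= 1.0


class TestPermutationP:
    def test_same_seed_reproducible(self):
        rl, cat = ranked_list(30), category(set(range(1, 7)), 30)
        assert permutation_p(rl, cat, n_perm=500, seed=11) == permutation_p(
            rl, cat, n_perm=500, seed=11
        )

    def test_flat_profile_gives_one(self):
        rl = ranked_list(4)
        assert permutation_p(rl, category({1, 2, 3, 4}, 4), n_perm=50, seed=0) == 1.0

    def test_agrees_with_exact_within_binomial_error(self):
        rl, cat = ranked_list(6), category({1, 2}, 6)
        n_perm = 20_000
        p_true = 2 / 15
        se = math.sqrt(p_true * (1 - p_true) / n_perm)
        assert permutation_p(rl, cat, n_perm=n_perm, seed=5) == pytest.approx(
            p_true, abs=3 * se
        )


class TestGseaTest:
    def test_min_size_filter_excludes_singletons(self):
        coll = CategoryCollection(
            {
                "solo": category({1}, 6, "solo"),
                "pair": category({1, 2}, 6, "pair"),
            },
            namespace="gene",
        )
        results = gsea_test(ranked_list(6), coll, min_size=2)
        assert [r.category for r in results] == ["pair"]

    def test_whole_list_category_reported_once_with_p_one(self):
        coll = CategoryCollection(
            {"all": category(set(range(1, 7)), 6, "all")}, namespace="gene"
        )
        results = gsea_test(ranked_list(6), coll)
        assert len(results) == 1
        assert results[0].max_abs_deviation == 0
        assert results[0].p_raw == 1.0

    def test_null_symmetry_of_top_and_bottom_categories(self):
        coll = CategoryCollection(
            {
                "top": category({1, 2}, 6, "top"),
                "bottom": category({5, 6}, 6, "bottom"),
            },
            namespace="gene",
        )
        by = {r.category: r for r in gsea_test(ranked_list(6), coll)}
        assert by["top"].p_raw == pytest.approx(by["bottom"].p_raw)
        assert by["top"].direction == "enriched"
        assert by["bottom"].direction == "depleted"

    def test_reversing_the_list_preserves_p_and_flips_direction(self):
        rl = ranked_list(12)
        rev = RankedGeneList(
            genes=list(reversed(rl.genes)), scores=rl.scores, comparison="rev"
        )
        coll = CategoryCollection(
            {"c": category({1, 2, 4}, 12, "c")}, namespace="gene"
        )
        fwd = gsea_test(rl, coll)[0]
        bwd = gsea_test(rev, coll)[0]
        assert fwd.max_abs_deviation == bwd.max_abs_deviation
        assert fwd.p_raw == pytest.approx(bwd.p_raw)
        assert {fwd.direction, bwd.direction} == {"enriched", "depleted"}

    def test_permutation_fallback_engages_above_cell_budget(self):
        coll = CategoryCollection(
            {"c": category({1, 2, 3}, 50, "c")}, namespace="gene"
        )
        results = gsea_test(ranked_list(50), coll, max_dp_cells=10, n_perm=200, seed=3)
        assert results[0].method == "permutation"
        assert 0 < results[0].p_raw <= 1
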