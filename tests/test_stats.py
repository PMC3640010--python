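"""Exact rank-sum / signed-rank tests and stratified contingencies."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from episelect import (
    IMPROVEMENT_ONLY,
    SEIZURE_FREE,
    exact_rank_sum_test,
    exact_signed_rank_test,
    rank_table,
    stratified_contingency,
)

from conftest import make_cohort


def enumeration_rank_sum_p(a, b):
    """Oracle: exact two-sided p by enumerating all C(n, n1) assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    n1 = min(len(a), len(b))
    obs = ranks[: len(a)].sum() if len(a) <= len(b) else ranks[len(a):].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(n), n1)]
    sums = np.array(sums)
    lo = (sums <= obs + 1e-9).mean()
    hi = (sums >= obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_identical_constant_groups(self):
        res = exact_rank_sum_test([2, 2, 2], [2, 2])
        assert res.p_two_sided == 1.0

    def test_three_permutation_example(self):
        res = exact_rank_sum_test([1, 2], [3])
        assert res.p_two_sided == pytest.approx(2 / 3)

    def test_binary_side_configuration(self):
        """5 Left improvements vs 5 Left + 9 Right seizure-free."""
        a = [1] * 5  # improvement group, all Left
        b = [1] * 5 + [2] * 9
        res = exact_rank_sum_test(a, b)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2 * 252 / 11628, abs=1e-12)

    def test_agrees_with_full_enumeration_on_tied_data(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(5, 12))
            n1 = int(rng.integers(2, n - 1))
            vals = rng.integers(1, 4, size=n)  # heavy ties
            a, b = vals[:n1], vals[n1:]
            res = exact_rank_sum_test(a, b)
            assert res.p_two_sided == pytest.approx(
                enumeration_rank_sum_p(a, b), abs=1e-12
            )

    def test_invariant_under_monotone_recoding(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(1, 5, size=6)
            b = rng.integers(1, 5, size=4)
            p1 = exact_rank_sum_test(a, b).p_two_sided
            recode = {1: 10, 2: 20, 3: 25, 4: 100}
            p2 = exact_rank_sum_test(
                [recode[v] for v in a], [recode[v] for v in b]
            ).p_two_sided
            assert p1 == pytest.approx(p2, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 5), (4, 4)])
    def test_untied_boundaries_match_reference_distribution(self, n1, n2):
        """Without ties the exact p equals the classical Wilcoxon tables
        (scipy's exact Mann-Whitney as reference)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = rng.permutation(n1 + n2) + 1.0  # no ties
            a, b = vals[:n1], vals[n1:]
            res = exact_rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_two_sided_p_at_least_point_mass(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = rng.integers(1, 4, size=5)
            b = rng.integers(1, 4, size=4)
            res = exact_rank_sum_test(a, b)
            assert 0 < res.p_two_sided <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            exact_rank_sum_test([], [1, 2])


class TestRankSumProperties:
    """Property-based checks of the exact rank-sum distribution."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.integers(min_value=1, max_value=3), min_size=2, max_size=6),
        st.lists(st.integers(min_value=1, max_value=3), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_equals_enumeration(self, a, b):
        res = exact_rank_sum_test(a, b)
        assert res.p_two_sided == pytest.approx(
            enumeration_rank_sum_p(a, b), abs=1e-12
        )
        assert 0 < res.p_two_sided <= 1

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=2, max_size=8),
        st.lists(st.integers(min_value=1, max_value=5), min_size=2, max_size=8),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_in_group_order(self, a, b):
        assert exact_rank_sum_test(a, b).p_two_sided == pytest.approx(
            exact_rank_sum_test(b, a).p_two_sided, abs=1e-12
        )


class TestSignedRank:
    def test_all_zero_deltas(self):
        res = exact_signed_rank_test([0, 0, 0])
        assert res.p_two_sided == 1.0
        assert res.n1 == 0

    def test_three_positive_deltas(self):
        res = exact_signed_rank_test([1, 2, 3])
        assert res.p_two_sided == pytest.approx(0.25)

    def test_symmetric_pair_with_midranks(self):
        res = exact_signed_rank_test([1, -1])
        assert res.p_two_sided == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            m = int(rng.integers(4, 10))
            mags = rng.permutation(m) + 1.0
            signs = rng.choice([-1, 1], size=m)
            d = mags * signs
            res = exact_signed_rank_test(d)
            ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)


class TestContingency:
    def test_reconstructed_side_and_pstyle(self, results_cohort):
        side = stratified_contingency(results_cohort, "Side")
        assert side.rows == {"Left": (5, 5), "Right": (9, 0)}
        ps = stratified_contingency(results_cohort, "P.Style")
        assert ps.rows == {"EB1": (3, 0), "EB2": (11, 2), "EB3": (0, 3)}
        assert ps.totals == (14, 5)

    def test_single_category_feature(self):
        cohort = make_cohort(
            {"f": ["A"] * 19},
            [SEIZURE_FREE] * 14 + [IMPROVEMENT_ONLY] * 5,
        )
        assert stratified_contingency(cohort, "f").rows == {"A": (14, 5)}

    def test_unknown_feature_rejected(self, results_cohort):
        with pytest.raises(KeyError):
            stratified_contingency(results_cohort, "nope")


class TestRankTable:
    def test_discriminative_features_flagged(self, results_cohort):
        df = rank_table(results_cohort)
        flagged = set(df[df["significant"]]["feature"])
        assert flagged == {"Side", "P.Style", "PIQ"}
        assert list(df["p"]) == sorted(df["p"])

    def test_single_feature_report(self):
        cohort = make_cohort(
            {"f": ["A", "B", "A", "B"]},
            [SEIZURE_FREE, SEIZURE_FREE, IMPROVEMENT_ONLY, IMPROVEMENT_ONLY],
        )
        df = rank_table(cohort)
        assert len(df) == 1

    def test_type_one_error_rate_on_noise(self):
        """About 5% of independent noise features reject at alpha = 0.05."""
        rng = np.random.default_rng(101)
        n_sim = 200
        rejections = 0
        for s in range(n_sim):
            codes = rng.integers(1, 5, size=200).astype(float)
            y = rng.random(200) < 0.5
            y[0], y[1] = True, False
            res = exact_rank_sum_test(codes[y], codes[~y])
            rejections += res.p_two_sided <= 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se

    def test_holm_correction_is_conservative(self, results_cohort):
        plain = rank_table(results_cohort)
        adj = rank_table(results_cohort, correction="holm")
        assert adj["significant"].sum() <= plain["significant"].sum()
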