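import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mirrorsym import (
    AgreementCategory,
    MattaGrade,
    categorize_distance,
    compare_directions,
    cumulative_curve,
    matta_grade,
    percent_agreement,
    rank_sum_exact_p,
    summarize,
    threshold_percentages,
)


class TestSummarize:
    def test_basic_moments(self):
        s = summarize([0.2, 0.4, 0.6, 0.8])
        assert s.mean_error == pytest.approx(0.5)
        assert s.max_dev == pytest.approx(0.8)
        assert s.sd == pytest.approx(np.std([0.2, 0.4, 0.6, 0.8], ddof=1))
        assert s.n_points == 4

    def test_single_distance_convention(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            s = summarize([0.7])
        assert s.mean_error == s.p95 == s.max_dev == 0.7
        assert s.sd == 0.0

    def test_p95_linear_interpolation(self):
        """1..100 gives 95.05 under interpolation between order statistics."""
        s = summarize(np.arange(1.0, 101.0))
        assert s.p95 == pytest.approx(95.05)

    def test_absolute_values_used(self):
        s = summarize([-1.0, 1.0])
        assert s.mean_error == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestThresholds:
    def test_strict_counting(self):
        p = threshold_percentages([0.2, 0.7, 1.2, 2.5], (0.5, 1.0, 1.5, 2.0))
        assert p.surface_percent == (25.0, 50.0, 75.0, 75.0)

    def test_boundary_value_not_counted(self):
        p = threshold_percentages([0.5], (0.5,))
        assert p.surface_percent == (0.0,)

    def test_all_zero_distances(self):
        p = threshold_percentages(np.zeros(10))
        assert p.surface_percent == (100.0, 100.0, 100.0, 100.0)

    def test_monotone_and_saturating(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(0.5, size=500)
        p = threshold_percentages(d, (0.25, 0.5, 1.0, 2.0, d.max() + 1))
        assert list(p.surface_percent) == sorted(p.surface_percent)
        assert p.surface_percent[-1] == 100.0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            threshold_percentages([1.0], (1.0, 0.5))


class TestCumulativeCurve:
    def test_consistent_with_thresholds(self):
        rng = np.random.default_rng(5)
        d = rng.gamma(2.0, 0.3, size=200)
        grid = (0.5, 1.0, 1.5, 2.0)
        np.testing.assert_allclose(
            cumulative_curve(d, grid), threshold_percentages(d, grid).surface_percent
        )

    def test_beyond_max_is_100(self):
        assert cumulative_curve([0.3, 0.9], [5.0])[0] == 100.0

    def test_single_point(self):
        np.testing.assert_allclose(cumulative_curve([1.0], [0.5, 2.0]), [0.0, 100.0])


class TestGrading:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.8, MattaGrade.ANATOMICAL),
            (1.0, MattaGrade.ANATOMICAL),
            (1.5, MattaGrade.IMPERFECT),  # the unnamed (1, 2) gap -> imperfect
            (2.5, MattaGrade.IMPERFECT),
            (3.0, MattaGrade.IMPERFECT),
            (3.5, MattaGrade.POOR),
        ],
    )
    def test_matta_examples(self, value, grade):
        assert matta_grade(value) is grade

    @pytest.mark.parametrize(
        "value,bin",
        [
            (0.46, AgreementCategory.BELOW_0_5),
            (0.5, AgreementCategory.FROM_0_5_TO_1),  # lower-inclusive bins
            (0.73, AgreementCategory.FROM_0_5_TO_1),
            (1.30, AgreementCategory.FROM_1_TO_1_5),
            (1.7, AgreementCategory.FROM_1_5_TO_2),
            (2.9, AgreementCategory.ABOVE_2),
        ],
    )
    def test_agreement_bins(self, value, bin):
        assert categorize_distance(value) is bin

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            matta_grade(-0.1)
        with pytest.raises(ValueError):
            categorize_distance(-0.1)

    def test_total_and_consistent_on_unit_interval(self):
        for v in np.linspace(0.0, 1.0, 101):
            assert matta_grade(v) is MattaGrade.ANATOMICAL
            assert categorize_distance(v) in (
                AgreementCategory.BELOW_0_5,
                AgreementCategory.FROM_0_5_TO_1,
                AgreementCategory.FROM_1_TO_1_5,
            )


class TestAgreement:
    def test_example(self):
        a = [AgreementCategory.BELOW_0_5] * 2 + [AgreementCategory.FROM_0_5_TO_1] * 2
        b = [AgreementCategory.BELOW_0_5] + [AgreementCategory.FROM_0_5_TO_1] * 3
        assert percent_agreement(a, b) == 75.0

    def test_identical_and_disjoint(self):
        a = [AgreementCategory.BELOW_0_5] * 5
        assert percent_agreement(a, a) == 100.0
        b = [AgreementCategory.ABOVE_2] * 5
        assert percent_agreement(a, b) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        cats = list(AgreementCategory)
        a = [cats[i] for i in rng.integers(0, 5, 20)]
        b = [cats[i] for i in rng.integers(0, 5, 20)]
        assert percent_agreement(a, b) == percent_agreement(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_agreement([AgreementCategory.BELOW_0_5], [])


class TestRankSum:
    def test_separated_samples_exact_p(self):
        """(1,2,3) vs (10,11,12): U = 0 and exact two-sided p = 2/20."""
        u, p = rank_sum_exact_p([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_is_one(self):
        _, p = rank_sum_exact_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 4), (5, 6), (6, 6)])
    def test_matches_scipy_exact_without_ties(self, n1, n2):
        """Independent oracle: scipy's exact Mann-Whitney on tie-free data,
        all combined sizes up to 12."""
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
            b = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), a)
            _, p = rank_sum_exact_p(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)


class TestCompareDirections:
    def test_non_normal_takes_exact_rank_path(self):
        """Strongly bimodal pooled data fails the KS normality check and
        routes to the exact rank-sum test (combined n = 20)."""
        a = np.zeros(10)
        b = np.ones(10)
        rep = compare_directions(a, b)
        assert not rep.normal
        assert rep.exact
        # fully separated samples: p = 2 / C(20, 10)
        assert rep.p_value == pytest.approx(2.0 / 184756.0)
        assert rep.significant

    def test_identical_samples_not_significant(self):
        rep = compare_directions([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        assert rep.p_value == 1.0
        assert not rep.significant

    def test_normal_data_takes_t_path(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.45, 0.1, 30)
        b = rng.normal(0.46, 0.1, 30)
        rep = compare_directions(a, b)
        assert rep.normal
        assert rep.test_name == "unpaired t"
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert rep.p_value == pytest.approx(float(ref.pvalue))

    def test_significance_flag_follows_alpha(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [10.0, 11.0, 12.0, 13.0, 14.0]
        rep = compare_directions(a, b, alpha=0.05)
        assert rep.p_value < 0.05 and rep.significant
        rep2 = compare_directions(a, b, alpha=1e-6)
        assert not rep2.significant

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.exponential(1.0, 15)
        b = rng.exponential(1.5, 15)
        rep = compare_directions(a, b)
        if not rep.normal:
            assert not rep.exact

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_directions([1.0, 2.0], [1.0, 2.0, 3.0])


def test_exact_enumeration_matches_first_principles():
    """Hand enumeration on a tiny case: n1=n2=2, sample (1,2) vs (3,4).

    C(4,2) = 6 subsets; U(a) = 0 only for {1,2}; two-sided p = 2/6.
    """
    _, p = rank_sum_exact_p([1.0, 2.0], [3.0, 4.0])
    assert p == pytest.approx(2.0 / 6.0)
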