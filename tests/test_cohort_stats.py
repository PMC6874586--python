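"""Cohort statistical protocol: summaries, tests, symmetry, gender."""

import math

import numpy as np
import pandas as pd
import pytest

from aaamorph import (
    SYMMETRY_PAIRS,
    cohort_angle_tables,
    default_angle_spec,
    gender_comparison,
    generate_cohort,
    median_test,
    normality_tests,
    pearson_corr,
    shapiro_wilk,
    summarize,
    summary_table,
    symmetry_tests,
)
from aaamorph.cohort_stats import adjust_pvalues, correlation_matrix


class TestSummarize:
    def test_basic_five_numbers(self):
        row = summarize([1, 2, 3, 4, 5], "v")
        assert row.median == 3 and row.min == 1 and row.max == 5
        assert row.iqr == 2.0  # linear-interpolation quartiles: q1=2, q3=4
        assert row.n_used == 5

    def test_singleton(self):
        row = summarize([7], "v")
        assert (row.median, row.iqr, row.min, row.max, row.n_used) == (7, 0, 7, 7, 1)

    def test_missing_values_dropped(self):
        row = summarize([1.0, math.nan, 3.0, math.nan], "v")
        assert row.n_used == 2 and row.median == 2.0

    def test_all_missing_names_variable(self):
        with pytest.raises(ValueError, match="neck_length"):
            summarize([math.nan, math.nan], "neck_length")

    def test_known_quartile_recovery(self, rng):
        draws = rng.normal(50.0, 10.0, 10_000)
        row = summarize(draws, "x")
        assert row.median == pytest.approx(50.0, abs=0.5)
        assert row.iqr == pytest.approx(2 * 0.67449 * 10.0, abs=0.6)

    def test_summary_table_shape(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        tab = summary_table(df)
        assert list(tab.index) == list("abc")
        assert set(tab.columns) == {"median", "iqr", "min", "max", "n_used"}


class TestShapiroWilk:
    def test_type_one_error_near_nominal(self):
        rejections = 0
        n_trials = 400
        for seed in range(n_trials):
            x = np.random.default_rng(seed).normal(size=258)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        rate = rejections / n_trials
        assert abs(rate - 0.05) < 3.5 * math.sqrt(0.05 * 0.95 / n_trials)

    def test_power_against_skewed_alternative(self):
        rejections = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=258)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 48

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(5001, dtype=float))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10, dtype=float)
        rho, p, n = pearson_corr(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho, _, _ = pearson_corr(x, y)
        want = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert rho == pytest.approx(want, abs=1e-12)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, math.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, math.nan, 10.0]
        rho, _, n = pearson_corr(x, y)
        assert n == 3 and rho == pytest.approx(1.0)

    def test_null_rate_at_alpha_001(self):
        hits = 0
        n_trials = 400
        for seed in range(n_trials):
            r = np.random.default_rng(10_000 + seed)
            _, p, _ = pearson_corr(r.normal(size=258), r.normal(size=258))
            hits += p < 0.01
        assert abs(hits / n_trials - 0.01) < 3.5 * math.sqrt(0.01 * 0.99 / n_trials)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_correlation_matrix_properties(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        out = correlation_matrix(df)
        rho = out["rho"].to_numpy()
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert ((out["p"].to_numpy() >= 0) & (out["p"].to_numpy() <= 1)).all()


class TestMedianTest:
    def test_identical_large_samples(self, rng):
        x = rng.normal(size=500)
        stat, p = median_test(x, x.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_fully_separated_groups(self):
        a = np.arange(50, dtype=float)
        b = a + 100.0
        _, p = median_test(a, b)
        assert p < 1e-10

    def test_matches_hand_built_contingency_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 10.0, 11.0])
        b = np.array([4.0, 5.0, 6.0, 7.0, 12.0])
        grand = np.median(np.concatenate([a, b]))
        # 2x2 table: counts <= grand median (ties below) / above, per group
        table = np.array(
            [[np.sum(a > grand), np.sum(b > grand)],
             [np.sum(a <= grand), np.sum(b <= grand)]], dtype=float
        )
        colsum = table.sum(axis=0)
        rowsum = table.sum(axis=1)
        expected = np.outer(rowsum, colsum) / table.sum()
        chi2_oracle = ((table - expected) ** 2 / expected).sum()
        stat, p = median_test(a, b)
        assert stat == pytest.approx(chi2_oracle, abs=1e-12)
        from scipy.stats import chi2
        assert p == pytest.approx(chi2.sf(chi2_oracle, 1), abs=1e-12)

    def test_all_identical_pooled_rejected(self):
        with pytest.raises(ValueError):
            median_test([5.0, 5.0], [5.0, 5.0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_test([], [1.0, 2.0])


class TestSymmetry:
    def test_sixteen_labelled_tests(self):
        cohort = generate_cohort(80, seed=5, torsion_jitter=25.0)
        out = symmetry_tests(cohort)
        assert len(out) == 16
        assert set(out.index.get_level_values("space")) == {"3D", "XZ", "YZ", "XY"}
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()

    def test_null_cohort_mostly_nonsignificant(self):
        # identical right/left marginals for every symmetry pair
        spec = default_angle_spec()
        angles = dict(spec.angles)
        for left, right in SYMMETRY_PAIRS:
            angles[right] = angles[left]
        from aaamorph import AngleDistributionSpec
        cohort = generate_cohort(
            120, angle_spec=AngleDistributionSpec(angles=angles),
            seed=17, torsion_jitter=25.0,
        )
        out = symmetry_tests(cohort)
        sig_3d = out.loc["3D", "significant_at_0.05"].sum()
        assert sig_3d <= 1

    def test_shifted_pair_detected(self):
        spec = default_angle_spec().shifted({"phi7": 10.0, "phi10": -10.0})
        cohort = generate_cohort(150, angle_spec=spec, seed=6, torsion_jitter=25.0)
        out = symmetry_tests(cohort)
        assert out.loc[("3D", "phi7-phi10"), "p"] < 0.01

    def test_single_patient_rejected(self):
        cohort = generate_cohort(1, seed=0)
        with pytest.raises(ValueError):
            symmetry_tests(cohort)


class TestGender:
    def test_null_cohort_pvalues_valid(self):
        cohort = generate_cohort(200, seed=23)
        rep = gender_comparison(cohort)
        for series in (rep.gender_dimensions, rep.gender_angles):
            vals = series.dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        assert len(rep.gender_angles) == 10

    def test_injected_dimension_shift_detected(self):
        cohort = generate_cohort(
            300, seed=29,
            gender_dimension_shifts={"average_tortuosity_index": 0.25},
        )
        rep = gender_comparison(cohort)
        assert rep.gender_dimensions["average_tortuosity_index"] < 0.01

    def test_injected_angle_shift_detected(self):
        cohort = generate_cohort(300, seed=31, gender_angle_shifts={"phi6": -20.0})
        rep = gender_comparison(cohort)
        assert rep.gender_angles["phi6"] < 0.01

    def test_too_few_per_gender_rejected(self):
        cohort = generate_cohort(5, seed=1, male_to_female_ratio=1e9)
        with pytest.raises(ValueError):
            gender_comparison(cohort)


class TestNormalityReport:
    def test_angle_table_normality(self):
        cohort = generate_cohort(100, seed=41)
        tables = cohort_angle_tables(cohort)
        rep = normality_tests(tables["3D"])
        assert list(rep.index) == [f"phi{i}" for i in range(1, 11)]
        assert ((rep["p"] >= 0) & (rep["p"] <= 1)).all()


def test_pvalue_adjustments_monotone():
    p = np.array([0.001, 0.01, 0.02, 0.2])
    bonf = adjust_pvalues(p, "bonferroni")
    bh = adjust_pvalues(p, "fdr_bh")
    assert (bonf >= p).all() and (bh >= p).all() and (bonf >= bh).all()
    assert bonf[0] == pytest.approx(0.004)
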