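"""Paired-device statistics: OLS, ICC(3,1), tiers, paired tests, export."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from crosspet import (
    ClassificationThresholds,
    PairedFeatureTable,
    classify_comparability,
    compare_modalities,
    export_interchange,
    fit_linear,
    icc_two_way_mixed_single,
    paired_metric_test,
    run_comparison,
)
from crosspet.errors import DegenerateDataError


class TestFitLinear:
    def test_identity_line(self):
        assert fit_linear([1, 2, 3], [1, 2, 3]) == pytest.approx((1.0, 0.0, 1.0))

    def test_exact_affine_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert fit_linear(x, 2 * x + 3) == pytest.approx((2.0, 3.0, 1.0))

    def test_four_point_hand_ols(self):
        slope, intercept, r2 = fit_linear([1, 2, 3, 4], [1, 2, 3, 5])
        assert slope == pytest.approx(1.3)
        assert intercept == pytest.approx(-0.5)
        assert r2 == pytest.approx(0.9657, abs=1e-4)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_linear([2, 2, 2, 2], [1, 2, 3, 4])


class TestIcc:
    def test_identity_gives_one(self):
        assert icc_two_way_mixed_single([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_constant_shift_gives_one_for_consistency_form(self):
        assert icc_two_way_mixed_single([1, 2, 3, 4], [3, 4, 5, 6]) == pytest.approx(1.0)
        # absolute agreement is penalized by the shift
        agree = icc_two_way_mixed_single([1, 2, 3, 4], [3, 4, 5, 6], form="agreement")
        assert agree < 1.0

    def test_perfect_anticonsistency(self):
        icc = icc_two_way_mixed_single([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert icc == pytest.approx(-1.0)

    def test_example_against_explicit_anova(self):
        icc = icc_two_way_mixed_single([1, 2, 3, 4], [2, 2, 4, 4])
        assert icc == pytest.approx(self._brute_icc([1, 2, 3, 4], [2, 2, 4, 4]), abs=1e-10)

    @staticmethod
    def _brute_icc(x, y):
        """Oracle: two-way ANOVA with residuals formed explicitly per cell."""
        data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        n, k = data.shape
        gm = data.mean()
        row = data.mean(axis=1, keepdims=True)
        col = data.mean(axis=0, keepdims=True)
        resid = data - row - col + gm
        ms_rows = (k * ((row - gm) ** 2).sum()) / (n - 1)
        ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
        return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_vectors_match_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(scale=0.5, size=n)
        assert icc_two_way_mixed_single(x, y) == pytest.approx(
            self._brute_icc(x, y), abs=1e-10
        )

    def test_matches_pingouin_both_forms(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=12)
        y = 1.2 * x + 0.3 + rng.normal(scale=0.4, size=12)
        df = pd.DataFrame(
            {
                "subj": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x, y]),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        ref = ref.set_index("Type")["ICC"]
        assert icc_two_way_mixed_single(x, y) == pytest.approx(ref["ICC(C,1)"], abs=1e-9)
        assert icc_two_way_mixed_single(x, y, form="agreement") == pytest.approx(
            ref["ICC(A,1)"], abs=1e-9
        )


class TestClassification:
    @pytest.mark.parametrize(
        "r2,icc,level",
        [
            (0.90, 0.80, "strong"),
            (0.60, 0.60, "moderate"),
            (0.40, 0.90, "weak"),
            (0.90, 0.40, "weak"),
            (0.85, 0.75, "moderate"),  # boundaries are strict ('larger than')
            (0.50, 0.50, "weak"),
            (float("nan"), 0.9, "weak"),
        ],
    )
    def test_three_tier_rule(self, r2, icc, level):
        assert classify_comparability(r2, icc) == level

    def test_threshold_ordering_enforced(self):
        with pytest.raises(DegenerateDataError):
            ClassificationThresholds(strong_r2=0.4, moderate_r2=0.5)


def identity_table(n_subjects=6, n_features=30, seed=0):
    rng = np.random.default_rng(seed)
    a = pd.DataFrame(
        rng.lognormal(1.0, 0.6, (n_subjects, n_features)),
        index=[f"s{i}" for i in range(n_subjects)],
        columns=[f"f{i:02d}" for i in range(n_features)],
    )
    roster = pd.DataFrame(
        {"name": a.columns, "family": "synthetic", "image_set": "n/a", "base_name": a.columns}
    )
    return PairedFeatureTable(a=a, b=a.copy(), roster=roster)


class TestCompareModalities:
    def test_identity_table_is_all_strong(self):
        results, summary = compare_modalities(identity_table())
        for r in results:
            assert r.level == "strong"
            assert r.slope == pytest.approx(1.0)
            assert r.intercept == pytest.approx(0.0, abs=1e-9)
            assert r.r2 == pytest.approx(1.0)
            assert r.icc == pytest.approx(1.0)
        assert summary["overall"]["pct_strong"] == 100.0

    def test_level_partition_counts(self):
        table = identity_table()
        table.b.iloc[:, 0] = 999.0  # constant y still fits; constant x does not
        table.a.iloc[:, 1] = 5.0  # degenerate x -> not assessable
        results, summary = compare_modalities(table)
        ov = summary["overall"]
        assert ov["strong"] + ov["moderate"] + ov["weak"] == ov["n_assessable"]
        assert ov["n_assessable"] + ov["n_not_assessable"] == ov["n"] == len(results)
        assert ov["n_not_assessable"] == 1

    def test_subject_mismatch_rejected(self):
        t = identity_table()
        b = t.b.copy()
        b.index = [f"x{i}" for i in range(len(b))]
        with pytest.raises(DegenerateDataError):
            PairedFeatureTable(a=t.a, b=b)


class TestPairedMetricTest:
    def test_identical_vectors_convention(self):
        v = np.linspace(0.1, 0.9, 49)
        assert paired_metric_test(v, v) == (0.0, 1.0)

    def test_constant_shift_with_jitter_is_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 0.9, 49)
        shifted = base - 0.2 + rng.normal(0, 0.01, 49)
        t, p = paired_metric_test(base, shifted)
        assert p < 0.001 and t > 0
        # cross-check against the closed-form paired t on the same sample
        d = base - shifted
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_ref, rel=1e-12)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.7, 0.1, 49)
            b = a + rng.normal(0, 0.05, 49)  # identical means: null is true
            _, p = paired_metric_test(a, b)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_metric_test([0.1, 0.2], [0.3, 0.4])


class TestExportInterchange:
    def test_identity_export_has_unit_equations(self):
        report = run_comparison(identity_table())
        table = report.interchange
        assert len(table) == 30
        assert np.allclose(table["slope"], 1.0)
        assert np.allclose(table["intercept"], 0.0, atol=1e-9)
        assert np.allclose(table["inverse_slope"], 1.0)

    def test_weak_features_excluded(self):
        t = identity_table(seed=1)
        rng = np.random.default_rng(5)
        t.b.iloc[:, 3] = rng.normal(size=len(t.b))  # uncorrelated -> weak
        results, _ = compare_modalities(t)
        weak = [r.feature for r in results if r.level == "weak"]
        assert t.a.columns[3] in weak
        exported = set(export_interchange(results)["feature"])
        assert not exported.intersection(weak)

    def test_inverse_equation_is_algebraic(self):
        results, _ = compare_modalities(identity_table(seed=2))
        table = export_interchange(results)
        np.testing.assert_allclose(table["inverse_slope"], 1.0 / table["slope"])
        np.testing.assert_allclose(
            table["inverse_intercept"], -table["intercept"] / table["slope"], atol=1e-12
        )
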