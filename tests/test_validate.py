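"""Screening, reliability, CFA recovery, summary tests, FDR, and the ML harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulbarkit.synthgen import make_factor_table
from bulbarkit.validate import (
    CVConfig,
    FactorSpec,
    GroupSummary,
    bartlett_scores,
    bh_fdr,
    chi2_yates,
    cohens_d,
    cohens_d_screen,
    cronbach_alpha,
    cv_evaluate,
    default_factor_spec,
    fit_cfa,
    summary_f_test,
    table1_statistics,
)


class TestScreening:
    def test_unit_effect_retained(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 4000)
        b = rng.normal(0.0, 1.0, 4000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.1)
        table = pd.DataFrame({"f": np.concatenate([a, b])})
        labels = np.array(["g1"] * 4000 + ["g2"] * 4000)
        retained, _, d = cohens_d_screen(table, labels)
        assert retained == ["f"]

    def test_identical_distributions_discarded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 2000)
        table = pd.DataFrame({"f": np.concatenate([x, x])})
        labels = np.array(["a"] * 2000 + ["b"] * 2000)
        retained, discarded, d = cohens_d_screen(table, labels)
        assert discarded == ["f"] and d["f"] == 0.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"f": rng.normal(0, 1, 100) + np.r_[np.ones(50), np.zeros(50)]})
        l1 = np.array(["a"] * 50 + ["b"] * 50)
        _, _, d1 = cohens_d_screen(table, l1)
        _, _, d2 = cohens_d_screen(table, np.where(l1 == "a", "b", "a"))
        assert d1["f"] == pytest.approx(-d2["f"])

    def test_zero_pooled_sd_flagged(self):
        table = pd.DataFrame({"f": np.ones(10)})
        labels = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="zero pooled SD"):
            retained, discarded, d = cohens_d_screen(table, labels)
        assert discarded == ["f"] and np.isnan(d["f"])


class TestCronbach:
    def test_perfectly_correlated_items(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 200)
        X = np.column_stack([base, base + 1, base - 3])  # parallel items
        assert cronbach_alpha(X) == pytest.approx(1.0, abs=0.02)

    def test_spearman_brown_parallel_items(self):
        """k=5 items with rho=0.4 -> alpha = 5*0.4/(1+4*0.4) = 0.769."""
        rng = np.random.default_rng(4)
        n, k, rho = 5000, 5, 0.4
        common = rng.normal(0, np.sqrt(rho), n)[:, None]
        X = common + rng.normal(0, np.sqrt(1 - rho), (n, k))
        assert cronbach_alpha(X) == pytest.approx(0.769, abs=0.02)

    def test_uncorrelated_items_near_zero(self):
        rng = np.random.default_rng(5)
        assert abs(cronbach_alpha(rng.normal(0, 1, (5000, 4)))) < 0.05

    def test_single_item_undefined(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))


class TestCFA:
    def test_parameter_recovery_multifactor(self):
        L = np.zeros((9, 3))
        true = [0.8, 0.7, 0.6]
        for j in range(3):
            L[3 * j:3 * j + 3, j] = true
        u = 1.0 - (L ** 2).sum(axis=1)
        names = [f"x{i}" for i in range(9)]
        table, _ = make_factor_table(2000, L, u, seed=6, feature_names=names)
        spec = FactorSpec({f"F{j}": tuple(names[3 * j:3 * j + 3])
                           for j in range(3)})
        fit = fit_cfa(table, spec)
        for j in range(3):
            for i in range(3):
                assert fit.loadings[names[3 * j + i]] == pytest.approx(
                    true[i], abs=0.05)
        assert fit.cfi >= 0.95
        assert fit.rmsea <= 0.05

    def test_low_loading_feature_pruned(self):
        L = np.array([[0.8], [0.8], [0.8], [0.2]])
        u = 1.0 - (L ** 2).ravel()
        names = ["a", "b", "c", "weak"]
        table, _ = make_factor_table(2000, L, u, seed=7, feature_names=names)
        fit = fit_cfa(table, FactorSpec({"F": tuple(names)}))
        assert fit.pruned == ["weak"]
        assert "weak" not in fit.loadings.index

    def test_bartlett_scores_recover_generating_factor(self):
        L = np.full((5, 1), 0.8)
        u = 1.0 - (L ** 2).ravel()
        table, eta = make_factor_table(2000, L, u, seed=8)
        fit = fit_cfa(table, FactorSpec({"F": tuple(table.columns)}),
                      prune=False)
        r = np.corrcoef(fit.scores.iloc[:, 0], eta.iloc[:, 0])[0, 1]
        assert r > 0.9
        # unbiasedness: regression slope of score on factor ~ 1
        slope = np.polyfit(eta.iloc[:, 0], fit.scores.iloc[:, 0], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_saturated_single_indicator_factor(self):
        rng = np.random.default_rng(9)
        L = np.array([[0.8], [0.7], [0.75]])
        u = 1.0 - (L ** 2).ravel()
        table, _ = make_factor_table(1500, L, u, seed=10)
        single = pd.Series(rng.normal(0, 1, 1500), name="solo")
        table["solo"] = single
        spec = FactorSpec({"F": ("x1", "x2", "x3"), "S": ("solo",)})
        fit = fit_cfa(table, spec, prune=False)
        r = np.corrcoef(fit.scores["S"],
                        (single - single.mean()) / single.std(ddof=1))[0, 1]
        assert r > 0.99

    def test_default_spec_covers_inventory(self):
        from bulbarkit.featuretable import FEATURE_NAMES
        spec = default_factor_spec(FEATURE_NAMES)
        assert len(spec.assignment) == 10
        # no acoustic-regularity factor: ShanEn_audio stays unassigned
        assert sorted(spec.features) == sorted(
            set(FEATURE_NAMES) - {"ShanEn_audio"})


class TestSummaryTests:
    def test_equal_means_f_zero(self):
        F, df, p = summary_f_test(GroupSummary(5.0, 1.0, 10),
                                  GroupSummary(5.0, 2.0, 12))
        assert F == 0.0 and p == pytest.approx(1.0)

    def test_matches_full_anova_oracle(self):
        """Summary-stat F equals scipy's one-way ANOVA on raw data with
        exactly those summaries."""
        from scipy import stats
        rng = np.random.default_rng(11)
        a = rng.normal(3.0, 1.0, 15)
        b = rng.normal(3.8, 1.3, 11)
        F_raw, p_raw = stats.f_oneway(a, b)
        F, df, p = summary_f_test(
            GroupSummary(a.mean(), a.std(ddof=1), a.size),
            GroupSummary(b.mean(), b.std(ddof=1), b.size))
        assert F == pytest.approx(F_raw)
        assert p == pytest.approx(p_raw)

    def test_proportional_table_chi2_near_zero(self):
        chi2, p = chi2_yates([[20, 40], [10, 20]])
        assert chi2 == pytest.approx(0.0, abs=0.05)

    def test_row_column_swap_invariance(self):
        c1, _ = chi2_yates([[5, 8], [7, 3]])
        c2, _ = chi2_yates([[3, 7], [8, 5]])
        assert c1 == pytest.approx(c2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ZeroDivisionError):
            chi2_yates([[0, 0], [5, 5]])

    def test_table1_reproduction(self):
        stats = table1_statistics()
        assert stats["speaking_rate_wpm"]["F"] == pytest.approx(11.14, rel=0.01)
        assert stats["intelligibility_pct"]["F"] == pytest.approx(2.32, rel=0.01)
        assert stats["age_years"]["F"] == pytest.approx(1.80, rel=0.01)
        assert stats["sex"]["chi2"] == pytest.approx(1.17, rel=0.01)


class TestFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03] * 3)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestCVHarness:
    def test_noiseless_linear_regression(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (80, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.3
        res = cv_evaluate(X, y, "regression", "mlr",
                          CVConfig(repeats=2, seed=0))
        assert res["metrics"]["r2"] >= 0.999
        assert res["metrics"]["rmse"] == pytest.approx(0.0, abs=1e-6)

    def test_permuted_labels_auc_half(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (120, 5))
        y = np.array(["a", "b"] * 60)
        res = cv_evaluate(X, y, "binary", "rf", CVConfig(repeats=10, seed=1))
        assert res["metrics"]["auc"] == pytest.approx(0.5, abs=0.1)

    def test_separable_classes_beat_null(self):
        rng = np.random.default_rng(14)
        X0 = rng.normal(0, 1, (60, 4))
        X1 = rng.normal(1.5, 1, (60, 4))
        X = np.vstack([X0, X1])
        y = np.array(["a"] * 60 + ["b"] * 60)
        res = cv_evaluate(X, y, "binary", "svm_rbf", CVConfig(repeats=3, seed=2))
        assert res["metrics"]["auc"] > 0.9
        assert res["metrics"]["sensitivity"] > 0.7
        assert res["metrics"]["specificity"] > 0.7

    def test_multiclass_metrics_present(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.normal(i * 1.5, 1, (40, 3)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 40)
        res = cv_evaluate(X, y, "multiclass", "rf", CVConfig(repeats=2, seed=3))
        m = res["metrics"]
        assert {"accuracy_a_vs_b", "accuracy_a_vs_c", "accuracy_b_vs_c",
                "auc"} <= set(m)
        assert m["auc"] > 0.8
        assert "importance" in res

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(16)
        X = rng.normal(0, 1, (60, 4))
        y = np.array(["a", "b"] * 30)
        r1 = cv_evaluate(X, y, "binary", "rf", CVConfig(repeats=2, seed=7))
        r2 = cv_evaluate(X, y, "binary", "rf", CVConfig(repeats=2, seed=7))
        assert r1["metrics"] == r2["metrics"]

    def test_degenerate_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError):
            cv_evaluate(X, y, "binary", "rf", CVConfig())
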