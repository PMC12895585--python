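"""Group tests, BH-FDR, symptom correlations, dose conversion, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnirsfc import stats as fstats


class TestChooseTest:
    def test_two_gaussian_samples_use_student_t(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.2, 1, 200)
        assert fstats.choose_test(x, y) == "student_t"

    def test_skewed_samples_use_ranksum(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            x = r.exponential(1.0, 80)
            y = r.exponential(1.2, 80)
            hits += fstats.choose_test(x, y) == "wilcoxon_ranksum"
        assert hits >= 19  # KS power against exponential at n=80 is ~1

    def test_constant_sample_falls_back_to_ranksum(self, rng):
        assert fstats.choose_test(np.ones(10), rng.normal(size=10)) == "wilcoxon_ranksum"

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            fstats.choose_test(np.ones(2), np.ones(5))


class TestChiSquare:
    def test_table1_sex_counts(self):
        stat, p = fstats.chi_square_2x2([[37, 46], [36, 42]])
        assert round(stat, 3) == 0.040
        assert round(p, 3) == 0.841

    def test_proportional_table_gives_zero(self):
        stat, _ = fstats.chi_square_2x2([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_closed_form(self):
        stat, _ = fstats.chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_transpose_invariance(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        s1, p1 = fstats.chi_square_2x2(t)
        s2, p2 = fstats.chi_square_2x2(t.T)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            fstats.chi_square_2x2([[0, 0], [5, 5]])


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert fstats.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        q = fstats.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_all_equal_p_stay_equal(self):
        q = fstats.bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    @given(seed=st.integers(0, 500), m=st.integers(2, 40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_statsmodels_reference(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(0, 1, m)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(fstats.bh_fdr(p), q_ref, atol=1e-12)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_p(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 20)
        q = fstats.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fstats.bh_fdr([0.5, 1.2])


class TestFluoxetineEquivalent:
    @pytest.mark.parametrize(
        "drug,dose,expected",
        [
            ("sertraline", 98.5, 40.0),  # the equivalence definition
            ("fluoxetine", 20.0, 20.0),  # identity drug
            ("venlafaxine", 74.7, 20.0),  # half the equivalent dose
            ("paroxetine", 34.0, 40.0),
            ("clomipramine", 58.05, 20.0),
        ],
    )
    def test_conversions(self, drug, dose, expected):
        assert fstats.fluoxetine_equivalent(drug, dose) == pytest.approx(expected)

    def test_multiple_medications_sum(self):
        total = fstats.total_fluoxetine_equivalent(
            [("fluoxetine", 20.0), ("sertraline", 49.25)]
        )
        assert total == pytest.approx(40.0)

    def test_unknown_drug_lists_supported(self):
        with pytest.raises(ValueError, match="sertraline"):
            fstats.fluoxetine_equivalent("bupropion", 150.0)


class TestScoreScreen:
    def test_majority_rule_reproduces_reference_inclusion(self, rng):
        n = 83
        clinical = pd.DataFrame(
            {
                "group": ["MDD"] * n,
                "dass_d": np.clip(rng.normal(16.12, 1.93, n).round(), 0, 21),
                "dass_a": np.clip(rng.normal(11.43, 4.16, n).round(), 0, 21),
                "dass_s": np.clip(rng.normal(11.22, 5.77, n).round(), 0, 21),
                "shaps": np.clip(rng.normal(33.07, 7.37, n).round(), 0, 42),
            }
        )
        included = fstats.screen_scores(clinical)
        assert "DASS-D" in included
        assert "DASS-A" in included
        assert "DASS-S" not in included
        assert "SHAPS" in included


class TestSpearman:
    def _features(self, n, rng):
        return pd.DataFrame(
            {"static|A~B": rng.standard_normal(n), "pc1|A~B": rng.standard_normal(n)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_strictly_monotone_pair_gives_unit_r(self, rng):
        n = 30
        feats = self._features(n, rng)
        clinical = pd.DataFrame(
            {"group": "MDD", "shaps": np.argsort(np.argsort(feats["static|A~B"]))},
            index=feats.index,
        )
        out = fstats.spearman_feature_symptoms(feats, clinical, scores=["SHAPS"])
        r = out.loc[out["feature"] == "static|A~B", "r"].item()
        assert r == pytest.approx(1.0)

    def test_permuted_scores_have_null_r_and_large_q(self, rng):
        n = 100
        feats = self._features(n, rng)
        clinical = pd.DataFrame(
            {"group": "MDD", "shaps": rng.permutation(n)}, index=feats.index
        )
        out = fstats.spearman_feature_symptoms(feats, clinical, scores=["SHAPS"])
        assert np.all(np.abs(out["r"]) < 4.0 / np.sqrt(n))
        assert np.all(out["q"] > 0.05)

    def test_constant_feature_reported_missing(self, rng):
        feats = self._features(20, rng)
        feats["static|A~B"] = 1.0
        clinical = pd.DataFrame(
            {"group": "MDD", "shaps": rng.permutation(20)}, index=feats.index
        )
        out = fstats.spearman_feature_symptoms(feats, clinical, scores=["SHAPS"])
        row = out[out["feature"] == "static|A~B"].iloc[0]
        assert np.isnan(row["r"]) and np.isnan(row["q"])


class TestRegression:
    def _design(self, n, rng):
        return pd.DataFrame(
            {
                "f1": rng.standard_normal(n),
                "age": rng.uniform(12, 18, n),
                "sex": rng.integers(0, 2, n).astype(float),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_exact_linear_outcome_gives_unit_r2(self, rng):
        X = self._design(40, rng)
        y = pd.Series(2 * X["f1"] - 0.5 * X["age"] + X["sex"], name="score")
        res = fstats.regress_clinical(y, X)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.adj_r_squared == pytest.approx(1.0, abs=1e-10)

    def test_independent_outcome_has_near_zero_adj_r2(self, rng):
        X = self._design(83, rng)
        y = pd.Series(rng.standard_normal(83), name="score", index=X.index)
        res = fstats.regress_clinical(y, X)
        assert res.adj_r_squared < 0.15  # null band at n=83, 3 predictors

    def test_planted_standardized_beta_recovered(self, rng):
        n = 83
        betas = []
        for s in range(10):
            r = np.random.default_rng(s)
            X = self._design(n, r)
            f = (X["f1"] - X["f1"].mean()) / X["f1"].std(ddof=1)
            # noise sd tuned so R^2 ~ 0.3 with beta = -0.5
            y = pd.Series(-0.5 * f + r.normal(0, 0.85, n), name="score")
            res = fstats.regress_clinical(y, X)
            betas.append(res.beta["f1"])
        assert np.mean(betas) == pytest.approx(-0.5, abs=0.2)

    def test_vif_and_diagnostics_present(self, rng):
        X = self._design(60, rng)
        y = pd.Series(X["f1"] + rng.standard_normal(60), name="score")
        res = fstats.regress_clinical(y, X)
        assert (res.vif >= 1 - 1e-9).all()
        assert res.adj_r_squared <= res.r_squared
        assert set(res.diagnostics_ok) == {
            "residuals_normal", "homoscedastic", "vif_below_10",
        }
        assert "adjusted R2" in res.summary()

    def test_collinear_design_rejected(self, rng):
        X = self._design(30, rng)
        X["dup"] = X["f1"] * 2.0
        y = pd.Series(rng.standard_normal(30), name="score", index=X.index)
        with pytest.raises(ValueError, match="collinear"):
            fstats.regress_clinical(y, X)


class TestDemographics:
    def test_table_covers_age_sex_education(self, rng):
        n = 40
        clinical = pd.DataFrame(
            {
                "group": ["MDD"] * n + ["HC"] * n,
                "age": rng.normal(15.5, 1.7, 2 * n),
                "education_years": rng.normal(8.6, 1.7, 2 * n),
                "sex": rng.choice(["M", "F"], 2 * n),
            }
        )
        out = fstats.demographics_table(clinical)
        assert set(out.index) == {"age", "education_years", "sex"}
        assert out.loc["sex", "test"] == "chi_square"
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


class TestGroupCompare:
    def test_families_and_directions(self, rng):
        n = 40
        idx = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["MDD"] * n + ["HC"] * n, index=idx, name="group")
        feats = pd.DataFrame(
            {
                "static|A~B": np.r_[rng.normal(-0.5, 1, n), rng.normal(0.5, 1, n)],
                "pc1|A~B": rng.standard_normal(2 * n),
            },
            index=idx,
        )
        out = fstats.group_compare_features(feats, groups)
        assert out.loc["static|A~B", "family"] == "static"
        assert out.loc["pc1|A~B", "family"] == "pc1"
        assert out.loc["static|A~B", "q"] < 0.05
        assert out.loc["static|A~B", "direction"] == -1.0
        assert out.loc["pc1|A~B", "q"] > 0.05
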