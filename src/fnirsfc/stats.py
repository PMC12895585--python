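"""Group statistics, FDR correction, symptom correlations and regression.

Between-group comparisons follow the normality-gated rule: a one-sample
Kolmogorov-Smirnov test (Lilliefors-corrected, parameters estimated) is
applied per group at alpha = 0.05; if both groups look normal a
two-sided pooled-variance Student t-test is used, otherwise the Wilcoxon
rank-sum test.  Categorical contingency tables use the Pearson chi-square
without continuity correction.  Multiple testing is controlled with the
Benjamini-Hochberg step-up within declared feature families.

Clinical-score correlation analyses (MDD group only) use Spearman rank
correlation with tie-corrected ranks, FDR-corrected across the full
feature x score grid.  A score enters the analysis only when a majority
of cases exceed its clinical threshold (DASS-D > 14, DASS-A > 7,
DASS-S > 14); the anhedonia score (SHAPS) is always included.

Antidepressant exposure is standardised to fluoxetine equivalents before
entering regression models as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors
from statsmodels.stats.outliers_influence import variance_inflation_factor

NORMALITY_ALPHA = 0.05
FDR_ALPHA = 0.05

#: published dose (mg/day) equivalent to fluoxetine 40 mg/day
FLUOXETINE_EQUIVALENTS_MG = {
    "fluoxetine": 40.0,
    "sertraline": 98.5,
    "paroxetine": 34.0,
    "clomipramine": 116.1,
    "venlafaxine": 149.4,
}

#: clinical thresholds used by the score inclusion screen
SCORE_THRESHOLDS = {"DASS-D": 14, "DASS-A": 7, "DASS-S": 14}
SCORE_COLUMNS = {"DASS-D": "dass_d", "DASS-A": "dass_a", "DASS-S": "dass_s",
                 "SHAPS": "shaps"}


# ---------------------------------------------------------------------------
# test selection and elementary tests


def choose_test(x: np.ndarray, y: np.ndarray) -> str:
    """Pick ``student_t`` or ``wilcoxon_ranksum`` via per-group normality.

    Degenerate (constant) samples cannot be tested for normality and fall
    back to the rank-sum test with tie handling.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 values per group")
    for g in (x, y):
        if np.ptp(g) == 0:
            return "wilcoxon_ranksum"
        _, p = lilliefors(g, dist="norm")
        if p < NORMALITY_ALPHA:
            return "wilcoxon_ranksum"
    return "student_t"


def compare_groups(x: np.ndarray, y: np.ndarray) -> tuple[str, float, float]:
    """(test_name, statistic, two-sided p) with the normality-gated rule."""
    test = choose_test(x, y)
    if test == "student_t":
        stat, p = sps.ttest_ind(x, y, equal_var=True)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p = res.statistic, res.pvalue
    return test, float(stat), float(p)


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# group comparison across the feature table


def group_compare_features(
    features: pd.DataFrame,
    groups: pd.Series,
    families: Mapping[str, Sequence[str]] | None = None,
    positive_group: str = "MDD",
) -> pd.DataFrame:
    """Between-group tests for every feature, BH-corrected within families.

    ``families`` maps a family name to its feature columns; by default
    the static features form one family and each PC order another,
    matching the per-map presentation of the group contrasts.  Returns a
    frame with test name, statistic, p, q, and the effect direction
    (sign of mean(positive_group) - mean(other)).
    """
    groups = groups.loc[features.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    other = [g for g in labels if g != positive_group][0]
    if families is None:
        families = {}
        static = [c for c in features.columns if c.startswith("static|")]
        if static:
            families["static"] = static
        orders = sorted(
            {int(c[2 : c.index("|")]) for c in features.columns if c.startswith("pc")}
        )
        for n in orders:
            families[f"pc{n}"] = [c for c in features.columns if c.startswith(f"pc{n}|")]
        leftover = [
            c for c in features.columns if not any(c in f for f in families.values())
        ]
        if leftover:
            families["other"] = leftover

    rows = []
    for fam, cols in families.items():
        ps = []
        for col in cols:
            x = features.loc[groups == positive_group, col].to_numpy()
            y = features.loc[groups == other, col].to_numpy()
            test, stat, p = compare_groups(x, y)
            ps.append(p)
            rows.append(
                {
                    "feature": col,
                    "family": fam,
                    "test": test,
                    "statistic": stat,
                    "p": p,
                    "direction": float(np.sign(x.mean() - y.mean())),
                }
            )
        qs = bh_fdr(ps)
        for r, q in zip(rows[-len(cols):], qs):
            r["q"] = float(q)
    return pd.DataFrame(rows).set_index("feature")


def demographics_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of demographics: age and education by the
    normality-gated continuous rule, sex by 2x2 Pearson chi-square."""
    groups = clinical["group"]
    labels = [g for g in ("MDD", "HC") if g in set(groups)]
    if len(labels) != 2:
        raise ValueError("demographics comparison needs both groups")
    rows = []
    for col in ("age", "education_years"):
        if col not in clinical.columns:
            continue
        x = clinical.loc[groups == labels[0], col].dropna().to_numpy(float)
        y = clinical.loc[groups == labels[1], col].dropna().to_numpy(float)
        test, stat, p = compare_groups(x, y)
        rows.append({"variable": col, "test": test, "statistic": stat, "p": p})
    if "sex" in clinical.columns:
        table = pd.crosstab(clinical["sex"], groups).to_numpy()
        if table.shape == (2, 2):
            stat, p = chi_square_2x2(table)
            rows.append(
                {"variable": "sex", "test": "chi_square", "statistic": stat, "p": p}
            )
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# symptom correlations


def screen_scores(
    clinical: pd.DataFrame,
    thresholds: Mapping[str, int] = SCORE_THRESHOLDS,
    always_include: Sequence[str] = ("SHAPS",),
) -> list[str]:
    """Scores entering correlation analyses (majority-above-threshold rule)."""
    included = []
    for score, thr in thresholds.items():
        vals = clinical[SCORE_COLUMNS[score]].dropna()
        if vals.size and (vals > thr).sum() > vals.size / 2:
            included.append(score)
    included += [s for s in always_include if s not in included]
    return included


def spearman_feature_symptoms(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    scores: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Spearman r between every feature and each included score (MDD rows).

    BH-FDR is applied across the full feature x score grid.  Constant
    features have undefined r and are reported as missing (excluded from
    the FDR family).
    """
    if "group" in clinical.columns:
        clinical = clinical[clinical["group"] == "MDD"]
    clinical = clinical.loc[clinical.index.intersection(features.index)]
    feats = features.loc[clinical.index]
    if scores is None:
        scores = screen_scores(clinical)
    rows = []
    for score in scores:
        svals = clinical[SCORE_COLUMNS[score]].to_numpy(float)
        for col in feats.columns:
            fvals = feats[col].to_numpy(float)
            if np.ptp(fvals) == 0 or np.ptp(svals) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(fvals, svals)
            rows.append({"feature": col, "score": score, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# medication standardisation


def fluoxetine_equivalent(drug: str, dose_mg_day: float) -> float:
    """Convert one antidepressant dose to its fluoxetine equivalent (mg/day)."""
    key = drug.strip().lower()
    if key not in FLUOXETINE_EQUIVALENTS_MG:
        raise ValueError(
            f"unknown drug {drug!r}; supported: "
            f"{sorted(FLUOXETINE_EQUIVALENTS_MG)}"
        )
    if dose_mg_day < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg_day * 40.0 / FLUOXETINE_EQUIVALENTS_MG[key]


def total_fluoxetine_equivalent(medications: Sequence[tuple[str, float]]) -> float:
    """Sum of fluoxetine equivalents over a participant's medications."""
    return float(sum(fluoxetine_equivalent(d, mg) for d, mg in medications))


# ---------------------------------------------------------------------------
# covariate-adjusted regression


@dataclass
class RegressionResult:
    outcome: str
    beta: pd.Series  # standardized coefficients
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    model_p: float
    vif: pd.Series
    residual_normality_p: float
    homoscedasticity_p: float
    n_obs: int
    _sm_result: object = field(repr=False, default=None)

    @property
    def diagnostics_ok(self) -> dict[str, bool]:
        return {
            "residuals_normal": self.residual_normality_p >= 0.05,
            "homoscedastic": self.homoscedasticity_p >= 0.05,
            "vif_below_10": bool((self.vif < 10).all()),
        }

    def summary(self) -> str:
        lines = [
            f"OLS regression of {self.outcome} (standardized predictors), "
            f"n = {self.n_obs}",
            f"R2 = {self.r_squared:.3f}, adjusted R2 = {self.adj_r_squared:.3f}, "
            f"model p = {self.model_p:.4f}",
            f"{'predictor':<32}{'beta':>9}{'t':>9}{'p':>9}{'VIF':>8}",
        ]
        for name in self.beta.index:
            lines.append(
                f"{name:<32}{self.beta[name]:>9.3f}{self.tvalues[name]:>9.3f}"
                f"{self.pvalues[name]:>9.4f}{self.vif.get(name, np.nan):>8.2f}"
            )
        diag = self.diagnostics_ok
        lines.append(
            "diagnostics: "
            + ", ".join(f"{k}={'yes' if v else 'NO'}" for k, v in diag.items())
        )
        return "\n".join(lines)


def regress_clinical(
    outcome: pd.Series, predictors: pd.DataFrame, standardize: bool = True
) -> RegressionResult:
    """OLS of a clinical score on features + covariates, with diagnostics.

    Continuous variables are z-scored so coefficients are standardized
    betas; binary dummies (e.g. sex coded 0/1) are left as is.  Reports
    adjusted R2, per-predictor t and p, VIFs, a Breusch-Pagan
    homoscedasticity p and a Lilliefors residual-normality p.
    """
    data = predictors.copy().astype(float)
    y = outcome.loc[data.index].astype(float)
    if data.shape[0] <= data.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    if standardize:
        for col in data.columns:
            vals = data[col]
            if set(np.unique(vals)) <= {0.0, 1.0}:
                continue  # keep dummies interpretable
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant predictor column {col!r}")
            data[col] = (vals - vals.mean()) / sd
        if y.std(ddof=1) > 0:
            y = (y - y.mean()) / y.std(ddof=1)
    X = sm.add_constant(data)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = data.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(f"singular design matrix; check collinear columns {worst}")
    fit = sm.OLS(y, X).fit()
    exog = X.to_numpy()
    vif = pd.Series(
        {
            col: variance_inflation_factor(exog, i)
            for i, col in enumerate(X.columns)
            if col != "const"
        }
    )
    resid = fit.resid.to_numpy()
    if np.ptp(resid) == 0:
        normality_p, bp_p = 1.0, 1.0
    else:
        _, normality_p = lilliefors(resid, dist="norm")
        _, bp_p, _, _ = het_breuschpagan(resid, exog)
    drop = fit.params.index != "const"
    return RegressionResult(
        outcome=str(outcome.name),
        beta=fit.params[drop],
        tvalues=fit.tvalues[drop],
        pvalues=fit.pvalues[drop],
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        vif=vif,
        residual_normality_p=float(normality_p),
        homoscedasticity_p=float(bp_p),
        n_obs=int(fit.nobs),
        _sm_result=fit,
    )


def regression_per_outcome(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    correlations: pd.DataFrame,
    alpha: float = FDR_ALPHA,
) -> dict[str, RegressionResult]:
    """One model per included score: its FDR-significant features + covariates.

    Covariates: age, sex (0/1), illness duration, total fluoxetine-
    equivalent dose.  Outcomes with no significant feature are skipped.
    """
    if "group" in clinical.columns:
        clinical = clinical[clinical["group"] == "MDD"]
    clinical = clinical.loc[clinical.index.intersection(features.index)]
    covs = pd.DataFrame(index=clinical.index)
    covs["age"] = clinical["age"]
    covs["sex"] = (clinical["sex"].astype(str).str.upper().isin(["F", "FEMALE"])).astype(float)
    covs["duration_months"] = clinical["duration_months"]
    covs["fluoxetine_equiv_mg"] = [
        total_fluoxetine_equivalent([(d, mg)]) if isinstance(d, str) and mg == mg else 0.0
        for d, mg in zip(clinical["medication"], clinical["dose_mg_day"])
    ]
    results: dict[str, RegressionResult] = {}
    for score in correlations["score"].unique():
        sig = correlations[(correlations["score"] == score) & (correlations["q"] < alpha)]
        if sig.empty:
            continue
        preds = pd.concat([features.loc[clinical.index, sig["feature"]], covs], axis=1)
        outcome = clinical[SCORE_COLUMNS[score]].rename(score)
        try:
            results[score] = regress_clinical(outcome, preds)
        except ValueError as e:
            # e.g. cohort too small for the predictor count
            import logging

            logging.getLogger(__name__).warning(
                "skipping regression for %s: %s", score, e
            )
    return results
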