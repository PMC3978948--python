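"""Cohort statistics: stratification, pain and JSN models, CART, ordinal
confirmation.

The pipeline mirrors a two-visit knee-OA cohort analysis.  Pain models are
ordinary least squares of WOMAC pain (0-20) on total-knee BML volume with
sex, weight, height and age as covariates; JSN models are logistic
regressions of baseline joint-space narrowing and of 24-month JSN
progression on index-compartment BML volume with sex, dichotomised age
(>=65 y) and dichotomised BMI (>=30 kg/m^2); volume change enters the
progression model as collapsed-quartile classes (regression / minimal /
progression, reference = minimal).  Knees with severe baseline JSN
(grade 3) cannot progress and are excluded from progression models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cart import CARTConfig, CARTTree, fit_cart as _fit_cart_raw
from .ordinal import fit_proportional_odds, score_test_proportional_odds

PAIN_COVARIATES = ["female", "weight_kg", "height_m", "age"]
JSN_COVARIATES = ["female", "age_ge65", "bmi_ge30"]

CHANGE_CLASSES = ("regression", "minimal", "progression")


@dataclass
class ModelResult:
    """A fitted model in reporting form."""

    name: str
    table: pd.DataFrame | None     # per-term estimate/SE/p (+ OR and CI)
    n_used: int
    c_statistic: float | None = None
    overall_p: float | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stratification

def stratify_baseline_tertiles(volumes) -> tuple[np.ndarray, tuple[float, float]]:
    """Tertile labels 0/1/2 by empirical cut points; ties go lower."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 volumes for tertiles")
    bounds = tuple(np.quantile(v, [1 / 3, 2 / 3]).tolist())
    if bounds[0] == bounds[1]:
        warnings.warn("degenerate tertiles: all cut points equal")
    labels = (v > bounds[0]).astype(int) + (v > bounds[1]).astype(int)
    return labels, bounds


def classify_change(changes, cuts: tuple[float, float] | None = None
                    ) -> tuple[np.ndarray, tuple[float, float]]:
    """Collapsed-quartile change classes.

    Lowest quartile -> ``regression``, middle two -> ``minimal``
    (reference), highest -> ``progression``; ties at a cut point go to the
    lower class.  Pre-computed cut points may be supplied.
    """
    c = np.asarray(changes, dtype=float)
    if cuts is None:
        if c.size < 4:
            raise ValueError("need at least 4 changes for quartiles")
        cuts = tuple(np.quantile(c, [0.25, 0.75]).tolist())
    labels = np.where(c <= cuts[0], "regression",
                      np.where(c <= cuts[1], "minimal", "progression"))
    return labels, cuts


def dichotomize_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Add binary age (>=65 y) and BMI (>=30 kg/m^2) indicators.

    Boundary values map to the upper category; missing values stay
    missing.
    """
    out = table.copy()
    out["age_ge65"] = (out["age"] >= 65).astype(float).where(out["age"].notna())
    out["bmi_ge30"] = (out["bmi"] >= 30).astype(float).where(out["bmi"].notna())
    return out


# ---------------------------------------------------------------------------
# linear (pain) models

def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        corr = np.corrcoef(arr, rowvar=False)
        bad = [X.columns[j] for j in range(arr.shape[1])
               if np.any(np.abs(np.delete(corr[j], j)) > 0.999)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ols(table: pd.DataFrame, outcome: str, predictors: list[str],
         name: str) -> ModelResult:
    cols = [outcome, *predictors]
    df = table[cols].dropna()
    X = sm.add_constant(df[predictors])
    _check_rank(X)
    res = sm.OLS(df[outcome], X).fit()
    tab = pd.DataFrame({"estimate": res.params, "se": res.bse,
                        "pvalue": res.pvalues})
    return ModelResult(name=name, table=tab, n_used=int(res.nobs),
                       diagnostics={"r_squared": float(res.rsquared),
                                    "rows_in": len(table),
                                    "rows_missing": len(table) - len(df)})


def fit_pain_models(table: pd.DataFrame) -> dict[str, ModelResult]:
    """Three OLS models of WOMAC pain on total-knee BML volume.

    1. baseline pain ~ baseline volume; 2. pain change ~ baseline volume;
    3. pain change ~ volume change; all adjusted for sex, weight, height
    and age at the baseline visit.
    """
    return {
        "baseline_pain": _ols(table, "womac_base",
                              ["bml_total_base", *PAIN_COVARIATES],
                              "baseline pain ~ baseline BML volume"),
        "pain_change_baseline_bml": _ols(
            table, "pain_change", ["bml_total_base", *PAIN_COVARIATES],
            "pain change ~ baseline BML volume"),
        "pain_change_bml_change": _ols(
            table, "pain_change", ["bml_total_change", *PAIN_COVARIATES],
            "pain change ~ BML volume change"),
    }


def fit_tertile_robust(table: pd.DataFrame, tertile_labels,
                       weight: str = "huber") -> dict[int, ModelResult]:
    """Robust (M-estimation) pain-change models within baseline tertiles.

    The default is a Huber norm with a widened tuning constant (t = 2) and
    Huber's proposal-2 scale: pain-change scores are discrete with a large
    point mass at zero, which collapses a MAD scale estimate and makes
    hard-rejection norms (bisquare) discard the legitimate tail; the wide
    Huber norm keeps protection against gross outliers at near-OLS
    efficiency.  ``bisquare`` and the classical 95%-efficiency ``huber13``
    remain available.  A tertile with fewer than 10 rows is skipped with a
    warning.
    """
    from statsmodels.robust.scale import HuberScale

    norm = {"bisquare": sm.robust.norms.TukeyBiweight(),
            "huber13": sm.robust.norms.HuberT(),
            "huber": sm.robust.norms.HuberT(t=2.0)}[weight]
    labels = np.asarray(tertile_labels)
    out: dict[int, ModelResult] = {}
    for t in sorted(np.unique(labels)):
        sub = table.loc[labels == t]
        df = sub[["pain_change", "bml_total_change", *PAIN_COVARIATES]].dropna()
        if len(df) < 10:
            warnings.warn(f"tertile {t}: only {len(df)} rows; skipped")
            continue
        X = sm.add_constant(df[["bml_total_change", *PAIN_COVARIATES]])
        res = sm.RLM(df["pain_change"], X, M=norm).fit(scale_est=HuberScale())
        tab = pd.DataFrame({"estimate": res.params, "se": res.bse,
                            "pvalue": 2 * stats.norm.sf(np.abs(res.tvalues))})
        out[int(t)] = ModelResult(
            name=f"robust pain change ~ BML change (tertile {t})",
            table=tab, n_used=int(res.nobs))
    return out


# ---------------------------------------------------------------------------
# logistic (JSN) models

def _logit(df: pd.DataFrame, outcome: str, predictors: list[str],
           name: str, rows_in: int, rows_grade3: int = 0,
           overall_terms: list[str] | None = None) -> ModelResult:
    data = df[[outcome, *predictors]].dropna()
    X = sm.add_constant(data[predictors])
    _check_rank(X)
    try:
        res = sm.Logit(data[outcome], X).fit(disp=False, maxiter=200)
    except np.linalg.LinAlgError:
        # (quasi-)separation: fall back to IRLS with a pseudoinverse; the
        # inflated SEs are flagged below
        res = sm.GLM(data[outcome], X,
                     family=sm.families.Binomial()).fit(maxiter=200)
    se = res.bse
    unstable = bool((se > 10).any())
    ci = res.conf_int()
    tab = pd.DataFrame({
        "estimate": res.params, "se": se, "pvalue": res.pvalues,
        "odds_ratio": np.exp(res.params),
        "ci_low": np.exp(ci[0]), "ci_high": np.exp(ci[1])})
    auc = float(roc_auc_score(data[outcome], res.predict(X)))
    overall_p = None
    if overall_terms:
        wt = res.wald_test([f"{t} = 0" for t in overall_terms], scalar=True)
        overall_p = float(wt.pvalue)
    diag = {"rows_in": rows_in, "rows_grade3_excluded": rows_grade3,
            "rows_missing": rows_in - rows_grade3 - len(data),
            "rows_analyzed": len(data), "unstable_ci": unstable}
    return ModelResult(name=name, table=tab, n_used=len(data),
                       c_statistic=auc, overall_p=overall_p,
                       diagnostics=diag)


def add_jsn_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Derive baseline JSN presence and the at-risk flag."""
    out = table.copy()
    out["jsn_baseline"] = ((out["jsn_medial_base"] >= 1)
                           | (out["jsn_lateral_base"] >= 1)).astype(int)
    index_grade = np.maximum(out["jsn_medial_base"], out["jsn_lateral_base"])
    out["at_risk"] = (index_grade < 3).astype(int)
    return out


def fit_jsn_models(table: pd.DataFrame,
                   change_cuts: tuple[float, float] | None = None
                   ) -> dict[str, ModelResult]:
    """Three logistic models of JSN on index-compartment BML volume.

    1. baseline JSN presence ~ baseline volume (continuous);
    2. progression ~ baseline volume (continuous);
    3. progression ~ change class (reference = minimal);
    all adjusted for sex, binary age and binary BMI; grade-3 knees are
    excluded from the progression models.
    """
    df = dichotomize_covariates(add_jsn_outcomes(table))
    rows_in = len(df)

    m1 = _logit(df, "jsn_baseline", ["bml_index_base", *JSN_COVARIATES],
                "baseline JSN ~ baseline index BML volume", rows_in)

    risk = df[df["at_risk"] == 1].copy()
    n_grade3 = rows_in - len(risk)
    m2 = _logit(risk, "jsn_progression",
                ["bml_index_base", *JSN_COVARIATES],
                "JSN progression ~ baseline index BML volume",
                rows_in, n_grade3)

    labels, cuts = classify_change(risk["bml_index_change"], cuts=change_cuts)
    risk["class_regression"] = (labels == "regression").astype(float)
    risk["class_progression"] = (labels == "progression").astype(float)
    m3 = _logit(risk, "jsn_progression",
                ["class_regression", "class_progression", *JSN_COVARIATES],
                "JSN progression ~ BML change class", rows_in, n_grade3,
                overall_terms=["class_regression", "class_progression"])
    m3.diagnostics["change_class_cuts"] = cuts
    return {"baseline_jsn": m1, "progression_baseline_bml": m2,
            "progression_change_class": m3}


def linearity_check(table: pd.DataFrame, predictor: str, outcome: str,
                    covariates: list[str] | None = None) -> dict:
    """Point estimates across predictor quartiles and a monotone verdict.

    The predictor is replaced by quartile indicators (lowest quartile is
    the reference, estimate 0); a binary outcome gets a logistic fit, a
    continuous outcome OLS.  Used to decide continuous-vs-binary coding.
    """
    covariates = covariates or []
    df = table[[outcome, predictor, *covariates]].dropna().copy()
    q = df[predictor].rank(pct=True)
    for j, (lo, hi) in enumerate([(0.25, 0.5), (0.5, 0.75), (0.75, 1.01)]):
        df[f"q{j + 2}"] = ((q > lo) & (q <= hi)).astype(float)
    terms = [f"q{j}" for j in (2, 3, 4)]
    X = sm.add_constant(df[terms + covariates])
    binary = set(np.unique(df[outcome])) <= {0, 1}
    if df[outcome].nunique() < 2:
        estimates = [0.0, 0.0, 0.0, 0.0]
    else:
        if binary:
            res = sm.Logit(df[outcome], X).fit(disp=False, maxiter=200)
        else:
            res = sm.OLS(df[outcome], X).fit()
        estimates = [0.0] + [float(res.params[t]) for t in terms]
    diffs = np.diff(estimates)
    monotone = bool((diffs >= 0).all() or (diffs <= 0).all())
    return {"estimates": estimates, "monotone": monotone,
            "scale": "log-odds" if binary else "mean"}


# ---------------------------------------------------------------------------
# CART

CART_FEATURES = ["bml_index_base", "bml_index_change", "age", "female", "bmi"]


def fit_cart(table: pd.DataFrame, config: CARTConfig | None = None
             ) -> CARTTree:
    """CART of JSN progression on baseline BML volume, BML change, age,
    sex and BMI, among at-risk knees."""
    df = add_jsn_outcomes(table)
    df = df[df["at_risk"] == 1]
    return _fit_cart_raw(df, "jsn_progression", CART_FEATURES, config)


# ---------------------------------------------------------------------------
# sensitivity and confirmatory analyses

def medial_sensitivity(table: pd.DataFrame) -> ModelResult:
    """Change-class progression model among medially dominant knees.

    The subset keeps knees whose baseline medial JSN grade is at least the
    lateral grade (i.e. primarily-lateral knees are dropped; a no-JSN knee
    counts as medial under the tie rule); change classes are collapsed
    quartiles of medial-compartment BML volume change.
    """
    df = dichotomize_covariates(add_jsn_outcomes(table))
    sub = df[df["jsn_medial_base"] >= df["jsn_lateral_base"]].copy()
    if len(sub) == 0:
        raise ValueError("no medially dominant knees in cohort (n = 0)")
    risk = sub[sub["jsn_medial_base"] < 3].copy()
    if len(risk) < 30 or risk["jsn_progression"].nunique() < 2:
        raise ValueError(
            f"medial-dominant subset too small for the model "
            f"(subset n = {len(sub)}, at-risk n = {len(risk)})")
    labels, cuts = classify_change(risk["bml_medial_change"])
    risk["class_regression"] = (labels == "regression").astype(float)
    risk["class_progression"] = (labels == "progression").astype(float)
    res = _logit(risk, "jsn_progression",
                 ["class_regression", "class_progression", *JSN_COVARIATES],
                 "medial JSN progression ~ medial BML change class",
                 len(sub), len(sub) - len(risk),
                 overall_terms=["class_regression", "class_progression"])
    res.diagnostics["change_class_cuts"] = cuts
    res.diagnostics["subset_n"] = len(sub)
    return res


def confirmatory_ordinal(table: pd.DataFrame, score_alpha: float = 0.05
                         ) -> ModelResult:
    """Ordinal model of cartilage-thickness-loss tertiles on fixed
    +/-3.2 cm^3 BML change classes.

    The outcome is the tertile of cartilage thickness loss (negative
    thickness change).  When the proportional-odds score test rejects at
    ``score_alpha`` the coefficient table is withheld, mirroring the
    convention of not reporting a model that fails its assumption check.
    """
    df = table[["bml_index_change", "cartilage_thickness_change_mm"]].dropna()
    change = df["bml_index_change"].to_numpy()
    classes = np.where(change < -3.2, "regression",
                       np.where(change > 3.2, "progression", "minimal"))
    loss = -df["cartilage_thickness_change_mm"].to_numpy()
    cuts = np.quantile(loss, [1 / 3, 2 / 3])
    y = np.digitize(loss, cuts)
    if np.unique(y).size < 3:
        raise ValueError("fewer than 3 distinct outcome levels")
    X = pd.DataFrame({
        "class_regression": (classes == "regression").astype(float),
        "class_progression": (classes == "progression").astype(float)})
    stat, dof, p_score = score_test_proportional_odds(y, X)
    diag = {"score_test_stat": stat, "score_test_df": dof,
            "score_test_p": p_score,
            "class_counts": {c: int((classes == c).sum())
                             for c in CHANGE_CLASSES}}
    if p_score < score_alpha:
        return ModelResult(
            name="cartilage loss tertile ~ BML change class",
            table=None, n_used=len(df), diagnostics=diag
            | {"withheld": "proportional-odds score test rejected"})
    model, res = fit_proportional_odds(y, X)
    params = res.params[:2]
    se = res.bse[:2]
    tab = pd.DataFrame({
        "estimate": params, "se": se,
        "pvalue": 2 * stats.norm.sf(np.abs(params / se)),
        "odds_ratio": np.exp(params),
        "ci_low": np.exp(params - 1.96 * se),
        "ci_high": np.exp(params + 1.96 * se)})
    wt = res.wald_test(np.eye(len(res.params))[:2], scalar=True)
    return ModelResult(name="cartilage loss tertile ~ BML change class",
                       table=tab, n_used=len(df),
                       overall_p=float(wt.pvalue), diagnostics=diag)
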