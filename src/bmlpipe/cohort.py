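"""Synthetic knee-OA cohort tables with injected association structure.

The generator draws per-knee records for two visits (baseline = 24-month,
follow-up = 48-month) whose marginal distributions match the study sample
it emulates (n = 404, 49% female, age 62.9 +/- 9.2 y, baseline total BML
volume 2.6 +/- 2.7 cm^3 on 0.1-15.5) and whose associations are injected
with known effect sizes, so the downstream estimators can be validated by
parameter recovery:

* baseline WOMAC pain increases with baseline total BML volume
  (``pain_base_slope`` points per cm^3);
* WOMAC pain change increases with total BML volume change
  (``pain_change_slope`` points per cm^3, optionally tertile-specific);
* presence of baseline joint-space narrowing (JSN) in the index
  tibiofemoral compartment follows a logistic model in index-compartment
  BML volume (``or_presence`` per cm^3);
* JSN progression over 24 months among at-risk knees follows a logistic
  model in baseline index BML volume (``or_progression`` per cm^3), or a
  step-risk function for tree-recovery experiments.

Pain scores are beta-binomial on 0-20, which keeps the injected linear
mean structure exact under the bounded support.  Volume change is
multiplicative with a log-baseline-dependent drift, reproducing the
regression-to-the-mean pattern in which large-baseline knees predominantly
shrink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

#: Column dictionary for generated cohort CSVs.
COHORT_COLUMNS = {
    "knee_id": "knee identifier",
    "age": "age in years at baseline (24-month) visit",
    "female": "1 = female, 0 = male",
    "weight_kg": "weight (kg) at baseline",
    "height_m": "height (m) at baseline",
    "bmi": "body mass index (kg/m^2)",
    "womac_base": "WOMAC pain score 0-20 at baseline",
    "womac_fu": "WOMAC pain score 0-20 at follow-up",
    "pain_change": "womac_fu - womac_base",
    "bml_total_base": "total knee BML volume (cm^3) at baseline",
    "bml_total_fu": "total knee BML volume (cm^3) at follow-up",
    "bml_total_change": "bml_total_fu - bml_total_base",
    "bml_medial_base": "medial tibiofemoral compartment BML volume (cm^3)",
    "bml_lateral_base": "lateral tibiofemoral compartment BML volume (cm^3)",
    "bml_medial_change": "medial compartment BML volume change (cm^3)",
    "bml_lateral_change": "lateral compartment BML volume change (cm^3)",
    "bml_index_base": "index-compartment BML volume (cm^3) at baseline",
    "bml_index_change": "index-compartment BML volume change (cm^3)",
    "jsn_medial_base": "OARSI medial JSN grade 0-3 at baseline",
    "jsn_lateral_base": "OARSI lateral JSN grade 0-3 at baseline",
    "jsn_medial_fu": "OARSI medial JSN grade 0-3 at follow-up",
    "jsn_lateral_fu": "OARSI lateral JSN grade 0-3 at follow-up",
    "within_grade_progression": "1 = within-grade JSN progression flag",
    "jsn_progression": "1 = any JSN grade increase incl. within-grade",
}


@dataclass(frozen=True)
class CohortSpec:
    """Marginal and effect parameters of the synthetic cohort."""

    n: int = 404
    seed: int = 0

    # demographics (study-sample marginals)
    age_mean: float = 62.9
    age_sd: float = 9.2
    female_p: float = 0.49
    weight_mean: float = 85.0
    weight_sd: float = 15.4
    height_mean: float = 1.70
    height_sd: float = 0.10

    # baseline total BML volume: left/right-clamped lognormal
    bml_mean: float = 2.6
    bml_sd: float = 2.7
    bml_range: tuple[float, float] = (0.1, 15.5)

    # volume change: V_fu = V * exp(g), g ~ N(a + b*ln V, sd)
    change_mu: float = -0.033
    change_logv_slope: float = -0.127
    change_sd: float = 0.5

    # pain effects (WOMAC points per cm^3)
    womac_mean: float = 3.3
    womac_kappa_base: float = 5.0
    womac_kappa_change: float = 7.4
    pain_base_slope: float = 0.16
    pain_change_slope: float = 0.21
    pain_change_baseline_slope: float = 0.0
    #: optional per-baseline-tertile override of pain_change_slope
    pain_change_slope_tertiles: tuple[float, float, float] | None = None

    # JSN structure
    medial_index_p: float = 0.85
    presence_prevalence: float = 246 / 375
    or_presence: float = 1.50          # per cm^3 of index baseline volume
    progression_rate: float = 68 / 350
    or_progression: float = 1.28       # per cm^3 of index baseline volume
    grade_probs: tuple[float, float, float] = (0.58, 0.32, 0.10)
    within_grade_fraction: float = 0.3
    #: optional step-risk override: (threshold cm^3, p below, p above)
    progression_step: tuple[float, float, float] | None = None
    #: optional medial-compartment change-class effect for sensitivity
    #: experiments: (OR regression class, OR progression class) applied on
    #: top of the baseline-volume model, with fixed class cuts at
    #: medial_class_cuts.
    medial_class_or: tuple[float, float] | None = None
    medial_class_cuts: tuple[float, float] = (-0.46, 0.24)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for p in (self.female_p, self.medial_index_p,
                  self.presence_prevalence, self.progression_rate,
                  self.within_grade_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for o in (self.or_presence, self.or_progression):
            if o <= 0:
                raise ValueError("odds ratios must be positive")
        if self.bml_range[0] >= self.bml_range[1]:
            raise ValueError("bml_range must be increasing")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _clamped_lognormal_params(mean: float, sd: float, lo: float,
                              hi: float) -> tuple[float, float]:
    """Lognormal parameters such that the range-clamped draw has the
    requested mean and SD (the clamp shrinks both, so the pre-clamp
    distribution must be wider)."""
    from scipy import stats

    def moments(m, s):
        F = lambda x: stats.norm.cdf((math.log(x) - m) / s)

        def partial(k, a, b):
            return math.exp(k * m + k * k * s * s / 2) * (
                stats.norm.cdf((math.log(b) - m - k * s * s) / s)
                - stats.norm.cdf((math.log(a) - m - k * s * s) / s))

        m1 = lo * F(lo) + hi * (1 - F(hi)) + partial(1, lo, hi)
        m2 = lo**2 * F(lo) + hi**2 * (1 - F(hi)) + partial(2, lo, hi)
        return m1, math.sqrt(max(m2 - m1 * m1, 1e-12))

    start = _lognormal_params(mean, sd)
    sol, _, ier, _ = optimize.fsolve(
        lambda p: np.array(moments(p[0], p[1])) - np.array([mean, sd]),
        np.asarray(start), full_output=True)
    return tuple(sol) if ier == 1 else start


def _beta_binomial(rng, n_trials: int, mean_p: np.ndarray,
                   kappa: float) -> np.ndarray:
    """Beta-binomial draws with exact mean ``n_trials * mean_p``."""
    p = np.clip(mean_p, 1e-9, 1 - 1e-9)
    probs = rng.beta(p * kappa, (1 - p) * kappa)
    return rng.binomial(n_trials, probs)


def _solve_intercept(target: float, linpred: np.ndarray) -> float:
    """Intercept a with mean(sigmoid(a + linpred)) = target."""

    def f(a):
        return special.expit(a + linpred).mean() - target

    return float(optimize.brentq(f, -30.0, 30.0))


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a paired-visit cohort table (one row per knee)."""
    spec = spec or CohortSpec()
    spec.validate()
    n = spec.n
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    female = rng.binomial(1, spec.female_p, n)
    weight = np.clip(rng.normal(spec.weight_mean, spec.weight_sd, n), 40, 160)
    height = np.clip(rng.normal(spec.height_mean, spec.height_sd, n), 1.4, 2.1)
    bmi = weight / height**2

    mu, sig = _clamped_lognormal_params(spec.bml_mean, spec.bml_sd,
                                        *spec.bml_range)
    v_base = np.clip(rng.lognormal(mu, sig, n), *spec.bml_range)

    g = rng.normal(spec.change_mu + spec.change_logv_slope * np.log(v_base),
                   spec.change_sd)
    v_fu = v_base * np.exp(g)
    v_change = v_fu - v_base

    # compartment split; the medial share is constant across visits
    index_medial = rng.random(n) < spec.medial_index_p
    m_share = np.where(index_medial, rng.beta(7, 3, n), rng.beta(3, 7, n))
    v_med_b, v_lat_b = v_base * m_share, v_base * (1 - m_share)
    v_med_c, v_lat_c = v_change * m_share, v_change * (1 - m_share)
    v_index_b = np.where(index_medial, v_med_b, v_lat_b)
    v_index_c = np.where(index_medial, v_med_c, v_lat_c)

    # --- baseline JSN presence (injected logistic in index volume)
    lin1 = math.log(spec.or_presence) * v_index_b
    a1 = _solve_intercept(spec.presence_prevalence, lin1)
    presence = rng.random(n) < special.expit(a1 + lin1)
    # A knee without any JSN has grades 0/0, and the tie rule then makes
    # its index compartment medial.  For the (few) no-JSN knees whose
    # preferred compartment was lateral, relabel the sides so the index
    # volume the analysis reads is the one the presence model was driven
    # by: side labels are exchangeable for a knee with no JSN.
    swap = ~presence & ~index_medial
    v_med_b, v_lat_b = (np.where(swap, v_lat_b, v_med_b),
                        np.where(swap, v_med_b, v_lat_b))
    v_med_c, v_lat_c = (np.where(swap, v_lat_c, v_med_c),
                        np.where(swap, v_med_c, v_lat_c))
    index_medial = np.where(presence, index_medial, True)
    v_index_b = np.where(index_medial, v_med_b, v_lat_b)
    v_index_c = np.where(index_medial, v_med_c, v_lat_c)

    grade_index = np.where(
        presence,
        rng.choice([1, 2, 3], size=n, p=list(spec.grade_probs)), 0)
    # the non-index side never exceeds the index side (strictly lower when
    # the index is lateral, so the tie-goes-medial rule stays consistent)
    upper = np.where(index_medial, grade_index, np.maximum(grade_index - 1, 0))
    grade_other = rng.integers(0, upper + 1)
    jsn_med_b = np.where(index_medial, grade_index, grade_other)
    jsn_lat_b = np.where(index_medial, grade_other, grade_index)

    # --- JSN progression among at-risk knees (index grade < 3)
    at_risk = grade_index < 3
    if spec.progression_step is not None:
        thr, p_lo, p_hi = spec.progression_step
        p_prog = np.where(v_index_b < thr, p_lo, p_hi)
    else:
        lin2 = math.log(spec.or_progression) * v_index_b
        if spec.medial_class_or is not None:
            or_reg, or_prog = spec.medial_class_or
            lo, hi = spec.medial_class_cuts
            lin2 = lin2 + np.where(
                index_medial & (v_med_c <= lo), math.log(or_reg), 0.0)
            lin2 = lin2 + np.where(
                index_medial & (v_med_c > hi), math.log(or_prog), 0.0)
        a2 = _solve_intercept(spec.progression_rate, lin2[at_risk])
        p_prog = special.expit(a2 + lin2)
    progression = at_risk & (rng.random(n) < p_prog)

    within_grade = progression & (rng.random(n) < spec.within_grade_fraction)
    grade_up = progression & ~within_grade
    jsn_med_fu = np.minimum(jsn_med_b + np.where(grade_up & index_medial, 1, 0), 3)
    jsn_lat_fu = np.minimum(jsn_lat_b + np.where(grade_up & ~index_medial, 1, 0), 3)

    # --- WOMAC pain.  Each knee has a latent pain propensity u (beta
    # around a mean linear in baseline volume); both visits draw binomial
    # scores from it, with the follow-up propensity scaled so that the
    # expected pain change is exactly the injected shift despite the
    # bounded 0-20 support (see the package methods note).
    b0 = spec.womac_mean - spec.pain_base_slope * spec.bml_mean
    mean_base = b0 + spec.pain_base_slope * v_base          # in points
    u = rng.beta(spec.womac_kappa_base * mean_base / 20.0,
                 spec.womac_kappa_base * (1 - mean_base / 20.0))
    womac_base = rng.binomial(20, u)

    if spec.pain_change_slope_tertiles is not None:
        cuts = np.quantile(v_base, [1 / 3, 2 / 3]) if n >= 3 else [0, 0]
        tert = np.digitize(v_base, cuts)
        slope = np.asarray(spec.pain_change_slope_tertiles)[tert]
    else:
        slope = spec.pain_change_slope
    shift = slope * v_change + spec.pain_change_baseline_slope * v_base
    factor = np.maximum(1.0 + shift / mean_base, 0.0)
    womac_fu = rng.binomial(20, np.minimum(u * factor, 1.0))

    return pd.DataFrame({
        "knee_id": [f"K{i:05d}" for i in range(n)],
        "age": age,
        "female": female,
        "weight_kg": weight,
        "height_m": height,
        "bmi": bmi,
        "womac_base": womac_base,
        "womac_fu": womac_fu,
        "pain_change": womac_fu.astype(float) - womac_base,
        "bml_total_base": v_base,
        "bml_total_fu": v_fu,
        "bml_total_change": v_change,
        "bml_medial_base": v_med_b,
        "bml_lateral_base": v_lat_b,
        "bml_medial_change": v_med_c,
        "bml_lateral_change": v_lat_c,
        "bml_index_base": v_index_b,
        "bml_index_change": v_index_c,
        "jsn_medial_base": jsn_med_b,
        "jsn_lateral_base": jsn_lat_b,
        "jsn_medial_fu": jsn_med_fu,
        "jsn_lateral_fu": jsn_lat_fu,
        "within_grade_progression": within_grade.astype(int),
        "jsn_progression": progression.astype(int),
    })


# ---------------------------------------------------------------------------
# confirmatory (manual-measurement) cohort

@dataclass(frozen=True)
class ConfirmatorySpec:
    """Cohort for the ordinal cartilage-thickness confirmation analysis.

    BML volume change is classified by fixed +/-3.2 cm^3 thresholds; the
    cartilage-loss outcome follows an exact proportional-odds structure
    (logistic latent with class shifts), so any tertile cut of the latent
    yields the injected ORs.
    """

    n: int = 103
    seed: int = 0
    change_mean: float = 0.9
    change_sd: float = 4.9
    or_regression: float = 2.72
    or_progression: float = 2.06
    latent_scale_mm: float = 0.2

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.or_regression <= 0 or self.or_progression <= 0:
            raise ValueError("odds ratios must be positive")


def generate_confirmatory_cohort(spec: ConfirmatorySpec | None = None
                                 ) -> pd.DataFrame:
    spec = spec or ConfirmatorySpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    change = rng.normal(spec.change_mean, spec.change_sd, n)
    reg = change < -3.2
    prog = change > 3.2
    latent_loss = (math.log(spec.or_regression) * reg
                   + math.log(spec.or_progression) * prog
                   + rng.logistic(0.0, 1.0, n))
    return pd.DataFrame({
        "knee_id": [f"C{i:04d}" for i in range(n)],
        "bml_index_change": change,
        "cartilage_thickness_change_mm": -spec.latent_scale_mm * latent_loss,
    })
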