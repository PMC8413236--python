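"""Synthetic IPF cohorts with PPFE-dependent FVC trajectories and survival.

The generator draws subject-level covariates (age, gender, smoking,
antifibrotic exposure, DLco, centre), assigns a PPFE category
(absent / moderate / marked) with a continuous computerised score
conditional on category, and then simulates

* longitudinal absolute FVC from a linear mixed-effects structure — random
  intercept and random slope per subject, Gaussian residuals, with an extra
  per-year decline (as a percentage of the subject's baseline FVC) attached
  to the PPFE category; and
* survival from an exponential proportional-hazards model with optional
  per-centre gamma frailty and independent uniform censoring.

Every generative parameter is recorded in the returned truth dictionary so
downstream estimators can be checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("absent", "moderate", "marked")


@dataclass
class FVCModelSpec:
    """Generative linear mixed-effects structure for absolute FVC (litres)."""

    slope_base: float = -0.12  # L/year drift shared by all subjects
    slope_antifibrotic: float = 0.04  # antifibrotics slow decline
    slope_ever_smoker: float = -0.01
    slope_age_per_year: float = 0.0
    slope_male: float = 0.0
    # extra decline attached to PPFE category, in percent of baseline FVC
    # per year (absent, moderate, marked)
    extra_decline_percent: tuple[float, float, float] = (0.0, 5.2, 18.3)
    re_sd_intercept: float = 0.15  # L
    re_sd_slope: float = 0.08  # L/year
    re_corr: float = 0.0
    residual_sd: float = 0.12  # L
    visit_times: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5)


@dataclass
class SurvivalModelSpec:
    """Exponential proportional-hazards mortality with uniform censoring."""

    baseline_hazard: float = 0.16  # events per person-year at covariate zero
    hr_moderate: float = 2.4
    hr_marked: float = 7.7
    hr_cppfe_flag: float = 1.0  # applied to cppfe >= 2.5% instead of / on top of categories
    hr_dlco_per_percent: float = 0.97  # per percent-predicted DLco above 50
    hr_antifibrotic: float = 0.64
    hr_male: float = 1.0
    hr_ever_smoker: float = 1.0
    hr_age_per_year: float = 1.0  # per year above 68
    frailty_variance: float = 0.0  # gamma frailty shared within centre
    censor_low: float = 0.5  # years
    censor_high: float = 8.0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.frailty_variance < 0:
            raise ValueError("frailty variance must be non-negative")
        if not 0 <= self.censor_low < self.censor_high:
            raise ValueError("censoring window must satisfy 0 <= low < high")


@dataclass
class CohortSpec:
    n_subjects: int = 300
    seed: int = 0
    age_mean: float = 68.0
    age_sd: float = 9.0
    male_prob: float = 0.79
    ever_smoker_prob: float = 0.71
    antifibrotic_prob: float = 0.67
    dlco_mean: float = 50.0
    dlco_sd: float = 16.0
    prob_missing_dlco: float = 0.0
    prob_no_followup: float = 0.0  # subjects left with the baseline visit only
    centre_labels: Sequence[str] = ("A",)
    centre_probs: Sequence[float] = (1.0,)
    ppfe_category_probs: tuple[float, float, float] = (0.45, 0.44, 0.11)
    fvc_ppred_mean: float = 77.0
    fvc_ppred_sd: float = 20.0
    predicted_fvc_mean: float = 3.8  # L, reference value FVC is a percent of
    predicted_fvc_sd: float = 0.6
    fvc_model: FVCModelSpec = field(default_factory=FVCModelSpec)
    survival_model: SurvivalModelSpec = field(default_factory=SurvivalModelSpec)

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if abs(sum(self.ppfe_category_probs) - 1.0) > 1e-9:
            raise ValueError("ppfe_category_probs must sum to 1")
        if abs(sum(self.centre_probs) - 1.0) > 1e-9:
            raise ValueError("centre_probs must sum to 1")
        if len(self.centre_probs) != len(self.centre_labels):
            raise ValueError("centre_labels and centre_probs must align")
        m = self.fvc_model
        if m.re_sd_intercept < 0 or m.re_sd_slope < 0 or not -1 < m.re_corr < 1:
            raise ValueError("random-effects covariance must be positive semi-definite")
        if m.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        self.survival_model.validate()


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    fvc_long: pd.DataFrame
    survival: pd.DataFrame
    truth: dict

    def save_csv(self, directory: str) -> None:
        import os

        self.subjects.to_csv(os.path.join(directory, "subjects.csv"), index=False)
        self.fvc_long.to_csv(os.path.join(directory, "fvc_long.csv"), index=False)
        self.survival.to_csv(os.path.join(directory, "survival.csv"), index=False)


_SUBJECT_COLUMNS = [
    "subject_id", "age", "male", "ever_smoker", "antifibrotic", "dlco_ppred",
    "centre", "ppfe_category", "cppfe_percent", "cppfe_ge_cutpoint",
    "vppfe_rul", "vppfe_lul", "vppfe_seven_point",
    "baseline_fvc_ppred", "baseline_fvc_abs", "true_intercept_l",
    "true_slope_l_per_year", "true_decline_percent", "true_log_hazard",
]


def _empty_cohort(spec: CohortSpec) -> SyntheticCohort:
    return SyntheticCohort(
        subjects=pd.DataFrame(columns=_SUBJECT_COLUMNS),
        fvc_long=pd.DataFrame(columns=["subject_id", "time_years", "fvc_l"]),
        survival=pd.DataFrame(columns=["subject_id", "time_years", "event"]),
        truth={"spec_seed": spec.seed, "n_subjects": 0},
    )


def _draw_cppfe(rng: np.random.Generator, category: np.ndarray) -> np.ndarray:
    """Continuous computerised score conditional on visual category."""
    n = category.size
    out = np.zeros(n)
    mod = category == 1
    mar = category == 2
    out[mod] = np.minimum(rng.lognormal(np.log(1.8), 0.7, mod.sum()), 30.0)
    out[mar] = np.minimum(5.0 + rng.lognormal(np.log(4.0), 0.6, mar.sum()), 60.0)
    return out


def _draw_upper_lobe_grades(rng: np.random.Generator, category: np.ndarray):
    """(RUL, LUL) grades consistent with the category of their sum."""
    n = category.size
    rul = np.zeros(n, dtype=int)
    lul = np.zeros(n, dtype=int)
    for i, cat in enumerate(category):
        if cat == 1:  # sum 1 or 2
            rul[i], lul[i] = [(0, 1), (1, 0), (1, 1)][rng.integers(3)]
        elif cat == 2:  # sum 3..6
            total = rng.integers(3, 7)
            rul[i] = int(np.clip(rng.integers(total - 3, 4), max(0, total - 3), 3))
            lul[i] = total - rul[i]
            if lul[i] > 3:  # rebalance
                rul[i] += lul[i] - 3
                lul[i] = 3
    return rul, lul


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a cohort; deterministic for a fixed ``spec.seed``."""
    spec.validate()
    if spec.n_subjects == 0:
        return _empty_cohort(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    fm, sm = spec.fvc_model, spec.survival_model

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 40, 92)
    male = rng.random(n) < spec.male_prob
    smoker = rng.random(n) < spec.ever_smoker_prob
    antifib = rng.random(n) < spec.antifibrotic_prob
    dlco = np.clip(rng.normal(spec.dlco_mean, spec.dlco_sd, n), 18, 120)
    centre = rng.choice(list(spec.centre_labels), size=n, p=list(spec.centre_probs))
    category = rng.choice(3, size=n, p=list(spec.ppfe_category_probs))
    cppfe = _draw_cppfe(rng, category)
    rul, lul = _draw_upper_lobe_grades(rng, category)

    ppred = np.clip(rng.normal(spec.fvc_ppred_mean, spec.fvc_ppred_sd, n), 40, 130)
    pred_fvc = np.clip(rng.normal(spec.predicted_fvc_mean, spec.predicted_fvc_sd, n), 2.0, 6.5)
    baseline_abs = ppred / 100.0 * pred_fvc

    cov_re = np.array(
        [[fm.re_sd_intercept ** 2,
          fm.re_corr * fm.re_sd_intercept * fm.re_sd_slope],
         [fm.re_corr * fm.re_sd_intercept * fm.re_sd_slope,
          fm.re_sd_slope ** 2]]
    )
    re = rng.multivariate_normal([0.0, 0.0], cov_re, size=n)
    extra = np.asarray(fm.extra_decline_percent)[category]
    intercept_i = baseline_abs + re[:, 0]
    slope_i = (
        fm.slope_base
        + fm.slope_antifibrotic * antifib
        + fm.slope_ever_smoker * smoker
        + fm.slope_age_per_year * (age - spec.age_mean)
        + fm.slope_male * male
        + re[:, 1]
        - extra / 100.0 * intercept_i
    )
    true_decline_pct = -100.0 * slope_i / intercept_i

    times = np.asarray(list(fm.visit_times), dtype=float)
    no_fu = rng.random(n) < spec.prob_no_followup
    rows = []
    for i in range(n):
        t_i = times[:1] if no_fu[i] else times
        fvc = intercept_i[i] + slope_i[i] * t_i
        if fm.residual_sd > 0:
            fvc = fvc + rng.normal(0.0, fm.residual_sd, t_i.size)
        for t, v in zip(t_i, fvc):
            rows.append((f"S{i:05d}", float(t), float(max(v, 0.2))))
    fvc_long = pd.DataFrame(rows, columns=["subject_id", "time_years", "fvc_l"])

    log_h = (
        np.log(sm.baseline_hazard)
        + np.log(sm.hr_moderate) * (category == 1)
        + np.log(sm.hr_marked) * (category == 2)
        + np.log(sm.hr_cppfe_flag) * (cppfe >= 2.5)
        + np.log(sm.hr_dlco_per_percent) * (dlco - 50.0)
        + np.log(sm.hr_antifibrotic) * antifib
        + np.log(sm.hr_male) * male
        + np.log(sm.hr_ever_smoker) * smoker
        + np.log(sm.hr_age_per_year) * (age - 68.0)
    )
    if sm.frailty_variance > 0:
        shape = 1.0 / sm.frailty_variance
        frailty_by_centre = {
            c: rng.gamma(shape, sm.frailty_variance) for c in spec.centre_labels
        }
        log_h = log_h + np.log([frailty_by_centre[c] for c in centre])
    else:
        frailty_by_centre = {c: 1.0 for c in spec.centre_labels}
    t_event = rng.exponential(1.0, n) / np.exp(log_h)
    t_cens = rng.uniform(sm.censor_low, sm.censor_high, n)
    time_obs = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    missing_dlco = rng.random(n) < spec.prob_missing_dlco
    dlco_out = dlco.copy()
    dlco_out[missing_dlco] = np.nan

    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "male": male.astype(int),
            "ever_smoker": smoker.astype(int),
            "antifibrotic": antifib.astype(int),
            "dlco_ppred": np.round(dlco_out, 1),
            "centre": centre,
            "ppfe_category": [CATEGORIES[c] for c in category],
            "cppfe_percent": np.round(cppfe, 3),
            "cppfe_ge_cutpoint": (cppfe >= 2.5).astype(int),
            "vppfe_rul": rul,
            "vppfe_lul": lul,
            "vppfe_seven_point": rul + lul,
            "baseline_fvc_ppred": np.round(ppred, 1),
            "baseline_fvc_abs": baseline_abs,
            "true_intercept_l": intercept_i,
            "true_slope_l_per_year": slope_i,
            "true_decline_percent": true_decline_pct,
            "true_log_hazard": log_h,
        }
    )
    survival = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"],
            "time_years": np.maximum(time_obs, 1e-4),
            "event": event,
        }
    )
    truth = {
        "seed": spec.seed,
        "n_subjects": n,
        "extra_decline_percent": list(fm.extra_decline_percent),
        "slope_base": fm.slope_base,
        "residual_sd": fm.residual_sd,
        "re_sd_intercept": fm.re_sd_intercept,
        "re_sd_slope": fm.re_sd_slope,
        "baseline_hazard": sm.baseline_hazard,
        "hr_moderate": sm.hr_moderate,
        "hr_marked": sm.hr_marked,
        "hr_dlco_per_percent": sm.hr_dlco_per_percent,
        "hr_antifibrotic": sm.hr_antifibrotic,
        "frailty_variance": sm.frailty_variance,
        "frailty_by_centre": frailty_by_centre,
        "censor_window": [sm.censor_low, sm.censor_high],
    }
    return SyntheticCohort(subjects=subjects, fvc_long=fvc_long,
                           survival=survival, truth=truth)


def expected_event_fraction(spec: CohortSpec, subjects: pd.DataFrame) -> float:
    """Analytic P(event) implied by the hazards and uniform censoring.

    With T ~ Exp(h) and independent C ~ U(a, b),
    P(T <= C | h) = 1 - (exp(-h a) - exp(-h b)) / (h (b - a)).
    Averaged over the cohort's realised hazards.
    """
    sm = spec.survival_model
    h = np.exp(subjects["true_log_hazard"].to_numpy())
    a, b = sm.censor_low, sm.censor_high
    p = 1.0 - (np.exp(-h * a) - np.exp(-h * b)) / (h * (b - a))
    return float(np.mean(p))
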