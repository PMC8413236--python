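"""LME-predicted 1-year FVC decline and its regression on PPFE variables.

The outcome statistic: fit a linear mixed-effects (LME) model to the first
18 months of absolute FVC after the baseline CT — random intercept and
random slope per subject; fixed effects for gender, age, smoking status,
antifibrotic use, baseline percent-predicted FVC, and study time — then for
each subject define

    decline% = 100 * (observed baseline FVC - predicted FVC at 1 year)
                    / observed baseline FVC,

where the prediction is subject-specific (fixed part plus the subject's
predicted random effects) and the observed baseline is the measurement
closest to the baseline CT within +/-3 months, ties broken toward the
earlier measurement. Positive values mean FVC fell.

The decline is then regressed on a PPFE variable with the standard covariate
set: ordinary least squares for a single-centre (derivation-style) cohort,
or a mixed model with a centre grouping term for a multi-centre
(validation-style) cohort. Multivariable linear models are checked for
heteroscedasticity with the studentised Breusch-Pagan test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import het_breuschpagan

BASELINE_WINDOW_YEARS = 3.0 / 12.0
FOLLOWUP_MIN_YEARS = 3.0 / 12.0
FOLLOWUP_MAX_YEARS = 18.0 / 12.0

FIXED_EFFECTS = ["male", "age", "ever_smoker", "antifibrotic", "baseline_fvc_ppred"]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# eligibility

def apply_fvc_eligibility(fvc_long: pd.DataFrame,
                          baseline_window: float = BASELINE_WINDOW_YEARS,
                          followup_min: float = FOLLOWUP_MIN_YEARS,
                          followup_max: float = FOLLOWUP_MAX_YEARS):
    """Keep subjects with a baseline FVC (within 3 months of the baseline CT)
    and at least one further measurement 3-18 months after baseline.

    Returns the filtered long table and a machine-readable exclusion log.
    The filter is idempotent and order-independent: it is a pure per-subject
    predicate on measurement times.
    """
    log = []
    eligible_ids = []
    for sid, grp in fvc_long.groupby("subject_id", sort=True):
        t = grp["time_years"].to_numpy()
        has_baseline = bool((np.abs(t) <= baseline_window).any())
        has_followup = bool(((t > followup_min) & (t <= followup_max)).any())
        if has_baseline and has_followup:
            eligible_ids.append(sid)
        elif not has_baseline:
            log.append({"subject_id": sid, "reason": "no_fvc_within_3m_of_baseline"})
        else:
            log.append({"subject_id": sid, "reason": "no_fvc_3_to_18m_after_baseline"})
    out = fvc_long[fvc_long["subject_id"].isin(eligible_ids)].copy()
    return out, log


def apply_cohort_eligibility(subjects: pd.DataFrame,
                             require_dlco: bool = True,
                             trial_subset: bool = False):
    """Table-driven cohort filters.

    Always excluded: missing antifibrotic information. With
    ``require_dlco`` (the multivariable-analysis rule), subjects with no
    DLco measurement are excluded. ``trial_subset`` additionally restricts
    to the antifibrotic-regulatory window: FVC >= 50% predicted and DLco in
    [30, 79]% predicted (both bounds inclusive).
    """
    log = []
    keep = pd.Series(True, index=subjects.index)
    if "antifibrotic" in subjects.columns:
        bad = subjects["antifibrotic"].isna()
        for sid in subjects.loc[bad, "subject_id"]:
            log.append({"subject_id": sid, "reason": "missing_antifibrotic_info"})
        keep &= ~bad
    if require_dlco:
        bad = subjects["dlco_ppred"].isna()
        for sid in subjects.loc[bad & keep, "subject_id"]:
            log.append({"subject_id": sid, "reason": "missing_dlco"})
        keep &= ~bad
    if trial_subset:
        fvc_ok = subjects["baseline_fvc_ppred"] >= 50.0
        dlco_ok = subjects["dlco_ppred"].between(30.0, 79.0, inclusive="both")
        bad = ~(fvc_ok & dlco_ok.fillna(False))
        for sid in subjects.loc[bad & keep, "subject_id"]:
            log.append({"subject_id": sid, "reason": "outside_trial_subset_window"})
        keep &= ~bad
    return subjects[keep].copy(), log


# ---------------------------------------------------------------------------
# LME fit and per-subject decline

@dataclass
class FVCModelFit:
    result: object  # statsmodels MixedLMResults
    design: pd.DataFrame
    fixed_effects: pd.Series
    random_effects: dict
    converged: bool


def _build_design(fvc_long: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    need = {"subject_id", *FIXED_EFFECTS}
    missing = need - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table lacks columns: {sorted(missing)}")
    df = fvc_long.merge(subjects[list(need)], on="subject_id", how="inner")
    if df.isna().any().any():
        raise ValueError("design contains missing values; filter eligibility first")
    return df


def fit_fvc_lme(fvc_long: pd.DataFrame, subjects: pd.DataFrame,
                reml: bool = True) -> FVCModelFit:
    """REML fit of the trajectory model with random intercept and slope.

    Raises ConvergenceError when the optimiser fails, and ValueError for a
    rank-deficient fixed-effects design.
    """
    df = _build_design(fvc_long, subjects)
    counts = df.groupby("subject_id").size()
    if (counts < 2).any():
        raise ValueError(
            "every subject must have >= 2 FVC measurements; "
            "apply_fvc_eligibility first"
        )
    exog = sm.add_constant(df[FIXED_EFFECTS + ["time_years"]].astype(float))
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    model = sm.MixedLM(
        endog=df["fvc_l"].astype(float),
        exog=exog,
        groups=df["subject_id"],
        exog_re=sm.add_constant(df[["time_years"]].astype(float)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
        except Exception as exc:  # noqa: BLE001 - surfaced with diagnostics
            raise ConvergenceError(f"mixed-model fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError(
            "mixed-model fit did not converge; "
            f"gradient norm {np.linalg.norm(getattr(res, 'score', np.nan)):.3g}"
        )
    return FVCModelFit(
        result=res,
        design=df,
        fixed_effects=res.fe_params,
        random_effects=res.random_effects,
        converged=bool(res.converged),
    )


@dataclass
class DeclineEstimate:
    subject_id: str
    baseline_fvc_obs: float
    predicted_fvc_1y: float
    decline_percent: float


def observed_baseline_fvc(fvc_long: pd.DataFrame, subject_id: str,
                          window: float = BASELINE_WINDOW_YEARS) -> float:
    """Measurement closest to the baseline CT within +/-3 months; ties go to
    the earlier measurement."""
    grp = fvc_long[fvc_long["subject_id"] == subject_id]
    grp = grp[np.abs(grp["time_years"]) <= window]
    if grp.empty:
        raise ValueError(f"{subject_id}: no FVC within the baseline window")
    order = grp.assign(absdist=np.abs(grp["time_years"]))
    order = order.sort_values(["absdist", "time_years"], kind="stable")
    return float(order["fvc_l"].iloc[0])


def predict_decline(fit: FVCModelFit, subject_id: str,
                    subject_specific: bool = True) -> DeclineEstimate:
    """Subject-level 1-year decline as a percentage of observed baseline FVC."""
    df = fit.design
    rows = df[df["subject_id"] == subject_id]
    if rows.empty:
        raise KeyError(f"{subject_id} was not part of the fitted model")
    x = rows.iloc[0]
    fe = fit.fixed_effects
    pred = (
        fe["const"]
        + sum(fe[c] * float(x[c]) for c in FIXED_EFFECTS)
        + fe["time_years"] * 1.0
    )
    if subject_specific:
        re = fit.random_effects[subject_id]
        pred += float(re.iloc[0])  # random intercept
        if len(re) > 1:
            pred += float(re.iloc[1]) * 1.0  # random slope at t = 1
    base = observed_baseline_fvc(df, subject_id)
    return DeclineEstimate(
        subject_id=subject_id,
        baseline_fvc_obs=base,
        predicted_fvc_1y=float(pred),
        decline_percent=100.0 * (base - float(pred)) / base,
    )


def decline_table(fit: FVCModelFit, subject_specific: bool = True) -> pd.DataFrame:
    rows = [
        predict_decline(fit, sid, subject_specific=subject_specific)
        for sid in fit.design["subject_id"].unique()
    ]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "baseline_fvc_obs": [r.baseline_fvc_obs for r in rows],
            "predicted_fvc_1y": [r.predicted_fvc_1y for r in rows],
            "decline_percent": [r.decline_percent for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# decline ~ PPFE regression

ADJUSTMENT_COVARIATES = ["age", "male", "ever_smoker", "antifibrotic", "dlco_ppred"]


@dataclass
class RegressionReport:
    table: pd.DataFrame  # term, beta, ci_low, ci_high, p
    r_squared: float | None
    breusch_pagan_lm: float | None
    breusch_pagan_p: float | None
    mode: str
    n: int = 0
    extra: dict = field(default_factory=dict)


def regress_decline(declines: pd.DataFrame, subjects: pd.DataFrame,
                    ppfe_terms: list[str], mode: str = "derivation",
                    adjust: bool = True) -> RegressionReport:
    """Regress decline% on PPFE variables with the standard covariate set.

    mode="derivation": ordinary linear model (single centre).
    mode="validation": linear mixed model with a random intercept per centre
    to absorb between-centre differences; requires >= 2 centres.
    """
    if mode not in ("derivation", "validation"):
        raise ValueError("mode must be 'derivation' or 'validation'")
    covs = ADJUSTMENT_COVARIATES if adjust else []
    cols = ["subject_id"] + ppfe_terms + covs + (
        ["centre"] if mode == "validation" else []
    )
    df = declines.merge(subjects[cols], on="subject_id", how="inner").dropna(
        subset=ppfe_terms + covs
    )
    terms = ppfe_terms + covs
    formula = "decline_percent ~ " + " + ".join(terms)
    if mode == "derivation":
        fit = smf.ols(formula, data=df).fit()
        ci = fit.conf_int()
        table = pd.DataFrame(
            {
                "term": fit.params.index,
                "beta": fit.params.to_numpy(),
                "ci_low": ci[0].to_numpy(),
                "ci_high": ci[1].to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
        lm_stat, lm_p, _, _ = het_breuschpagan(
            fit.resid, fit.model.exog, robust=True
        )
        return RegressionReport(table=table, r_squared=float(fit.rsquared),
                                breusch_pagan_lm=float(lm_stat),
                                breusch_pagan_p=float(lm_p),
                                mode=mode, n=len(df))
    if df["centre"].nunique() < 2:
        raise ValueError("validation mode needs >= 2 centres")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(formula, data=df, groups=df["centre"]).fit(
            method=["lbfgs", "bfgs"]
        )
    ci = fit.conf_int()
    keep = fit.fe_params.index
    table = pd.DataFrame(
        {
            "term": keep,
            "beta": fit.fe_params.to_numpy(),
            "ci_low": ci.loc[keep, 0].to_numpy(),
            "ci_high": ci.loc[keep, 1].to_numpy(),
            "p": fit.pvalues.loc[keep].to_numpy(),
        }
    )
    return RegressionReport(table=table, r_squared=None,
                            breusch_pagan_lm=None, breusch_pagan_p=None,
                            mode=mode, n=len(df))
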