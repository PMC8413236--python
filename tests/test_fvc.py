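"""Eligibility filters, LME trajectory fit, and the 1-year decline statistic."""

import numpy as np
import pandas as pd
import pytest

from ppfequant.fvc import (apply_cohort_eligibility,
                           apply_fvc_eligibility, decline_table, fit_fvc_lme,
                           observed_baseline_fvc, predict_decline,
                           regress_decline)
from ppfequant.synthetic.cohort import CohortSpec, FVCModelSpec, generate_cohort


def long_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "time_years", "fvc_l"])


class TestEligibility:
    def test_fvc_measurement_rule(self):
        df = long_frame([
            ("baseline_only", 0.0, 3.0),
            ("ok", 0.0, 3.0), ("ok", 1.0, 2.8),
            ("early_only", 0.0, 3.0), ("early_only", 2 / 12, 2.9),
            ("no_baseline", 0.5, 3.0), ("no_baseline", 1.0, 2.9),
        ])
        kept, log = apply_fvc_eligibility(df)
        assert set(kept["subject_id"]) == {"ok"}
        reasons = {e["subject_id"]: e["reason"] for e in log}
        assert reasons["baseline_only"] == "no_fvc_3_to_18m_after_baseline"
        assert reasons["early_only"] == "no_fvc_3_to_18m_after_baseline"
        assert reasons["no_baseline"] == "no_fvc_within_3m_of_baseline"

    def test_filter_idempotent(self):
        df = long_frame([("a", 0.0, 3.0), ("a", 0.9, 2.9), ("b", 0.0, 3.0)])
        once, _ = apply_fvc_eligibility(df)
        twice, log2 = apply_fvc_eligibility(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2 == []

    def test_trial_subset_window(self):
        subjects = pd.DataFrame(
            {
                "subject_id": ["low_fvc", "dlco_hi_ok", "dlco_too_high",
                               "missing_dlco", "ok"],
                "baseline_fvc_ppred": [49.0, 80.0, 80.0, 80.0, 60.0],
                "dlco_ppred": [50.0, 79.0, 80.0, np.nan, 45.0],
                "antifibrotic": [1, 0, 1, 1, 0],
            }
        )
        kept, log = apply_cohort_eligibility(subjects, trial_subset=True)
        assert set(kept["subject_id"]) == {"dlco_hi_ok", "ok"}
        reasons = {e["subject_id"]: e["reason"] for e in log}
        assert reasons["low_fvc"] == "outside_trial_subset_window"
        assert reasons["missing_dlco"] == "missing_dlco"

    def test_missing_antifibrotic_excluded(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a", "b"], "baseline_fvc_ppred": [70.0, 70.0],
             "dlco_ppred": [50.0, 50.0], "antifibrotic": [np.nan, 1]}
        )
        kept, log = apply_cohort_eligibility(subjects)
        assert list(kept["subject_id"]) == ["b"]
        assert log[0]["reason"] == "missing_antifibrotic_info"


@pytest.fixture(scope="module")
def noise_free_fit():
    spec = CohortSpec(
        n_subjects=40, seed=1,
        fvc_model=FVCModelSpec(slope_base=-0.3, slope_antifibrotic=0.0,
                               slope_ever_smoker=0.0,
                               extra_decline_percent=(0.0, 0.0, 0.0),
                               re_sd_intercept=0.0, re_sd_slope=0.0,
                               residual_sd=0.0),
    )
    cohort = generate_cohort(spec)
    return cohort, fit_fvc_lme(cohort.fvc_long, cohort.subjects)


class TestLME:
    def test_noise_free_slope_exact(self, noise_free_fit):
        _, fit = noise_free_fit
        assert fit.fixed_effects["time_years"] == pytest.approx(-0.3, abs=1e-6)

    def test_noise_free_decline_matches_analytic(self, noise_free_fit):
        cohort, fit = noise_free_fit
        dt = decline_table(fit).merge(cohort.subjects, on="subject_id")
        assert np.abs(dt["decline_percent"]
                      - dt["true_decline_percent"]).max() < 1e-3

    def test_flat_trajectory_zero_decline(self):
        rng = np.random.default_rng(3)
        n = 10
        subjects = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)],
             "male": rng.integers(0, 2, n), "age": rng.normal(68, 8, n),
             "ever_smoker": rng.integers(0, 2, n),
             "antifibrotic": rng.integers(0, 2, n),
             "baseline_fvc_ppred": rng.normal(75, 15, n)}
        )
        levels = rng.uniform(2.0, 4.0, n)
        rows = [(f"s{i}", t, levels[i]) for i in range(n)
                for t in (0.0, 0.5, 1.0, 1.5)]
        fit = fit_fvc_lme(long_frame(rows), subjects)
        for i in range(n):
            assert predict_decline(fit, f"s{i}").decline_percent == pytest.approx(
                0.0, abs=0.01)

    def test_rank_deficient_design_raises(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a", "b"], "male": [1, 1], "age": [65.0, 65.0],
             "ever_smoker": [1, 1], "antifibrotic": [1, 1],
             "baseline_fvc_ppred": [80.0, 80.0]}
        )
        rows = [(s, t, 3.0 - 0.2 * t) for s in ("a", "b")
                for t in (0.0, 0.5, 1.0)]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_fvc_lme(long_frame(rows), subjects)

    def test_single_measurement_subject_rejected(self):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "male": [1], "age": [65.0],
             "ever_smoker": [0], "antifibrotic": [0],
             "baseline_fvc_ppred": [80.0]}
        )
        with pytest.raises(ValueError, match=">= 2"):
            fit_fvc_lme(long_frame([("a", 0.0, 3.0)]), subjects)

    def test_unknown_subject_prediction_raises(self, noise_free_fit):
        _, fit = noise_free_fit
        with pytest.raises(KeyError):
            predict_decline(fit, "nobody")

    def test_decline_recovery_low_noise(self):
        """Subject-level 1-year declines recovered within 1 pp at low
        residual noise."""
        spec = CohortSpec(
            n_subjects=300, seed=23,
            fvc_model=FVCModelSpec(residual_sd=0.05),
        )
        cohort = generate_cohort(spec)
        fit = fit_fvc_lme(cohort.fvc_long, cohort.subjects)
        dt = decline_table(fit).merge(cohort.subjects, on="subject_id")
        # estimator error: predicted subject trajectory at 1 year vs the
        # latent trajectory, as a percentage of baseline FVC
        latent_1y = dt["true_intercept_l"] + dt["true_slope_l_per_year"]
        mae = (100.0 * np.abs(dt["predicted_fvc_1y"] - latent_1y)
               / dt["true_intercept_l"]).mean()
        assert mae < 1.0

    def test_decline_scale_invariance(self):
        """Rescaling every FVC by c > 0 rescales the model but leaves the
        percentage decline unchanged."""
        spec = CohortSpec(n_subjects=60, seed=31)
        cohort = generate_cohort(spec)
        fit1 = fit_fvc_lme(cohort.fvc_long, cohort.subjects)
        scaled = cohort.fvc_long.assign(fvc_l=cohort.fvc_long["fvc_l"] * 2.0)
        subj = cohort.subjects.assign(
            baseline_fvc_ppred=cohort.subjects["baseline_fvc_ppred"])
        fit2 = fit_fvc_lme(scaled, subj)
        d1 = decline_table(fit1)["decline_percent"].to_numpy()
        d2 = decline_table(fit2)["decline_percent"].to_numpy()
        assert np.allclose(d1, d2, atol=1e-4)


def test_observed_baseline_tie_breaks_earlier():
    df = long_frame([("a", -0.1, 3.1), ("a", 0.1, 2.9), ("a", 1.0, 2.5)])
    assert observed_baseline_fvc(df, "a") == 3.1


class TestDeclineRegression:
    def test_derivation_mode_recovers_group_effect_exactly_when_noise_free(self):
        spec = CohortSpec(
            n_subjects=300, seed=2,
            fvc_model=FVCModelSpec(slope_base=0.0, slope_antifibrotic=0.0,
                                   slope_ever_smoker=0.0,
                                   extra_decline_percent=(0.0, 5.2, 18.3),
                                   re_sd_intercept=0.0, re_sd_slope=0.0,
                                   residual_sd=0.0),
        )
        cohort = generate_cohort(spec)
        fit = fit_fvc_lme(cohort.fvc_long, cohort.subjects)
        declines = decline_table(fit)
        subj = cohort.subjects.assign(
            moderate=(cohort.subjects["ppfe_category"] == "moderate").astype(int),
            marked=(cohort.subjects["ppfe_category"] == "marked").astype(int),
        )
        rep = regress_decline(declines, subj, ["moderate", "marked"],
                              adjust=False)
        beta = dict(zip(rep.table["term"], rep.table["beta"]))
        assert beta["moderate"] == pytest.approx(5.2, abs=1e-3)
        assert beta["marked"] == pytest.approx(18.3, abs=1e-3)

    def test_validation_mode_needs_multiple_centres(self):
        declines = pd.DataFrame(
            {"subject_id": ["a", "b"], "decline_percent": [1.0, 2.0]}
        )
        subj = pd.DataFrame(
            {"subject_id": ["a", "b"], "centre": ["A", "A"],
             "flag": [0, 1], "age": [60.0, 65.0], "male": [1, 0],
             "ever_smoker": [0, 1], "antifibrotic": [0, 1],
             "dlco_ppred": [50.0, 55.0]}
        )
        with pytest.raises(ValueError, match="centres"):
            regress_decline(declines, subj, ["flag"], mode="validation")

    def test_null_covariate_type_i_calibration(self):
        """A PPFE flag independent of decline: 95% CI covers zero at roughly
        the nominal rate."""
        rng = np.random.default_rng(7)
        n, reps, covered = 150, 200, 0
        for _ in range(reps):
            subj = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n)],
                    "flag": rng.integers(0, 2, n),
                    "age": rng.normal(68, 8, n),
                    "male": rng.integers(0, 2, n),
                    "ever_smoker": rng.integers(0, 2, n),
                    "antifibrotic": rng.integers(0, 2, n),
                    "dlco_ppred": rng.normal(50, 15, n),
                }
            )
            declines = pd.DataFrame(
                {"subject_id": subj["subject_id"],
                 "decline_percent": rng.normal(5, 8, n)}
            )
            rep = regress_decline(declines, subj, ["flag"])
            row = rep.table[rep.table["term"] == "flag"].iloc[0]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert covered / reps >= 0.93
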