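"""Cox fits (lifelines path and the frailty EM), C-index bootstrap,
Kaplan-Meier medians and the fixed-horizon confusion rule."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter

from ppfequant.survival import (ConfusionMetrics, _cox_newton,
                                cindex_bootstrap, confusion_at_horizon,
                                fit_cox, km_analysis)
from ppfequant.synthetic.cohort import (CohortSpec, SurvivalModelSpec,
                                        generate_cohort)


def sim_survival(n=400, seed=0, log_hr=np.log(2.0), rate=0.2, censor=6.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0, n) / (rate * np.exp(log_hr * x))
    c = rng.uniform(0.5, censor, n)
    return pd.DataFrame(
        {"time_years": np.minimum(t, c), "event": (t <= c).astype(int), "x": x}
    )


class TestCoxCore:
    def test_matches_lifelines_without_ties(self):
        df = sim_survival(n=500, seed=1)
        beta, cov, _ = _cox_newton(df[["x"]].to_numpy(float),
                                   df["time_years"].to_numpy(),
                                   df["event"].to_numpy(int),
                                   np.zeros(len(df)))
        cph = CoxPHFitter().fit(df, "time_years", "event")
        assert beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert np.sqrt(cov[0, 0]) == pytest.approx(
            cph.summary["se(coef)"].iloc[0], abs=1e-6)

    def test_matches_lifelines_with_efron_ties(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(2.0, n) * np.exp(-0.5 * x[:, 0]) * 4) / 4
        e = rng.random(n) < 0.8
        df = pd.DataFrame({"time_years": t, "event": e.astype(int),
                           "x0": x[:, 0], "x1": x[:, 1]})
        beta, _, _ = _cox_newton(x, t, e.astype(int), np.zeros(n))
        cph = CoxPHFitter().fit(df, "time_years", "event")
        assert np.allclose(beta, cph.params_.to_numpy(), atol=1e-6)


class TestFitCox:
    def test_recovers_true_hr(self):
        df = sim_survival(n=2000, seed=2)
        rep = fit_cox(df, ["x"])
        row = rep.table.iloc[0]
        se = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.96)
        assert abs(np.log(row["hr"]) - np.log(2.0)) <= 3 * se

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(40):
            df = sim_survival(n=250, seed=seed, log_hr=0.0)
            row = fit_cox(df, ["x"]).table.iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 33  # ~95% nominal, 3 sigma slack at 40 reps

    def test_no_events_is_an_error(self):
        df = sim_survival(n=50, seed=3).assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, ["x"])

    def test_schoenfeld_reported(self):
        rep = fit_cox(sim_survival(n=300, seed=4), ["x"])
        assert rep.schoenfeld is not None
        assert 0.0 <= rep.schoenfeld_global_p <= 1.0


class TestFrailtyCox:
    def test_single_group_matches_plain_cox(self):
        df = sim_survival(n=400, seed=7).assign(centre="A")
        plain = fit_cox(df, ["x"])
        frail = fit_cox(df, ["x"], frailty_group="centre")
        assert frail.table["hr"].iloc[0] == pytest.approx(
            plain.table["hr"].iloc[0], abs=1e-4)

    def test_matches_r_survival_frailty(self, tmp_path):
        """Independent oracle: R survival's gamma-frailty Cox on the same data."""
        spec = CohortSpec(
            n_subjects=400, seed=6, centre_labels=tuple("ABCDEF"),
            centre_probs=(1 / 6,) * 6,
            survival_model=SurvivalModelSpec(frailty_variance=0.2,
                                             hr_marked=2.0, hr_moderate=1.0),
        )
        c = generate_cohort(spec)
        df = c.subjects.merge(c.survival, on="subject_id")
        df["marked"] = (df["ppfe_category"] == "marked").astype(int)
        rep = fit_cox(df, ["marked", "dlco_ppred"], frailty_group="centre")
        csv = tmp_path / "frail.csv"
        df[["time_years", "event", "marked", "dlco_ppred", "centre"]].to_csv(
            csv, index=False)
        rscript = (
            f'd <- read.csv("{csv}"); suppressMessages(library(survival)); '
            'f <- coxph(Surv(time_years, event) ~ marked + dlco_ppred + '
            'frailty(centre, distribution="gamma"), data=d); '
            'cat(exp(coef(f)), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        r_hrs = [float(v) for v in out.stdout.strip().splitlines()]
        py_hrs = rep.table["hr"].to_numpy()
        assert np.allclose(py_hrs, r_hrs, rtol=0.01)


class TestCindexBootstrap:
    def test_constant_score_gives_half(self):
        df = sim_survival(n=200, seed=8).assign(x=1.0)
        out = cindex_bootstrap(df, ["x"], iterations=20, seed=0)
        assert out["c_index"] == 0.5

    def test_perfect_ranking_no_censoring(self):
        n = 100
        t = np.linspace(1, 10, n)
        df = pd.DataFrame({"time_years": t, "event": 1, "x": -t})
        out = cindex_bootstrap(df, ["x"], iterations=20, seed=0)
        assert out["c_index"] == 1.0

    def test_ci_contains_full_sample_value(self):
        df = sim_survival(n=300, seed=9)
        out = cindex_bootstrap(df, ["x"], iterations=100, seed=3)
        assert out["ci_low"] <= out["c_index"] <= out["ci_high"]

    def test_reproducible_under_seed(self):
        df = sim_survival(n=200, seed=10)
        a = cindex_bootstrap(df, ["x"], iterations=50, seed=11)
        b = cindex_bootstrap(df, ["x"], iterations=50, seed=11)
        assert a == b


class TestKM:
    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(1.0, 5000) / (np.log(2) / 2.0)
        df = pd.DataFrame({"time_years": t, "event": 1, "g": "all"})
        km = km_analysis(df, "g")
        assert km.groups[0].median == pytest.approx(2.0, rel=0.05)
        assert km.groups[0].median_ci_low < 2.0 < km.groups[0].median_ci_high

    def test_all_censored_median_not_reached(self):
        df = pd.DataFrame(
            {"time_years": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
             "event": [0, 0, 0, 1, 0, 0],
             "g": ["a"] * 3 + ["b"] * 3}
        )
        km = km_analysis(df, "g")
        by = {g.group: g for g in km.groups}
        assert by["a"].median is None

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(2.0, 300)
        df = pd.DataFrame({"time_years": t, "event": 1, "g": "all"})
        km = km_analysis(df, "g")
        curve = km.curves
        ts = np.sort(t)
        for _, row in curve.iloc[1::37].iterrows():
            emp = (ts > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-9)

    def test_identical_groups_logrank_near_null(self):
        """p-values approximately uniform when the groups share one law."""
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(60):
            t = rng.exponential(2.0, 120)
            c = rng.uniform(0.5, 6.0, 120)
            df = pd.DataFrame(
                {"time_years": np.minimum(t, c), "event": (t <= c).astype(int),
                 "g": rng.integers(0, 2, 120)}
            )
            ps.append(km_analysis(df, "g").logrank_p)
        assert 0.25 < np.mean(ps) < 0.75  # crude uniformity check


class TestConfusion:
    def test_reconstructed_published_style_counts(self):
        cm = ConfusionMetrics(tp=43, fp=40, fn=30, tn=155)
        assert round(cm.sensitivity, 1) == 58.9
        assert round(cm.specificity, 1) == 79.5
        assert round(cm.ppv, 1) == 51.8
        assert round(cm.npv, 1) == 83.8
        cm2 = ConfusionMetrics(tp=17, fp=12, fn=56, tn=183)
        assert round(cm2.ppv, 1) == 58.6
        assert round(cm2.npv, 1) == 76.6

    def test_perfect_classifier(self):
        df = pd.DataFrame(
            {"time_years": [0.5, 1.0, 3.0, 4.0], "event": [1, 1, 0, 0],
             "flag": [True, True, False, False]}
        )
        cm = confusion_at_horizon(df, "flag")
        assert (cm.sensitivity, cm.specificity, cm.ppv, cm.npv) == (
            100.0, 100.0, 100.0, 100.0)

    def test_censored_before_horizon_excluded(self):
        df = pd.DataFrame(
            {"time_years": [1.5, 0.5, 3.0], "event": [0, 1, 0],
             "flag": [True, True, False]}
        )
        cm = confusion_at_horizon(df, "flag")
        assert cm.tp + cm.fp + cm.fn + cm.tn == 2

    @given(
        st.lists(
            st.tuples(st.floats(0.05, 5.0), st.booleans(), st.booleans()),
            min_size=1, max_size=60,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_counts_match_per_record_oracle(self, rows):
        df = pd.DataFrame(rows, columns=["time_years", "event", "flag"])
        df["event"] = df["event"].astype(int)
        cm = confusion_at_horizon(df, "flag", horizon=2.0)
        tp = fp = fn = tn = 0
        for _, r in df.iterrows():
            died = r["event"] == 1 and r["time_years"] < 2.0
            alive = r["time_years"] >= 2.0
            if died:
                tp, fn = tp + r["flag"], fn + (not r["flag"])
            elif alive:
                fp, tn = fp + r["flag"], tn + (not r["flag"])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        if cm.defined:
            assert cm.sensitivity == 100.0 * tp / (tp + fn)
            if tn + fn > 0:
                assert cm.npv == 100.0 * tn / (tn + fn)
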