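"""Survival and fixed-horizon classification analyses.

Standard Cox proportional-hazards fits, Schoenfeld proportionality checks
and Kaplan-Meier machinery go through lifelines. A shared gamma-frailty Cox
model (random multiplicative hazard per centre) is fitted here directly —
via an EM algorithm over a Newton-Raphson Efron-ties partial-likelihood
core with offset support — because no installed package exposes frailty
terms. The fixed-horizon confusion metrics implement the
censoring-exclusion rule: deaths before the horizon are events, subjects
followed alive beyond it are non-events, and subjects censored before the
horizon enter no cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index
from scipy.special import gammaln
from scipy.stats import norm


# ---------------------------------------------------------------------------
# Efron-ties Cox partial likelihood with offset (numpy core)

def _cox_efron_loglik(beta, X, time, event, offset):
    """Efron partial log-likelihood, gradient and Hessian.

    Arrays must be sorted by ascending time.
    """
    n, p = X.shape
    eta = X @ beta + offset
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # cumulative risk-set sums from the back
    order_rev = slice(None, None, -1)
    cw = np.cumsum(w[order_rev])[order_rev]
    cwx = np.cumsum((w[:, None] * X)[order_rev], axis=0)[order_rev]
    cwxx = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[order_rev],
                     axis=0)[order_rev]
    ev = np.flatnonzero(event == 1)
    if ev.size and np.unique(time[ev]).size == ev.size:
        # no tied event times: Efron coincides with Breslow; fully vectorised
        cw_d = cw[ev]
        xbar = cwx[ev] / cw_d[:, None]
        ll = float(eta[ev].sum() - np.log(cw_d).sum())
        grad = (X[ev] - xbar).sum(axis=0)
        hess = -(
            (cwxx[ev] / cw_d[:, None, None]).sum(axis=0)
            - np.einsum("ij,ik->jk", xbar, xbar)
        )
        return ll, grad, hess
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d_idx = np.arange(i, j + 1)[event[i: j + 1] == 1]
        d = d_idx.size
        if d > 0:
            wd = w[d_idx]
            xd = X[d_idx]
            s0 = cw[i]
            s1 = cwx[i]
            s2 = cwxx[i]
            td0 = wd.sum()
            td1 = xd.T @ wd
            td2 = (wd[:, None, None] * (xd[:, :, None] * xd[:, None, :])).sum(axis=0)
            ll += eta[d_idx].sum()
            for r in range(d):
                f = r / d
                a0 = s0 - f * td0
                a1 = s1 - f * td1
                a2 = s2 - f * td2
                ll -= np.log(a0)
                grad_term = a1 / a0
                grad -= grad_term
                hess -= a2 / a0 - np.outer(grad_term, grad_term)
            grad += xd.sum(axis=0)
        i = j + 1
    return ll, grad, hess


def _cox_newton(X, time, event, offset, tol=1e-9, max_iter=50):
    # centre columns and the offset: the partial likelihood depends on the
    # linear predictor only through within-risk-set differences, so beta and
    # its covariance are unchanged while exp() stays in range
    Xc = X - X.mean(axis=0)
    oc = offset - offset.mean()
    order = np.argsort(time, kind="stable")
    Xs, ts, es, os_ = Xc[order], time[order], event[order], oc[order]
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    ll_new = -np.inf
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            ll, grad, hess = _cox_efron_loglik(beta, Xs, ts, es, os_)
        if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(hess))):
            break  # monotone-likelihood boundary: keep the last finite iterate
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Cox fit") from exc
        # step-halving safeguard
        accepted = False
        for _ in range(30):
            cand = beta + step
            with np.errstate(all="ignore"):
                ll_new, _, _ = _cox_efron_loglik(cand, Xs, ts, es, os_)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        beta = beta + step
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll_new
    with np.errstate(all="ignore"):
        ll, grad, hess = _cox_efron_loglik(beta, Xs, ts, es, os_)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return beta, cov, ll


def _breslow_subject_cumhaz(X, time, event, offset, beta):
    """Per-subject Breslow cumulative hazard Lambda_i = H0(t_i) exp(eta_i),
    evaluated at each subject's exit time (original order).

    Computed on a centred linear predictor; the product H0 * exp(eta) is
    invariant to the centring.
    """
    eta = X @ beta + offset
    eta = eta - eta.mean()
    order = np.argsort(time, kind="stable")
    w = np.exp(eta[order])
    ts, es = time[order], event[order]
    n = ts.size
    cw = np.cumsum(w[::-1])[::-1]
    uniq_t, dN, denom = [], [], []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        d = int(es[i: j + 1].sum())
        if d > 0:
            uniq_t.append(ts[i])
            dN.append(d)
            denom.append(cw[i])
        i = j + 1
    uniq_t = np.asarray(uniq_t)
    increments = np.asarray(dN) / np.asarray(denom)
    cum = np.cumsum(increments)
    idx = np.searchsorted(uniq_t, time, side="right") - 1
    H0 = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    return H0 * np.exp(eta)


# ---------------------------------------------------------------------------
# public fits

@dataclass
class CoxReport:
    table: pd.DataFrame  # term, hr, ci_low, ci_high, p
    c_index: float
    schoenfeld: pd.DataFrame | None
    schoenfeld_global_p: float | None
    frailty_variance: float | None = None
    warnings_: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def fit_cox(records: pd.DataFrame, covariates: list[str],
            frailty_group: str | None = None,
            time_col: str = "time_years", event_col: str = "event") -> CoxReport:
    """Cox proportional-hazards fit with HRs, 95% CIs, p-values, C-index and
    Schoenfeld proportionality tests; gamma frailty on ``frailty_group``
    when supplied."""
    df = records.dropna(subset=covariates + [time_col, event_col]).copy()
    if df[event_col].sum() < 1:
        raise ValueError("no events in the data")
    if frailty_group is not None:
        return _fit_frailty_cox(df, covariates, frailty_group, time_col, event_col)
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df[covariates + [time_col, event_col]], duration_col=time_col,
                event_col=event_col)
    warn_msgs = [str(w.message) for w in caught
                 if "convergence" in str(w.message).lower()
                 or "complete separation" in str(w.message).lower()]
    summ = cph.summary
    table = pd.DataFrame(
        {
            "term": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    sch = proportional_hazard_test(cph, df[covariates + [time_col, event_col]],
                                   time_transform="rank")
    sch_table = sch.summary.reset_index().rename(columns={"index": "term"})
    global_p = _global_schoenfeld_p(cph, df, covariates, time_col, event_col)
    return CoxReport(table=table, c_index=float(cph.concordance_index_),
                     schoenfeld=sch_table, schoenfeld_global_p=global_p,
                     warnings_=warn_msgs, extra={"model": cph})


def _global_schoenfeld_p(cph, df, covariates, time_col, event_col) -> float:
    """Global proportionality score test across all covariates jointly."""
    res = proportional_hazard_test(cph, df[covariates + [time_col, event_col]],
                                   time_transform="rank")
    # combine per-covariate chi2 as a sum (independent approximation)
    from scipy.stats import chi2

    stat = float(res.summary["test_statistic"].sum())
    dof = len(res.summary)
    return float(chi2.sf(stat, dof))


def _frailty_group_terms(theta, D_g, H_g):
    """Per-group integrated-frailty terms of the profiled marginal likelihood.

    For gamma frailty with variance theta,
    log E[w^D exp(-w H)] = lnG(1/t + D) - lnG(1/t) + (1/t) ln(1/t)
                           - (1/t + D) ln(1/t + H);
    the theta -> 0 limit is -H (frailty degenerate at 1).
    """
    D_g = np.asarray(D_g, dtype=float)
    H_g = np.asarray(H_g, dtype=float)
    if theta <= 0:
        return float(-H_g.sum())
    inv = 1.0 / theta
    return float(
        np.sum(
            gammaln(inv + D_g) - gammaln(inv)
            + inv * np.log(inv)
            - (inv + D_g) * np.log(inv + H_g)
        )
    )


def _fit_frailty_cox(df, covariates, group_col, time_col, event_col) -> CoxReport:
    """Shared gamma frailty per group via EM; frailty variance chosen by
    profile marginal likelihood on a log-spaced grid (0 included)."""
    X = df[covariates].to_numpy(dtype=float)
    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    groups = df[group_col].to_numpy()
    glabels = np.unique(groups)
    gidx = {g: np.flatnonzero(groups == g) for g in glabels}

    def group_totals(logw, beta):
        lam = _breslow_subject_cumhaz(X, time, event, logw, beta)
        D_g, H_g = [], []
        for g in glabels:
            idx = gidx[g]
            D_g.append(int(event[idx].sum()))
            # group hazard total with frailty divided back out
            H_g.append(float((lam[idx] / np.exp(logw[idx])).sum()))
        return D_g, H_g

    def em_fit(theta, beta_init=None):
        logw = np.zeros(len(df))
        beta = np.zeros(X.shape[1]) if beta_init is None else beta_init.copy()
        cov = None
        for _ in range(40):
            beta, cov, ll = _cox_newton(X, time, event, logw)
            if theta == 0:
                break
            D_g, H_g = group_totals(logw, beta)
            new_logw = np.zeros(len(df))
            for g, d, h in zip(glabels, D_g, H_g):
                new_logw[gidx[g]] = np.log((1.0 / theta + d) / (1.0 / theta + h))
            delta = float(np.max(np.abs(new_logw - logw)))
            logw = new_logw
            if delta < 1e-8:
                break
        beta, cov, pll = _cox_newton(X, time, event, logw)
        D_g, H_g = group_totals(logw, beta)
        # profiled marginal likelihood: the event terms of the full
        # likelihood equal the offset partial likelihood minus the events'
        # frailty offsets; the integrated-frailty group terms are added
        d_logw = sum(
            int(event[gidx[g]].sum()) * float(logw[gidx[g][0]]) for g in glabels
        )
        marg = pll - d_logw + _frailty_group_terms(theta, D_g, H_g)
        return beta, cov, logw, marg

    thetas = np.concatenate([[0.0], np.geomspace(0.02, 2.0, 8)])
    fits = []
    beta_prev = None
    for t in thetas:
        f = em_fit(t, beta_prev)
        beta_prev = f[0]
        fits.append(f)
    best = int(np.argmax([f[3] for f in fits]))
    theta_hat = float(thetas[best])
    beta, cov, logw, _ = fits[best]

    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": covariates,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": p,
        }
    )
    risk_score = X @ beta + logw
    cidx = concordance_index(time, -risk_score, event)
    return CoxReport(table=table, c_index=float(cidx), schoenfeld=None,
                     schoenfeld_global_p=None, frailty_variance=theta_hat,
                     extra={"beta": beta, "cov": cov,
                            "log_frailty": dict(zip(glabels,
                                                    [float(logw[gidx[g][0]])
                                                     for g in glabels]))})


# ---------------------------------------------------------------------------
# C-index bootstrap

def cindex_bootstrap(records: pd.DataFrame, covariates: list[str],
                     iterations: int = 500, seed: int = 0,
                     time_col: str = "time_years",
                     event_col: str = "event") -> dict:
    """Bootstrap mean and percentile 95% CI of the model C-index.

    Subjects are resampled with replacement, the Cox model refitted, and the
    refit model's concordance evaluated on the resample. Deterministic for a
    fixed seed.
    """
    df = records.dropna(subset=covariates + [time_col, event_col]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    X = df[covariates].to_numpy(dtype=float)
    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    if np.ptp(X, axis=0).max() == 0:  # constant risk score
        full_c = 0.5
    else:
        beta, _, _ = _cox_newton(X, time, event, np.zeros(len(df)))
        full_c = concordance_index(time, -(X @ beta), event)
    vals = []
    for _ in range(iterations):
        idx = rng.integers(0, len(df), len(df))
        Xb, tb, eb = X[idx], time[idx], event[idx]
        if eb.sum() == 0 or np.ptp(Xb, axis=0).max() == 0:
            vals.append(0.5)
            continue
        try:
            beta_b, _, _ = _cox_newton(Xb, tb, eb, np.zeros(len(idx)))
            vals.append(concordance_index(tb, -(Xb @ beta_b), eb))
        except RuntimeError:
            continue
    vals = np.asarray(vals)
    return {
        "c_index": float(full_c),
        "mean": float(vals.mean()),
        "ci_low": float(np.percentile(vals, 2.5)),
        "ci_high": float(np.percentile(vals, 97.5)),
        "iterations": int(vals.size),
    }


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMGroupSummary:
    group: str
    n: int
    events: int
    median: float | None  # None = not reached
    median_ci_low: float | None
    median_ci_high: float | None
    ci_method: str


@dataclass
class KMReport:
    groups: list[KMGroupSummary]
    logrank_statistic: float
    logrank_p: float
    curves: pd.DataFrame  # group, time, survival


def _median_ci_from_band(times, surv, lower, upper):
    """Median CI by inverting the pointwise confidence band: the bound is the
    earliest time at which the band crosses 0.5 (reflected-bound reading,
    with the band-inversion value as fallback)."""
    def first_crossing(curve):
        below = np.flatnonzero(curve <= 0.5)
        return float(times[below[0]]) if below.size else None

    # the pessimistic (lower) band crosses 0.5 earliest -> lower limit
    return first_crossing(lower), first_crossing(upper)


def km_analysis(records: pd.DataFrame, group_col: str,
                time_col: str = "time_years", event_col: str = "event",
                alpha: float = 0.05) -> KMReport:
    """Per-group product-limit curves, median survival with CI, and the
    k-group log-rank test."""
    df = records.dropna(subset=[group_col, time_col, event_col])
    if df[event_col].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    summaries = []
    curve_rows = []
    for g, grp in df.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(grp[time_col], grp[event_col], label=str(g))
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        ci = kmf.confidence_interval_
        lower = ci.iloc[:, 0].to_numpy()
        upper = ci.iloc[:, 1].to_numpy()
        med = kmf.median_survival_time_
        median = None if np.isinf(med) else float(med)
        lo, hi = _median_ci_from_band(times, surv, lower, upper)
        summaries.append(
            KMGroupSummary(group=str(g), n=len(grp),
                           events=int(grp[event_col].sum()),
                           median=median, median_ci_low=lo, median_ci_high=hi,
                           ci_method="band-inversion (log-log)")
        )
        for t, s in zip(times, surv):
            curve_rows.append({"group": str(g), "time": float(t), "survival": float(s)})
    lr = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return KMReport(groups=summaries,
                    logrank_statistic=float(lr.test_statistic),
                    logrank_p=float(lr.p_value),
                    curves=pd.DataFrame(curve_rows))


# ---------------------------------------------------------------------------
# fixed-horizon confusion metrics

@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    defined: bool = True

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn)

    def to_dict(self) -> dict:
        d = {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
             "defined": self.defined}
        if self.defined:
            d["sensitivity"] = self.sensitivity
            d["specificity"] = self.specificity
            d["ppv"] = self.ppv if self.tp + self.fp > 0 else None
            d["npv"] = self.npv if self.tn + self.fn > 0 else None
        return d


def confusion_at_horizon(records: pd.DataFrame, classifier_col: str,
                         horizon: float = 2.0,
                         time_col: str = "time_years",
                         event_col: str = "event") -> ConfusionMetrics:
    """2x2 metrics for death within the horizon.

    Events: died before the horizon. Non-events: followed beyond the horizon
    (subjects whose follow-up ends alive exactly at the horizon count as
    non-events). Censored before the horizon: excluded from every cell.
    """
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=int)
    flag = records[classifier_col].to_numpy(dtype=bool)
    died = (e == 1) & (t < horizon)
    alive = (t >= horizon)
    included = died | alive
    tp = int((flag & died).sum())
    fn = int((~flag & died).sum())
    fp = int((flag & alive).sum())
    tn = int((~flag & alive).sum())
    defined = (tp + fn) > 0 and (fp + tn) > 0
    del included
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, defined=defined)
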