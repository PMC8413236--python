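"""ROC analysis with DeLong variance machinery.

The AUC is computed as the Mann-Whitney statistic with mid-ranks for ties
(identical to the trapezoidal area under the empirical ROC curve), and its
confidence interval and paired two-sided comparisons use the DeLong
structural-components estimator for correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


def _midrank_components(scores: np.ndarray, outcome: np.ndarray):
    """DeLong structural components V10 (cases) and V01 (controls)."""
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_cases: int
    n_controls: int


def roc_auc(scores, outcome, alpha: float = 0.05) -> AUCResult:
    """AUC with a two-sided DeLong confidence interval.

    ``outcome`` must contain both classes; ties in scores are handled by
    mid-ranks so the AUC equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must align")
    m = int((outcome == 1).sum())
    n = int((outcome == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    auc, v10, v01 = _midrank_components(scores, outcome)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha / 2)
    return AUCResult(
        auc=float(auc),
        ci_low=float(np.clip(auc - z * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + z * se, 0.0, 1.0)),
        se=se,
        n_cases=m,
        n_controls=n,
    )


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    difference: float
    se_difference: float
    z: float
    p: float


def compare_auc_delong(scores_a, scores_b, outcome) -> AUCComparison:
    """Paired two-sided DeLong test of AUC(a) - AUC(b) on identical subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if not (scores_a.shape == scores_b.shape == outcome.shape):
        raise ValueError("paired comparison needs aligned scores on identical subjects")
    m = int((outcome == 1).sum())
    n = int((outcome == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    auc_a, v10a, v01a = _midrank_components(scores_a, outcome)
    auc_b, v10b, v01b = _midrank_components(scores_b, outcome)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    diff = float(auc_a - auc_b)
    se = float(np.sqrt(var))
    if se == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = diff / se
        p = float(2 * norm.sf(abs(z)))
    return AUCComparison(auc_a=float(auc_a), auc_b=float(auc_b),
                         difference=diff, se_difference=se, z=float(z), p=p)
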