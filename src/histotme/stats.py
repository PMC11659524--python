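"""Evaluation statistics: ROC with DeLong inference, exact binomial CIs,
confusion metrics, and survival comparisons.

AUROC is the Mann–Whitney concordance probability (ties count one half);
its variance, confidence interval and the paired two-sided comparison of
two markers on the same patients use the DeLong placement-value estimator.
Sensitivity/specificity/PPV carry exact Clopper–Pearson binomial intervals.
Survival comparisons use the log-rank test and a univariate Cox
proportional-hazards fit (Efron tie handling, via lifelines). All tests are
two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class SurvivalComparison:
    groups: tuple
    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values. Returns (auc, V10 per positive, V01 per negative)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    # psi(x, y) = 1 if x>y, 0.5 if tie, 0 otherwise
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def auroc(scores, labels) -> ROCResult:
    """AUROC with DeLong 95% CI and the ROC curve itself."""
    scores, labels = _check_binary(scores, labels)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    a = float(np.trapezoid(tpr, fpr))
    lo, hi = delong_ci(scores, labels)
    return ROCResult(
        auroc=a, ci_low=lo, ci_high=hi,
        n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()),
        fpr=fpr, tpr=tpr, thresholds=thr,
    )


def delong_variance(scores, labels) -> float:
    scores, labels = _check_binary(scores, labels)
    _, v10, v01 = _placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI for AUROC from the DeLong variance, clipped to [0,1]."""
    scores, labels = _check_binary(scores, labels)
    a, v10, v01 = _placements(scores, labels)
    var = delong_variance(scores, labels)
    if var <= 0:
        logger.warning("zero DeLong variance (perfect separation): degenerate CI")
        return (a, a)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (max(0.0, a - half), min(1.0, a + half))


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test for a difference in AUROC.

    Both score vectors must refer to the same patients/labels. Returns
    ``(auc_a - auc_b, p)``.
    """
    scores_a, labels = _check_binary(scores_a, labels)
    scores_b, _ = _check_binary(scores_b, labels)
    a1, v10a, v01a = _placements(scores_a, labels)
    a2, v10b, v01b = _placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    diff = a1 - a2
    if np.array_equal(scores_a, scores_b):
        return 0.0, 1.0
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        logger.warning("non-positive paired DeLong variance; p reported as 1")
        return diff, 1.0
    z = diff / np.sqrt(var)
    return float(diff), float(2.0 * sps.norm.sf(abs(z)))


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper–Pearson) confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def confusion_metrics(pred_labels, true_labels, level: float = 0.95) -> pd.DataFrame:
    """Sensitivity, specificity and PPV, each with an exact binomial CI."""
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    if len(np.unique(true)) < 2:
        raise ValueError("both classes must be present in the truth")
    tp = int(((pred == 1) & (true == 1)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    rows = {}
    rows["sensitivity"] = (tp, tp + fn)
    rows["specificity"] = (tn, tn + fp)
    rows["ppv"] = (tp, tp + fp)
    out = []
    for name, (s, d) in rows.items():
        if d == 0:
            logger.warning("%s undefined (empty denominator); reported as NaN", name)
            out.append({"metric": name, "value": np.nan, "ci_low": np.nan, "ci_high": np.nan})
        else:
            lo, hi = clopper_pearson_ci(s, d, level)
            out.append({"metric": name, "value": s / d, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(out).set_index("metric")


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError("logrank_test expects exactly two groups")
    if events.sum() == 0:
        raise ValueError("no events in either group")
    from lifelines.statistics import logrank_test as _lr

    g0 = groups == uniq[0]
    res = _lr(times[g0], times[~g0], event_observed_A=events[g0], event_observed_B=events[~g0])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate_hr(times, events, group, level: float = 0.95) -> SurvivalComparison:
    """Univariate Cox PH fit on a binary group indicator (Efron ties).

    The hazard ratio is for ``group == 1`` (e.g. predicted responder /
    Immune-Inflamed) versus ``group == 0``; HR < 1 means the indexed group
    has lower hazard (better survival).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group).astype(int)
    uniq = np.unique(group)
    if len(uniq) != 2:
        raise ValueError("cox_univariate_hr expects a binary group")
    for g in uniq:
        if events[group == g].sum() < 1:
            raise ValueError(f"group {g} has no events")
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": times, "e": events, "g": group})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="t", event_col="e")
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    z = sps.norm.ppf(0.5 + level / 2.0)
    stat, p_lr = logrank_test(times, events, group)
    return SurvivalComparison(
        groups=tuple(uniq),
        logrank_stat=stat,
        logrank_p=p_lr,
        hazard_ratio=float(np.exp(coef)),
        hr_ci_low=float(np.exp(coef - z * se)),
        hr_ci_high=float(np.exp(coef + z * se)),
        cox_p=float(cph.summary.loc["g", "p"]),
    )


def km_table(times, events) -> pd.DataFrame:
    """Kaplan–Meier step function as a table (time, at-risk, survival)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events).astype(int))
    tab = km.event_table.copy()
    surv = km.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "time": surv.index.to_numpy(),
        "survival": surv.to_numpy(),
    })
    out["at_risk"] = tab["at_risk"].reindex(surv.index).to_numpy()
    return out
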