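"""Cohort-level response statistics.

Percent changes of tumor metrics relative to the baseline visit (V21%,
V31%), Wilcoxon rank-sum comparison of responder groups, paired t-tests
between analysis approaches, and ROC analysis of pathologic complete
response (pCR) prediction via univariate logistic regression, with DeLong
95% confidence intervals on the AUC.

Because the logistic transform of a single score is monotone, the ROC of
the fitted probabilities coincides with the concordant-pair (rank) AUC of
the raw score up to score direction; both routes are computed and exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "ROCResult",
    "percent_change",
    "wilcoxon_rank_sum",
    "paired_t_test",
    "roc_auc",
    "add_percent_changes",
    "predict_response",
]


def percent_change(v_visit, v_baseline):
    """100 * (v_visit - v_baseline) / v_baseline.

    Vectorized; a zero baseline makes the change undefined and yields NaN
    (callers flag such rows rather than dropping them silently).
    """
    v_visit = np.asarray(v_visit, dtype=float)
    v_baseline = np.asarray(v_baseline, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (v_visit - v_baseline) / v_baseline
    out = np.where(v_baseline == 0, np.nan, out)
    return float(out) if out.ndim == 0 else out


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of the rank distribution when n_a + n_b <= 12 and the
    data are tie-free; otherwise the normal approximation with tie
    correction. Identical constant groups return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def paired_t_test(values_a, values_b) -> float:
    """Two-sided paired Student's t-test p-value on per-subject differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(a, b)
    return float(res.pvalue)


def _delong_auc_variance(labels, scores):
    """DeLong (1988) variance of the rank AUC, via midrank components."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels], scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    # V10[i]: placement of positive i among negatives; V01[j] symmetric.
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong 95% CI; rank and logistic routes agree by construction.

    ``flipped`` records whether scores were negated so that the reported AUC
    is the discriminative orientation (>= 0.5).
    """

    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    auc_rank: float
    auc_logistic: float
    flipped: bool = False


def _logistic_probs(labels, scores):
    """Fitted probabilities from a univariate logistic model.

    statsmodels Logit; on separation/convergence failure fall back to a
    weakly-penalized sklearn fit (the monotone transform leaves the ROC of
    the score unchanged either way).
    """
    import warnings

    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(scores, dtype=float))
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(np.asarray(labels, dtype=float), x).fit(
                disp=0, maxiter=200, warn_convergence=False)
            probs = np.asarray(fit.predict(x))
        if not np.all(np.isfinite(probs)):
            raise ValueError
        return probs
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=1000)
        clf.fit(np.asarray(scores, dtype=float).reshape(-1, 1),
                np.asarray(labels, dtype=int))
        return clf.predict_proba(np.asarray(scores, dtype=float).reshape(-1, 1))[:, 1]


def roc_auc(labels, scores) -> ROCResult:
    """ROC AUC of a single predictor, via univariate logistic regression.

    The AUC of the fitted logistic probabilities is computed alongside the
    concordant-pair (rank, tie = half credit) AUC of the raw score; the two
    agree because the logistic transform is monotone in the score. The
    reported value uses the orientation giving AUC >= 0.5; the CI is DeLong.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be matching 1-D arrays")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need both classes present")
    labels = (labels == classes.max()).astype(int)

    auc_rank = float(roc_auc_score(labels, scores))
    flipped = auc_rank < 0.5
    oriented = -scores if flipped else scores
    probs = _logistic_probs(labels, oriented)
    auc_logit = float(roc_auc_score(labels, probs))
    auc, var = _delong_auc_variance(labels.astype(bool), oriented)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))
    return ROCResult(auc=float(auc), ci95=ci,
                     n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()),
                     auc_rank=float(max(auc_rank, 1 - auc_rank)),
                     auc_logistic=auc_logit, flipped=bool(flipped))


def add_percent_changes(cohort: pd.DataFrame, baseline_visit: str = "V1"
                        ) -> pd.DataFrame:
    """Derive per-patient percent changes of every metric vs the baseline visit.

    ``cohort`` is long-form with columns (patient, group, visit, metric,
    value). Returns one row per (patient, metric) with columns V21, V31, ...
    (percent change of each later visit relative to baseline); changes with
    zero or missing baseline are NaN.
    """
    required = {"patient", "group", "visit", "metric", "value"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    wide = cohort.pivot_table(index=["patient", "group", "metric"],
                              columns="visit", values="value", aggfunc="first")
    if baseline_visit not in wide.columns:
        raise ValueError(f"no {baseline_visit} rows in cohort table")
    out = wide[[baseline_visit]].copy()
    out.columns = [baseline_visit]
    for visit in sorted(c for c in wide.columns if c != baseline_visit):
        col = f"V{visit[1:]}{baseline_visit[1:]}%"  # e.g. V2,V1 -> V21%
        out[col] = percent_change(wide[visit].to_numpy(),
                                  wide[baseline_visit].to_numpy())
    return out.reset_index()


def predict_response(cohort: pd.DataFrame, metric: str, change_column: str,
                     positive_group: str = "pCR") -> dict:
    """One response-prediction table row for a metric's percent change.

    Computes per-group median and IQR bounds of ``change_column``
    (e.g. "V31%"), the two-sided Wilcoxon rank-sum p-value between groups,
    and the logistic-ROC AUC with DeLong 95% CI. Patients missing the
    needed visit (NaN change) are dropped and counted.
    """
    changes = add_percent_changes(cohort)
    rows = changes[changes["metric"] == metric]
    if rows.empty:
        raise ValueError(f"metric {metric!r} not present in cohort table")
    if change_column not in rows.columns:
        raise ValueError(f"{change_column!r} not derivable from the visits present")
    vals = rows[change_column].to_numpy(dtype=float)
    groups = rows["group"].to_numpy()
    keep = np.isfinite(vals)
    n_dropped = int((~keep).sum())
    vals, groups = vals[keep], groups[keep]
    pos = vals[groups == positive_group]
    neg = vals[groups != positive_group]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need patients from both response groups")

    def med_iqr(v):
        return (float(np.median(v)), (float(np.quantile(v, 0.25)),
                                      float(np.quantile(v, 0.75))))

    roc = roc_auc((groups == positive_group).astype(int), vals)
    return {
        "metric": metric,
        "change": change_column,
        "n_pos": int(pos.size),
        "n_neg": int(neg.size),
        "n_dropped": n_dropped,
        "median_pos": med_iqr(pos)[0],
        "iqr_pos": med_iqr(pos)[1],
        "median_neg": med_iqr(neg)[0],
        "iqr_neg": med_iqr(neg)[1],
        "wilcoxon_p": wilcoxon_rank_sum(pos, neg),
        "roc": roc,
    }
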