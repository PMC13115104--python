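"""Evaluation suite: confusion-matrix metrics, rank AUC, DeLong AUC
comparison, fold-aggregated confidence intervals, and thin univariable
reporting helpers.

Positive class is resistant (label 1) throughout.  Metrics with a zero
denominator are returned as NaN with an ``undefined`` flag rather than
raising, so that sparse subgroup analyses never crash a report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_T_DIST = stats.t


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(labels: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("length mismatch")
    for arr in (labels, predicted):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predicted == 1))),
        fp=int(np.sum((labels == 0) & (predicted == 1))),
        tn=int(np.sum((labels == 0) & (predicted == 0))),
        fn=int(np.sum((labels == 1) & (predicted == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metric_suite(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV, G-mean from counts.

    Zero-denominator entries come back as NaN (flagged in ``undefined``).
    """
    total = cm.tp + cm.fp + cm.tn + cm.fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": (cm.tp + cm.tn) / total,
        "ppv": _safe_div(cm.tp, cm.tp + cm.fp),
        "npv": _safe_div(cm.tn, cm.tn + cm.fn),
        "gmean": float(np.sqrt(sens * spec)),
    }
    out["undefined"] = sorted(k for k, v in out.items()
                              if isinstance(v, float) and np.isnan(v))
    return out


def gmean_score(labels: np.ndarray, predicted: np.ndarray) -> float:
    """sqrt(sensitivity * specificity) of hard predictions."""
    m = metric_suite(confusion(labels, predicted))
    return m["gmean"]


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with midranks for ties.

    Equals the trapezoidal ROC area and the probability that a random
    positive outscores a random negative (ties count one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ------------------------------------------------------------------ DeLong

def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Structural components: V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i),
    V01[j] symmetric."""
    v10 = np.array([
        (np.sum(neg_scores < s) + 0.5 * np.sum(neg_scores == s)) / len(neg_scores)
        for s in pos_scores])
    v01 = np.array([
        (np.sum(pos_scores > s) + 0.5 * np.sum(pos_scores == s)) / len(pos_scores)
        for s in neg_scores])
    return v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """Paired comparison of two correlated AUCs on the same rows.

    Returns (delta_auc, variance of the difference, two-sided normal p).
    Uses the placement-value covariance estimator; identical score vectors
    give delta 0 and p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores must align with labels")
    pos = labels == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both classes required")
    m, n = int(pos.sum()), int(neg.sum())

    v10_a, v01_a = _placements(scores_a[pos], scores_a[neg])
    v10_b, v01_b = _placements(scores_b[pos], scores_b[neg])
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    delta = auc_a - auc_b

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if abs(delta) > 1e-12:
            raise ValueError("zero variance with nonzero AUC difference")
        return delta, 0.0, 1.0
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(delta), float(var), p


def fold_ci(values: np.ndarray, level: float = 0.95,
            clip_unit: bool = True) -> tuple[float, float, float]:
    """t-based confidence interval of fold-level metric values.

    mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n), truncated to [0, 1] for
    metrics on the unit scale.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need >= 2 fold values")
    mean = float(values.mean())
    half = float(_T_DIST.ppf((1 + level) / 2, n - 1)
                 * values.std(ddof=1) / np.sqrt(n))
    lo, hi = mean - half, mean + half
    if clip_unit:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return mean, lo, hi


# --------------------------------------------------------- univariable fits

def univariable_report(X: np.ndarray, y: np.ndarray,
                       feature_names: list[str]) -> pd.DataFrame:
    """Per-feature single-predictor logistic fits plus raw rank AUC.

    Reports per-unit OR = exp(beta) with Wald 95% CI and p; fits that do
    not converge (e.g. perfect separation) are flagged, not fatal.
    """
    import statsmodels.api as sm

    rows = []
    y = np.asarray(y)
    for j, name in enumerate(feature_names):
        x = np.asarray(X[:, j], dtype=float)
        entry = {"feature": name, "auc": auc_rank(x, y)}
        if entry["auc"] < 0.5:  # direction-free discrimination
            entry["auc_directional"] = entry["auc"]
            entry["auc"] = 1 - entry["auc"]
        try:
            design = sm.add_constant(x)
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            beta = float(fit.params[1])
            se = float(fit.bse[1])
            converged = bool(fit.mle_retvals.get("converged", False)) \
                and np.isfinite(se) and se < 1e3
            entry.update({
                "or": float(np.exp(beta)),
                "or_low": float(np.exp(beta - 1.959963984540054 * se)),
                "or_high": float(np.exp(beta + 1.959963984540054 * se)),
                "p": float(fit.pvalues[1]),
                "converged": converged,
            })
        except Exception:
            entry.update({"or": float("nan"), "or_low": float("nan"),
                          "or_high": float("nan"), "p": float("nan"),
                          "converged": False})
        rows.append(entry)
    return pd.DataFrame(rows)


def report_from_folds(fold_metrics: list[dict[str, float]],
                      pooled_cm: ConfusionMatrix,
                      pooled_auc: float) -> dict:
    """Assemble the evaluation report: per-fold metrics, fold-mean CIs,
    pooled confusion-matrix metrics, and the pooled-score AUC."""
    keys = ["auc", "accuracy", "sensitivity", "specificity", "gmean",
            "ppv", "npv"]
    ci_table = {}
    for key in keys:
        vals = np.array([fm[key] for fm in fold_metrics if key in fm])
        vals = vals[~np.isnan(vals)]
        if len(vals) >= 2:
            mean, lo, hi = fold_ci(vals)
            ci_table[key] = {"mean": mean, "low": lo, "high": hi}
    pooled = metric_suite(pooled_cm)
    return {
        "per_fold": fold_metrics,
        "fold_ci": ci_table,
        "pooled": {
            "confusion": {"tp": pooled_cm.tp, "fp": pooled_cm.fp,
                          "tn": pooled_cm.tn, "fn": pooled_cm.fn},
            **{k: v for k, v in pooled.items() if k != "undefined"},
            "auc": pooled_auc,
        },
    }
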