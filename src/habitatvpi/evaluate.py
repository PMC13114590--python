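"""Discrimination, calibration, clinical-utility and agreement statistics.

AUCs use the Mann-Whitney (midrank) formulation; confidence intervals and
paired model comparisons use DeLong's structural-components covariance
estimator.  Decision-curve analysis reports net benefit
NB(t) = TP/n - FP/n * t/(1-t) against treat-all / treat-none references.
Inter-rater agreement is the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation, ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(probs: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    y = np.asarray(labels)
    pos = np.asarray(probs, float)[y == 1]
    neg = np.asarray(probs, float)[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray


def roc_auc(probabilities, labels, alpha: float = 0.05) -> RocResult:
    """AUC with a DeLong-variance CI (logit-transformed bounds).

    The logit transform keeps the interval inside [0, 1]; degenerate AUCs of
    exactly 0 or 1 fall back to a clipped plain interval.
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _delong_components(p, y)
    m, n = (y == 1).sum(), (y == 0).sum()
    # a single-member class contributes no estimable component variance
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) \
        + (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    if 0.0 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - z * se_logit)))
        hi = 1 / (1 + np.exp(-(logit + z * se_logit)))
    else:
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    # ROC points (thresholds descending)
    order = np.argsort(-p, kind="mergesort")
    ys = y[order]
    tps = np.concatenate([[0], np.cumsum(ys == 1)])
    fps = np.concatenate([[0], np.cumsum(ys == 0)])
    return RocResult(float(auc), float(lo), float(hi), se, int(m), int(n),
                     fps / n, tps / m)


@dataclass
class DelongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float
    var_delta: float


def delong_test(probs_a, probs_b, labels) -> DelongComparison:
    """DeLong paired test for two correlated AUCs on the same cases."""
    y = np.asarray(labels)
    pa, pb = np.asarray(probs_a, float), np.asarray(probs_b, float)
    if pa.shape != pb.shape or pa.shape != y.shape:
        raise ValueError("both probability vectors must cover the same cases")
    auc_a, v10a, v01a = _delong_components(pa, y)
    auc_b, v10b, v01b = _delong_components(pb, y)
    m, n = (y == 1).sum(), (y == 0).sum()
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        raise ValueError("zero variance of AUC difference (identical predictors?)")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DelongComparison(float(auc_a), float(auc_b), float(auc_a - auc_b),
                            float(z), float(p), float(var))


def format_percent(numer: int, denom: int) -> str:
    """Count-fraction percentage with one-decimal rounding: '64/73 [87.7%]'."""
    return f"{numer}/{denom} [{100.0 * numer / denom:.1f}%]"


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else None

    @property
    def ppv(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def npv(self) -> float | None:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else None

    def as_strings(self) -> dict[str, str]:
        out = {}
        for name, num, den in [
            ("sensitivity", self.tp, self.tp + self.fn),
            ("specificity", self.tn, self.tn + self.fp),
            ("ppv", self.tp, self.tp + self.fp),
            ("npv", self.tn, self.tn + self.fn),
        ]:
            out[name] = format_percent(num, den) if den else "undefined"
        return out


def confusion_metrics(predicted, labels) -> ConfusionReport:
    """Confusion counts and derived metrics for binary predictions."""
    pred = np.asarray(predicted).astype(int)
    y = np.asarray(labels).astype(int)
    if not set(np.unique(pred)) <= {0, 1} or not set(np.unique(y)) <= {0, 1}:
        raise ValueError("inputs must be binary")
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return ConfusionReport(tp, fp, tn, fn)


def brier(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(((p - y) ** 2).mean())


def calibration_curve(
    probabilities, labels, n_bins: int = 10
) -> pd.DataFrame:
    """Equal-width reliability bins: (mean predicted, observed rate, count).

    Empty bins are omitted; bin counts sum to n.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append({
            "bin": b,
            "mean_predicted": p[sel].mean(),
            "observed_rate": y[sel].mean(),
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def decision_curve(
    probabilities, labels, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none across thresholds.

    NB(t) = TP/n - FP/n * t/(1-t); the default grid is 0.01..0.80 step 0.01.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.801, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        pred = p > t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        odds = t / (1 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is cases x raters (no missing values).  Zero between-case
    variance returns 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (>=2 cases) x (>=2 raters)")
    if np.any(np.isnan(x)):
        raise ValueError("missing ratings not supported")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(1)
    col_m = x.mean(0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= mse and np.isclose(msr, 0):
        warnings.warn("zero between-case variance; ICC undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return float((msr - mse) / denom)


ICC_SATISFACTORY = 0.80


def icc_satisfactory(icc: float) -> bool:
    """Agreement above 0.80 counts as satisfactory."""
    return icc > ICC_SATISFACTORY
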