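"""Classification metrics and model-comparison tests for imbalanced cohorts.

Threshold-free discrimination is summarized by the AUROC (Mann-Whitney
formulation, ties counted one half) and the AUPRC (step-wise,
non-interpolated estimator — the average-precision convention), the latter
preferred when cases are heavily outnumbered. The single operating point is
the probability threshold maximizing the absolute Matthews correlation
coefficient, at which F1, accuracy, precision, recall, and specificity are
reported. Paired AUROCs on identical samples are compared with the DeLong
test; paired per-bootstrap AUPRCs with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score


class MetricError(ValueError):
    """Metric undefined for the given inputs (e.g., single-class labels)."""


def _check_binary(labels: np.ndarray, need_both: bool = True) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise MetricError("labels must be binary 0/1")
    if need_both and (y.sum() == 0 or y.sum() == len(y)):
        raise MetricError("both classes must be present")
    return y


def auroc(scores, labels) -> float:
    """Probability that a random case outscores a random control (ties 1/2)."""
    y = _check_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under precision-recall by the step-wise estimator."""
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise MetricError("labels must be binary 0/1")
    if y.sum() == 0:
        raise MetricError("at least one positive required")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# MCC-optimal operating point
# ---------------------------------------------------------------------------

@dataclass
class ThresholdedMetrics:
    threshold: float
    mcc: float
    f1: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    degenerate: bool = False
    negative_orientation: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("threshold", "mcc", "f1", "accuracy", "precision", "recall",
                 "specificity")}


def _confusion_counts(scores: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    """Vectorized TP/FP/TN/FN for rule score >= threshold -> positive."""
    order = np.argsort(scores, kind="mergesort")
    s, ys = scores[order], y[order]
    P = ys.sum()
    N = len(ys) - P
    # predictions positive for scores >= t: cum sums from the right
    cum_pos = np.cumsum(ys[::-1])[::-1]           # cases with score >= s[i]
    idx = np.searchsorted(s, thresholds, side="left")
    tp = np.where(idx < len(s), np.concatenate([cum_pos, [0]])[idx], 0.0)
    n_ge = len(s) - idx
    fp = n_ge - tp
    fn = P - tp
    tn = N - fp
    return tp, fp, tn, fn, P, N


def _mcc(tp, fp, tn, fn):
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    return mcc


def mcc_threshold(scores, labels) -> ThresholdedMetrics:
    """Operating point maximizing |MCC| over candidate thresholds.

    Candidates are midpoints of adjacent distinct scores; ties take the
    lower threshold. If the optimum has negative MCC the orientation is
    flagged. All scores identical -> degenerate status.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    if len(uniq) == 1:
        return ThresholdedMetrics(float(uniq[0]), 0, 0, 0, 0, 0, 0,
                                  degenerate=True)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    tp, fp, tn, fn, P, N = _confusion_counts(s, y, cands)
    mccs = _mcc(tp, fp, tn, fn)
    best = int(np.argmax(np.abs(mccs)))  # argmax returns first (lowest) tie
    t = float(cands[best])
    tpb, fpb, tnb, fnb = tp[best], fp[best], tn[best], fn[best]
    prec = tpb / (tpb + fpb) if tpb + fpb > 0 else 0.0
    rec = tpb / P
    spec = tnb / N
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    acc = (tpb + tnb) / (P + N)
    return ThresholdedMetrics(t, float(mccs[best]), float(f1), float(acc),
                              float(prec), float(rec), float(spec),
                              negative_orientation=mccs[best] < 0)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    p: float
    auroc_a: float
    auroc_b: float
    z: float = np.nan
    degenerate: bool = False

    @property
    def difference(self) -> float:
        return self.auroc_a - self.auroc_b


def _placements(scores: np.ndarray, y: np.ndarray):
    """Structural components (placement values) of the AUROC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # midrank-based placements handle ties with the 1/2 convention
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    for j, x in enumerate(neg):
        v01[j] = (np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test for paired AUROC difference.

    Uses the structural-component (placement-value) covariance estimate on
    the same samples. Zero variance of the difference returns p = 1 with a
    degenerate flag.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(y) or len(b) != len(y):
        raise MetricError("scores must be paired on identical samples")
    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    aa, ab = float(np.mean(v10a)), float(np.mean(v10b))
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var <= 0:
        return DeLongResult(1.0, aa, ab, degenerate=True)
    z = (aa - ab) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return DeLongResult(float(p), aa, ab, float(z))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    p: float
    statistic: float = np.nan
    degenerate: bool = False


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 distinct nonzero differences, the normal approximation with
    tie and continuity correction above. All-zero differences -> p = 1
    with a degenerate flag.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise MetricError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return WilcoxonResult(1.0, degenerate=True)
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return WilcoxonResult(float(res.pvalue), float(res.statistic))


# ---------------------------------------------------------------------------
# Reports and model comparison
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """All metrics of one model at its MCC-optimal threshold."""

    auprc: float
    auroc: float
    thresholded: ThresholdedMetrics
    comparison: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"auprc": self.auprc, "auroc": self.auroc}
        d.update(self.thresholded.as_dict())
        d.update(self.comparison)
        return d


def evaluate(scores, labels) -> EvalReport:
    """AUPRC, AUROC, and thresholded metrics at the |MCC|-optimal point."""
    return EvalReport(auprc(scores, labels), auroc(scores, labels),
                      mcc_threshold(scores, labels))


def compare_models(predictions: dict, labels,
                   bootstrap_auprc: dict | None = None) -> pd.DataFrame:
    """Pairwise model comparison table.

    For each ordered pair (a, b): relative AUPRC/AUROC change of b over a
    in percent ((b - a) / a * 100), the DeLong p on the pooled hold-out
    scores, and — when per-iteration bootstrap AUPRCs sharing resample
    indices are supplied — the paired Wilcoxon p.
    """
    y = np.asarray(labels, dtype=float)
    for name, s in predictions.items():
        if len(np.asarray(s)) != len(y):
            raise MetricError(f"scores of {name!r} not aligned to labels")
    rows = []
    names = list(predictions)
    stats_ = {n: (auprc(predictions[n], y), auroc(predictions[n], y))
              for n in names}
    for a in names:
        for b in names:
            if a == b:
                continue
            pr_a, roc_a = stats_[a]
            pr_b, roc_b = stats_[b]
            dl = delong_test(predictions[b], predictions[a], y)
            row = {"model_a": a, "model_b": b,
                   "auprc_a": pr_a, "auprc_b": pr_b,
                   "auroc_a": roc_a, "auroc_b": roc_b,
                   "delta_auprc_pct": (pr_b - pr_a) / pr_a * 100.0,
                   "delta_auroc_pct": (roc_b - roc_a) / roc_a * 100.0,
                   "delong_p": dl.p, "delong_degenerate": dl.degenerate,
                   "wilcoxon_p": np.nan}
            if bootstrap_auprc and a in bootstrap_auprc and b in bootstrap_auprc:
                wr = wilcoxon_signed_rank(bootstrap_auprc[b], bootstrap_auprc[a])
                row["wilcoxon_p"] = wr.p
            rows.append(row)
    return pd.DataFrame(rows)
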