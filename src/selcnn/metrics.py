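"""Binary-classifier evaluation: thresholding, confusion counts, ROC/PR.

Conventions fixed here (and relied on by the rest of the package):

* classification is *inclusive* at the threshold — a gene is called positive
  when its score Z satisfies Z >= threshold (default 0.5);
* ROC AUC uses trapezoidal integration over the curve built at every distinct
  score plus both endpoints, which gives tied scores half-concordance — the
  standard Mann-Whitney convention;
* the precision-recall curve's recall -> 0 endpoint carries the precision of
  the highest-score point (not 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class truth)."""


@dataclass
class MetricsReport:
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    tpr: float
    fpr: float
    precision: float
    recall: float
    roc_auc: float
    pr_auc: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n": self.n,
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "precision": self.precision,
            "recall": self.recall,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
        }


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    return scores


def classify(scores, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff score >= threshold (inclusive at the threshold)."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return (_check_scores(scores) >= threshold).astype(int)


def _validated(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    scores = _check_scores(scores)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal lengths")
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth labels must be binary 0/1")
    return scores, truth.astype(int)


def roc_curve(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) over all distinct scores plus endpoints."""
    scores, truth = _validated(scores, truth)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC is undefined for single-class truth")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], truth[order]
    # group tied scores so ties contribute a single diagonal segment
    distinct = np.r_[True, np.diff(s) != 0]
    idx = np.flatnonzero(distinct)
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    ends = np.r_[idx[1:] - 1, len(s) - 1]
    tpr = np.r_[0.0, tp_cum[ends] / n_pos]
    fpr = np.r_[0.0, fp_cum[ends] / n_neg]
    thresholds = np.r_[np.inf, s[idx]]
    return fpr, tpr, thresholds


def roc_auc(scores, truth) -> float:
    fpr, tpr, _ = roc_curve(scores, truth)
    return float(np.trapezoid(tpr, fpr))


def pr_curve(scores, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(recall, precision, thresholds); recall->0 endpoint repeats the
    precision of the highest-score point."""
    scores, truth = _validated(scores, truth)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == len(truth):
        raise UndefinedMetricError("PR curve is undefined for single-class truth")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], truth[order]
    distinct = np.r_[True, np.diff(s) != 0]
    idx = np.flatnonzero(distinct)
    ends = np.r_[idx[1:] - 1, len(s) - 1]
    tp = np.cumsum(y)[ends]
    predicted = ends + 1
    precision = tp / predicted
    recall = tp / n_pos
    return (
        np.r_[0.0, recall],
        np.r_[precision[0], precision],
        np.r_[np.inf, s[idx]],
    )


def pr_auc(scores, truth) -> float:
    recall, precision, _ = pr_curve(scores, truth)
    return float(np.trapezoid(precision, recall))


def compute_report(scores, truth, threshold: float = 0.5) -> MetricsReport:
    """Confusion counts, rates and both AUCs at one decision threshold."""
    scores, truth = _validated(scores, truth)
    labels = classify(scores, threshold)
    tp = int(np.sum((labels == 1) & (truth == 1)))
    tn = int(np.sum((labels == 0) & (truth == 0)))
    fp = int(np.sum((labels == 1) & (truth == 0)))
    fn = int(np.sum((labels == 0) & (truth == 1)))
    n = len(truth)
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "metrics are undefined for single-class truth; "
            "supply both positive and negative genes"
        )
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return MetricsReport(
        threshold=threshold,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / n,
        tpr=tp / n_pos,
        fpr=fp / n_neg,
        precision=precision,
        recall=tp / n_pos,
        roc_auc=roc_auc(scores, truth),
        pr_auc=pr_auc(scores, truth),
    )


def read_codeml_results(path):
    """Adapter: ingest an externally produced CODEML result table.

    Expects a TSV with columns ``gene_id``, ``p_m1a_m2a``, ``p_m7_m8``
    (likelihood-ratio-test p-values).  A gene is called positively selected
    when both LRTs are significant at the given level (the conventional
    joint rule).  No likelihood computation happens here.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "p_m1a_m2a", "p_m7_m8"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CODEML table is missing columns: {sorted(missing)}")
    return df


def codeml_calls(df, alpha: float = 0.05) -> np.ndarray:
    return ((df["p_m1a_m2a"] < alpha) & (df["p_m7_m8"] < alpha)).astype(int).to_numpy()
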