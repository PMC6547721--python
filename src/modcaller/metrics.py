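"""Classification metrics for site-level modification calling.

Accuracy, precision, recall and F1 follow the set-count definitions over M
completely modified and N completely unmodified sites of which P were
predicted modified and Q unmodified.  Average precision (AP) is the
non-interpolated step sum of precision weighted by recall increments over
thresholds placed at each distinct score; AUC is the Mann-Whitney
probability that a random positive outscores a random negative, ties
counted half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "EvalResult",
    "confusion_metrics",
    "f1_score",
    "average_precision",
    "auc",
    "evaluate_sites",
]


@dataclass
class EvalResult:
    """Bundle of site-level evaluation metrics at one coverage threshold."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    ap: float
    auc: float
    n_modified: int
    n_unmodified: int
    n_pred_mod: int
    n_pred_unmod: int

    def as_dict(self) -> dict:
        return asdict(self)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def confusion_metrics(
    truth: np.ndarray, calls: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from binary truth and calls.

    With no modified predictions, precision is undefined and reported NaN
    (likewise recall with no modified truth); a warning is emitted.
    """
    y = np.asarray(truth).astype(bool)
    c = np.asarray(calls).astype(bool)
    if y.shape != c.shape:
        raise ValueError("truth and calls must be keyed identically")
    M = int(y.sum())
    N = int((~y).sum())
    P = int(c.sum())
    tp = int((c & y).sum())
    tn = int((~c & ~y).sum())
    accuracy = (tp + tn) / (M + N) if M + N else float("nan")
    if P == 0:
        warnings.warn("no modified predictions: precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = tp / P
    if M == 0:
        warnings.warn("no modified truth sites: recall undefined", stacklevel=2)
        recall = float("nan")
    else:
        recall = tp / M
    return accuracy, precision, recall, f1_score(precision, recall)


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-sum AP: sum of precision times recall increment per threshold.

    Thresholds are placed at each distinct score, descending; tied scores
    collapse into one threshold, so the result is invariant to within-tie
    ordering.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(np.float64)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("average precision requires at least one positive label")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # last index of each distinct-score run = one threshold
    thresh = np.flatnonzero(np.diff(s) != 0)
    thresh = np.concatenate([thresh, [len(s) - 1]])
    tp = np.cumsum(y)[thresh]
    pred_pos = thresh + 1.0
    precision = tp / pred_pos
    recall = tp / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    M = int(y.sum())
    N = int((~y).sum())
    if M == 0 or N == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(s)
    return float((ranks[y].sum() - M * (M + 1) / 2.0) / (M * N))


def ranking_tables(scores: np.ndarray, labels: np.ndarray):
    """Per-threshold precision/recall and ROC tables as DataFrames.

    One row per distinct score (descending); suitable for TSV export and
    PR/ROC plotting.
    """
    import pandas as pd

    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    M = int(y.sum())
    N = len(y) - M
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    thresh = np.flatnonzero(np.diff(s) != 0)
    thresh = np.concatenate([thresh, [len(s) - 1]])
    tp = np.cumsum(y)[thresh]
    fp = (thresh + 1) - tp
    pr = pd.DataFrame(
        {
            "threshold": s[thresh],
            "precision": tp / (thresh + 1),
            "recall": tp / M if M else np.nan,
        }
    )
    roc = pd.DataFrame(
        {
            "threshold": s[thresh],
            "tpr": tp / M if M else np.nan,
            "fpr": fp / N if N else np.nan,
        }
    )
    return pr, roc


def evaluate_sites(
    summaries: Mapping[tuple[str, int, str], "SiteSummary"],
    truth_labels: Mapping[tuple[str, int, str], int],
    min_cov: int = 1,
    call_threshold: float = 0.1,
) -> EvalResult:
    """Coverage-stratified site-level evaluation.

    Restricts to truth-labeled sites with coverage >= ``min_cov``; the
    predicted methylation percentage is the ranking score for AP/AUC, and a
    site is called modified when its percentage >= ``call_threshold``.
    """
    scores, y = [], []
    for key, label in truth_labels.items():
        summ = summaries.get(key)
        if summ is None or summ.coverage < min_cov:
            continue
        scores.append(summ.pct)
        y.append(label)
    if not scores:
        raise ValueError(
            "no truth-labeled site passes the coverage filter; nothing to evaluate"
        )
    scores = np.asarray(scores)
    y = np.asarray(y)
    calls = scores >= call_threshold
    accuracy, precision, recall, f1 = confusion_metrics(y, calls)
    return EvalResult(
        accuracy, precision, recall, f1,
        average_precision(scores, y), auc(scores, y),
        int(y.sum()), int(len(y) - y.sum()),
        int(calls.sum()), int(len(calls) - calls.sum()),
    )
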