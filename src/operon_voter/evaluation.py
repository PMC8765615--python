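"""Recall/specificity, ROC/AUC, bootstrap confidence intervals, repeated
75/25 split validation and feature-label Spearman diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .io import ALGORITHM_KEYS


@dataclass
class EvalReport:
    recall: Optional[float]
    specificity: Optional[float]
    n_pairs: int
    bootstrap: Dict[str, dict] = field(default_factory=dict)
    roc_points: Optional[List[Tuple[float, float]]] = None
    auc: Optional[float] = None


def _align(calls: Mapping[str, int], labels: Mapping[str, int]) -> Tuple[np.ndarray, np.ndarray]:
    common = sorted(set(calls) & set(labels))
    if not common:
        raise ValueError("no overlapping pair ids between calls and labels")
    y_pred = np.array([int(calls[p]) for p in common])
    y_true = np.array([int(labels[p]) for p in common])
    return y_pred, y_true


def recall_specificity(
    y_pred: np.ndarray, y_true: np.ndarray
) -> Tuple[Optional[float], Optional[float]]:
    """TP/(TP+FN) and TN/(TN+FP); None when a denominator is zero."""
    y_pred = np.asarray(y_pred, dtype=int)
    y_true = np.asarray(y_true, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    recall = tp / (tp + fn) if (tp + fn) else None
    specificity = tn / (tn + fp) if (tn + fp) else None
    return recall, specificity


def confusion_metrics(
    calls: Mapping[str, int], labels: Mapping[str, int]
) -> EvalReport:
    """Score binary calls against labels; only pairs present in both count."""
    y_pred, y_true = _align(calls, labels)
    recall, specificity = recall_specificity(y_pred, y_true)
    return EvalReport(recall=recall, specificity=specificity, n_pairs=y_true.size)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[List[Tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC.

    Works for continuous probabilities, integer vote counts, or a single
    binary call — for the last, the curve is the 3-point polyline through
    (1 - specificity, sensitivity) and AUC reduces to (sens + spec) / 2.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("roc_auc requires both classes in labels")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist())), float(auc(fpr, tpr))


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], Optional[float]],
    calls: Mapping[str, int],
    labels: Mapping[str, int],
    n_boot: int = 100,
    fraction: float = 0.10,
    seed: int = 0,
) -> dict:
    """Percentile bootstrap of a metric over pair subsets.

    Each iteration draws ``fraction * n`` pairs with replacement and
    recomputes ``metric(y_pred, y_true)``; reports the mean and the 2.5/97.5
    percentile bounds over iterations where the metric was defined. Errors
    out if the metric is undefined in more than half of the iterations.
    """
    y_pred, y_true = _align(calls, labels)
    n = y_true.size
    if n < 10:
        raise ValueError("bootstrap_ci needs at least 10 scored pairs")
    m = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=m)
        values.append(metric(y_pred[idx], y_true[idx]))
    defined = [v for v in values if v is not None]
    if len(defined) < n_boot / 2:
        raise ValueError(
            f"metric undefined in {n_boot - len(defined)}/{n_boot} bootstrap iterations"
        )
    arr = np.asarray(defined, dtype=float)
    return {
        "mean": float(arr.mean()),
        "ci_low": float(np.percentile(arr, 2.5)),
        "ci_high": float(np.percentile(arr, 97.5)),
        "n_defined": len(defined),
    }


def _metric_recall(y_pred, y_true):
    return recall_specificity(y_pred, y_true)[0]


def _metric_specificity(y_pred, y_true):
    return recall_specificity(y_pred, y_true)[1]


METRICS = {"recall": _metric_recall, "specificity": _metric_specificity}


def split_validate(
    features: pd.DataFrame,
    labels: Optional[np.ndarray] = None,
    n_splits: int = 50,
    train_fraction: float = 0.75,
    seed: int = 0,
    optimize: bool = False,
) -> pd.DataFrame:
    """Repeated random 75/25 train/validation splits of the feature table.

    Trains the full suite on each training split and scores per-algorithm
    recall and specificity on the held-out quarter; returns the per-algorithm
    means over splits. ``n_splits`` can be reduced for desk-scale runs.
    """
    from .estimators import OperonPairSuite  # deferred: avoids import cycle

    if labels is None:
        labels = features["label"].to_numpy()
    labels = np.asarray(labels, dtype=int)
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed
    )
    acc: Dict[str, List[float]] = {
        f"{key}_{m}": [] for key in ALGORITHM_KEYS for m in ("recall", "specificity")
    }
    for train_idx, test_idx in splitter.split(np.zeros(len(labels)), labels):
        suite = OperonPairSuite(optimize=optimize, random_state=seed).fit(
            features.iloc[train_idx], labels[train_idx]
        )
        calls = suite.predict_calls(features.iloc[test_idx])
        y_true = labels[test_idx]
        for key in ALGORITHM_KEYS:
            rec, spec = recall_specificity(calls[key].to_numpy(), y_true)
            if rec is not None:
                acc[f"{key}_recall"].append(rec)
            if spec is not None:
                acc[f"{key}_specificity"].append(spec)
    rows = [
        {
            "algorithm": key,
            "recall": float(np.mean(acc[f"{key}_recall"])),
            "specificity": float(np.mean(acc[f"{key}_specificity"])),
        }
        for key in ALGORITHM_KEYS
    ]
    return pd.DataFrame(rows, columns=["algorithm", "recall", "specificity"])


def feature_label_spearman(
    features: pd.DataFrame, labels: Optional[np.ndarray] = None
) -> pd.Series:
    """Midrank Spearman correlation of each feature column with the label.

    Constant features get NaN (correlation undefined).
    """
    from .io import FEATURE_COLUMNS

    if labels is None:
        labels = features["label"].to_numpy()
    labels = np.asarray(labels, dtype=float)
    if labels.size < 3:
        raise ValueError("feature_label_spearman needs at least 3 samples")
    out = {}
    for col in FEATURE_COLUMNS:
        x = features[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            out[col] = np.nan
            continue
        rho, _p = stats.spearmanr(x, labels)
        out[col] = float(rho)
    return pd.Series(out, name="spearman_rho")
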