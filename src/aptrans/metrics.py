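"""Evaluation metrics for the translation task (MSE, pooled R2, APD90
prediction error) and the classification task (AUROC, accuracy, recall,
precision, confusion counts)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .network import NetParams, forward_cached
from .preprocess import NormStats, denormalize, morphology_features

__all__ = [
    "EvalReport",
    "r2_score",
    "classification_metrics",
    "auroc",
    "apd90_error",
    "evaluate",
    "predict",
]


@dataclass
class EvalReport:
    """Per-dataset performance summary (translation and classification)."""

    n: int
    mse: float
    r2: float
    apd90_error_percent: Optional[float] = None
    apd90_failures: int = 0
    auroc: Optional[float] = None
    accuracy_percent: Optional[float] = None
    recall: Optional[float] = None
    precision: Optional[float] = None
    fpr: Optional[float] = None
    tp: Optional[int] = None
    tn: Optional[int] = None
    fp: Optional[int] = None
    fn: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    def table(self) -> str:
        """Human-readable two-section table."""
        lines = ["Translation", "  MSE        R2      APD90 error",
                 f"  {self.mse:<10.4g} {self.r2:<7.4g} "
                 + ("-" if self.apd90_error_percent is None
                    else f"{self.apd90_error_percent:.2f}%")]
        if self.auroc is not None:
            lines += ["Classification",
                      "  AUROC   Accuracy  Recall  Precision",
                      f"  {self.auroc:<7.3g} {self.accuracy_percent:<9.3g} "
                      f"{self.recall:<7.3g} "
                      + ("-" if self.precision is None else f"{self.precision:.3g}")]
        return "\n".join(lines)


def r2_score(true: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination pooled over all samples and time points."""
    y = np.asarray(true, dtype=float).ravel()
    f = np.asarray(predicted, dtype=float).ravel()
    if y.shape != f.shape:
        raise ValueError("shape mismatch between truth and prediction")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in the true traces; R2 undefined")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


def classification_metrics(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
) -> dict:
    """Accuracy (in percent), recall, precision, FPR and confusion counts.

    Precision is reported as None (missing) when nothing is predicted
    positive, rather than 0.
    """
    y = np.asarray(labels, dtype=int)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0/1")
    p = np.asarray(probabilities, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = tp + tn + fp + fn
    out = {
        "accuracy_percent": 100.0 * (tp + tn) / n,
        "recall": tp / (tp + fn) if tp + fn else None,
        "precision": tp / (tp + fp) if tp + fp else None,
        "fpr": fp / (fp + tn) if fp + tn else None,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }
    return out


def auroc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    Equivalent to P(score_pos > score_neg) + 0.5 P(tie), which is what
    trapezoidal integration over all thresholds yields.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(s)  # average ranks handle ties
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def apd90_error(
    true_traces: np.ndarray,
    translated_traces: np.ndarray,
    stats: NormStats,
    dt: float = 1.0,
    denormalize_true: bool = True,
) -> tuple[float, int]:
    """Mean absolute percentage error of the predicted adult APD90.

    Both inputs are normalized traces; they are mapped back to mV with the
    training-set statistics before feature extraction.  Traces on which
    the APD90 cannot be computed are excluded and counted.
    """
    t = np.atleast_2d(np.asarray(true_traces, dtype=float))
    p = np.atleast_2d(np.asarray(translated_traces, dtype=float))
    errs = []
    failures = 0
    for vt, vp in zip(t, p):
        try:
            a_true = morphology_features(
                denormalize(vt, stats) if denormalize_true else vt, dt).apd90_ms
            a_pred = morphology_features(denormalize(vp, stats), dt).apd90_ms
            errs.append(100.0 * abs(a_pred - a_true) / a_true)
        except ValueError:
            failures += 1
    if failures:
        warnings.warn(f"APD90 computation failed on {failures} trace(s)")
    if not errs:
        raise ValueError("APD90 could not be computed on any trace")
    return float(np.mean(errs)), failures


def predict(params: NetParams, X: np.ndarray, batch: int = 256):
    """Dropout-off forward over a dataset; returns (translations, probs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    outs = []
    probs = []
    for lo in range(0, len(X), batch):
        y, p, _ = forward_cached(X[lo:lo + batch], params, training=False)
        outs.append(np.atleast_2d(y))
        if p is not None:
            probs.append(np.atleast_1d(p))
    Y = np.concatenate(outs, axis=0)
    P = np.concatenate(probs) if probs else None
    return Y, P


def evaluate(
    params: NetParams,
    X: np.ndarray,
    Y_true: np.ndarray,
    labels: Optional[np.ndarray],
    stats_adult: NormStats,
    threshold: float = 0.5,
) -> EvalReport:
    """Run the network (dropout off) on a dataset and assemble the report."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) == 0:
        raise ValueError("empty dataset")
    Y_true = np.atleast_2d(np.asarray(Y_true, dtype=float))
    Y_pred, P = predict(params, X)
    try:
        apd_err, apd_fail = apd90_error(Y_true, Y_pred, stats_adult)
    except ValueError:  # no trace yielded an APD90 (e.g. untrained network)
        apd_err, apd_fail = None, len(X)
    report = EvalReport(
        n=len(X),
        mse=float(np.mean((Y_pred - Y_true) ** 2)),
        r2=r2_score(Y_true, Y_pred),
        apd90_error_percent=apd_err,
        apd90_failures=apd_fail,
    )
    if P is not None and labels is not None:
        cm = classification_metrics(labels, P, threshold)
        report.auroc = auroc(labels, P)
        report.accuracy_percent = cm["accuracy_percent"]
        report.recall = cm["recall"]
        report.precision = cm["precision"]
        report.fpr = cm["fpr"]
        report.tp, report.tn = cm["tp"], cm["tn"]
        report.fp, report.fn = cm["fp"], cm["fn"]
    return report
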