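"""Evaluation formulas for both heads.

Classification uses one-vs-rest per-phase counts: for phase p,
TP = #(true=p and pred=p), FP = #(true!=p and pred=p),
FN = #(true=p and pred!=p); precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), all in percent, and the *total accuracy* is the arithmetic
mean of the ten per-phase F1 scores (a macro-F1).  Regression uses
MSE = 1/n sum (y - yhat)^2, MAE = 1/n sum |y - yhat| and
R^2 = (Var(y) - MSE) / Var(y) with the population (divide-by-n) variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseConfusion",
    "ClassificationReport",
    "RegressionReport",
    "confusion_counts",
    "precision_recall_f1",
    "total_accuracy",
    "classification_report",
    "regression_metrics",
    "regression_report",
]

N_PHASES = 10


@dataclass
class PhaseConfusion:
    """One-vs-rest TP/FP/FN counts per respiratory phase."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.tp.sum() + self.fn.sum())


@dataclass
class ClassificationReport:
    precision: np.ndarray  # percent, per phase
    recall: np.ndarray
    f1: np.ndarray
    total_accuracy: float  # percent; mean of the ten F1 scores
    confusion: PhaseConfusion | None = None


@dataclass
class RegressionReport:
    """MSE/MAE on the min-max-normalized scale (reported as percent, i.e.
    the [0,1]-scale value x 100) and in physical mm, plus R^2."""

    mse_mm2: float
    mae_mm: float
    r2: float
    mse_percent: float | None = None  # normalized-scale MSE x 100
    mae_percent: float | None = None


def _check_labels(y, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if len(y) and (y.min() < 0 or y.max() >= N_PHASES):
        raise ValueError(f"{name} contains labels outside 0..{N_PHASES - 1}")
    return y


def confusion_counts(y_true, y_pred) -> PhaseConfusion:
    """One-vs-rest TP/FP/FN per phase."""
    y_true = _check_labels(y_true, "y_true")
    y_pred = _check_labels(y_pred, "y_pred")
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    tp = np.zeros(N_PHASES, dtype=int)
    fp = np.zeros(N_PHASES, dtype=int)
    fn = np.zeros(N_PHASES, dtype=int)
    for p in range(N_PHASES):
        tp[p] = np.sum((y_true == p) & (y_pred == p))
        fp[p] = np.sum((y_true != p) & (y_pred == p))
        fn[p] = np.sum((y_true == p) & (y_pred != p))
    return PhaseConfusion(tp=tp, fp=fp, fn=fn)


def precision_recall_f1(
    counts: PhaseConfusion,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-phase precision/recall/F1 in percent.

    A phase with no true positives (TP=0) gets 0% by convention, with a
    warning — the degenerate denominators never arise in clean evaluations.
    """
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)
    if np.any(tp < 0) or np.any(fp < 0) or np.any(fn < 0):
        raise ValueError("counts must be non-negative")
    precision = np.zeros(N_PHASES)
    recall = np.zeros(N_PHASES)
    f1 = np.zeros(N_PHASES)
    for p in range(N_PHASES):
        if tp[p] == 0:
            if fp[p] > 0 or fn[p] > 0:
                warnings.warn(
                    f"phase {p}: no true positives; precision/recall/F1 set to 0%",
                    stacklevel=2,
                )
            continue
        precision[p] = 100.0 * tp[p] / (tp[p] + fp[p])
        recall[p] = 100.0 * tp[p] / (tp[p] + fn[p])
        f1[p] = (
            2.0 * precision[p] * recall[p] / (precision[p] + recall[p])
        )
    return precision, recall, f1


def total_accuracy(f1_scores) -> float:
    """Arithmetic mean of the ten per-phase F1 scores (percent)."""
    f1_scores = np.asarray(f1_scores, dtype=float)
    if f1_scores.shape != (N_PHASES,):
        raise ValueError(f"expected exactly {N_PHASES} F1 scores")
    return float(f1_scores.mean())


def classification_report(y_true, y_pred) -> ClassificationReport:
    counts = confusion_counts(y_true, y_pred)
    precision, recall, f1 = precision_recall_f1(counts)
    return ClassificationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        total_accuracy=total_accuracy(f1),
        confusion=counts,
    )


def regression_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(MSE, MAE, R^2) on whatever scale the inputs are given.

    R^2 = (Var - MSE)/Var with population variance; a constant truth
    sequence has no variance and is rejected.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("sequences must be non-empty and of equal length")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    var = float(np.mean((y_true - y_true.mean()) ** 2))
    if var == 0:
        raise ValueError("true sequence is constant; R^2 is undefined")
    r2 = (var - mse) / var
    return mse, mae, r2


def regression_report(y_true_mm, y_pred_mm, y_scaler=None) -> RegressionReport:
    """Assemble the full regression report.

    Physical-scale metrics always; when the fitted target ``MinMaxScaler``
    is supplied, MSE/MAE are additionally reported on the normalized [0, 1]
    scale x 100 ("percent"), the convention used for the published error
    bands.  R^2 is scale-invariant under the affine min-max map, so one
    value serves both.
    """
    mse_mm2, mae_mm, r2 = regression_metrics(y_true_mm, y_pred_mm)
    mse_pct = mae_pct = None
    if y_scaler is not None:
        yt = y_scaler.transform(np.asarray(y_true_mm, dtype=float)[:, None]).ravel()
        yp = y_scaler.transform(np.asarray(y_pred_mm, dtype=float)[:, None]).ravel()
        err = yt - yp
        mse_pct = 100.0 * float(np.mean(err**2))
        mae_pct = 100.0 * float(np.mean(np.abs(err)))
    return RegressionReport(
        mse_mm2=mse_mm2, mae_mm=mae_mm, r2=r2,
        mse_percent=mse_pct, mae_percent=mae_pct,
    )
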