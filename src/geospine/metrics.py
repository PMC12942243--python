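"""Agreement and classification metrics.

Agreement between predicted and reference geometry indices is summarized the
way method-comparison studies report it: mean absolute error, Lin's
concordance correlation coefficient, R² about the identity line,
Bland–Altman bias with 95 % limits of agreement, and Deming regression
(errors in both variables, variance ratio 1).  Classification metrics
(accuracy, macro-F1, one-vs-rest macro AUROC) are delegated to
scikit-learn behind this module's surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

__all__ = [
    "agreement_metrics",
    "classification_metrics",
    "ccc",
    "deming_regression",
    "bland_altman",
]


def ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·cov(x, y) / (σx² + σy² + (μx − μy)²); population moments.
    Undefined (NaN) when both inputs are constant.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / (vx + vy + (x.mean() - y.mean()) ** 2))


def deming_regression(x: np.ndarray, y: np.ndarray, variance_ratio: float = 1.0):
    """Deming slope/intercept with error-variance ratio λ (default 1).

    slope = [s_yy − λ s_xx + sqrt((s_yy − λ s_xx)² + 4 λ s_xy²)] / (2 s_xy).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx, syy = x.var(ddof=1), y.var(ddof=1)
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)
    if sxy == 0:
        return float("nan"), float("nan")
    lam = variance_ratio
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy ** 2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def bland_altman(x: np.ndarray, y: np.ndarray):
    """Bias (mean difference y − x) and 95 % limits of agreement (±1.96 SD)."""
    d = np.asarray(y, float) - np.asarray(x, float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def agreement_metrics(predicted: np.ndarray, reference: np.ndarray) -> dict:
    """MAE, CCC, R² (identity line), Bland–Altman and Deming for one index.

    R² is computed about the identity line y = x (not a refit), so it
    penalizes calibration error as well as scatter.
    """
    y, x = np.asarray(predicted, float), np.asarray(reference, float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    mae = float(np.abs(y - x).mean())
    ss_res = float(((y - x) ** 2).sum())
    ss_tot = float(((x - x.mean()) ** 2).sum())
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    bias, limits = bland_altman(x, y)
    slope, intercept = deming_regression(x, y)
    return {
        "mae": mae,
        "ccc": ccc(x, y),
        "r2": r2,
        "bland_altman_bias": bias,
        "bland_altman_limits": limits,
        "deming_slope": slope,
        "deming_intercept": intercept,
    }


def classification_metrics(labels: np.ndarray, probabilities: np.ndarray) -> dict:
    """Accuracy, macro-F1 and one-vs-rest macro AUROC.

    ``labels`` are integer class indices; ``probabilities`` rows must sum
    to 1.  Classes absent from ``labels`` are excluded from the macro means
    (warned).
    """
    labels = np.asarray(labels, int)
    probs = np.asarray(probabilities, float)
    if probs.ndim != 2 or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    pred = probs.argmax(axis=1)
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least 2 classes present")
    if len(present) < probs.shape[1]:
        warnings.warn("some classes absent from labels; macro means cover present classes")
    acc = float(accuracy_score(labels, pred))
    f1 = float(f1_score(labels, pred, labels=present, average="macro", zero_division=0))
    if probs.shape[1] == 2:
        auroc = float(roc_auc_score(labels, probs[:, 1]))
    elif len(present) == probs.shape[1]:
        auroc = float(roc_auc_score(labels, probs, multi_class="ovr", average="macro"))
    else:
        sub = probs[:, present]
        sub = sub / sub.sum(axis=1, keepdims=True)
        remap = {c: i for i, c in enumerate(present)}
        auroc = float(roc_auc_score(np.array([remap[c] for c in labels]), sub,
                                    multi_class="ovr", average="macro"))
    return {"accuracy": acc, "macro_f1": f1, "auroc": auroc}
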