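"""Multiclass confusion-matrix metrics: RCI, CEN, IBA, GM, MCC.

All metrics consume a K x K count matrix with rows = true class and columns =
predicted class.  The study names these five metrics without printing their
formulas; the standard literature definitions are used here:

* RCI — relative classifier information, the mutual information between true
  and predicted labels normalised by the true-label entropy,
  ``(H(T) - H(T|P)) / H(T)``.
* CEN — per-class confusion entropy: the entropy (log base ``2(K-1)``) of the
  misclassification probabilities in class j's row and column, each normalised
  by ``S_j = sum_k C[j,k] + sum_k C[k,j]``.
* IBA — index of balanced accuracy of the one-vs-rest table,
  ``(1 + alpha*(TPR - TNR)) * TPR * TNR`` (alpha defaults to 0.1).
* GM — geometric mean of one-vs-rest sensitivity and specificity.
* MCC — Matthews correlation coefficient of the one-vs-rest 2x2 table, with
  the usual 0-on-zero-denominator convention.

Conventions: ``0 * log 0 == 0`` throughout; averages over classes are
unweighted ("balanced") means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "rci",
    "cen_per_class",
    "iba_per_class",
    "gm_per_class",
    "mcc_per_class",
    "class_average",
    "round_half_away",
    "metric_row",
    "DegenerateMatrixError",
]


class DegenerateMatrixError(ValueError):
    """Metric undefined for this matrix (e.g. single-class truth marginal)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K integer counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if counts.shape[0] < 2:
            raise ValueError("at least 2 classes required")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() < 1:
            raise ValueError("total count must be >= 1")
        names = tuple(self.class_names) or tuple(str(i) for i in range(counts.shape[0]))
        if len(names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", names)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, j: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) of class j against the rest."""
        c = self.counts
        tp = int(c[j, j])
        fn = int(c[j].sum() - tp)
        fp = int(c[:, j].sum() - tp)
        tn = int(c.sum() - tp - fn - fp)
        return tp, fn, fp, tn


def _xlogx(p: np.ndarray) -> np.ndarray:
    # 0*log 0 == 0
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def rci(cm: ConfusionMatrix) -> float:
    """Relative classifier information, ``I(T;P) / H(T)`` in [0, 1]."""
    joint = cm.counts / cm.n
    p_true = joint.sum(axis=1)
    p_pred = joint.sum(axis=0)
    h_true = -_xlogx(p_true).sum()
    if h_true == 0:
        raise DegenerateMatrixError("true-class marginal has zero entropy")
    # H(T|P) = H(T,P) - H(P)
    h_joint = -_xlogx(joint).sum()
    h_pred = -_xlogx(p_pred).sum()
    value = (h_true - (h_joint - h_pred)) / h_true
    return float(min(max(value, 0.0), 1.0))


def cen_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Confusion entropy of each class (0 = never confused); log base 2(K-1)."""
    c = cm.counts.astype(np.float64)
    k = cm.k
    log_base = np.log2(2 * (k - 1))
    out = np.zeros(k)
    for j in range(k):
        s_j = c[j, :].sum() + c[:, j].sum()
        if s_j == 0:
            out[j] = 0.0  # class never observed nor predicted
            continue
        total = 0.0
        for other in range(k):
            if other == j:
                continue
            for p in (c[j, other] / s_j, c[other, j] / s_j):
                if p > 0:
                    total += p * np.log2(p) / log_base
        out[j] = -total
    return out


def _rates(cm: ConfusionMatrix, j: int) -> tuple[float, float]:
    tp, fn, fp, tn = cm.one_vs_rest(j)
    if tp + fn == 0 or fp + tn == 0:
        raise DegenerateMatrixError(
            f"class {cm.class_names[j]!r} has no positives or no negatives"
        )
    return tp / (tp + fn), tn / (tn + fp)


def iba_per_class(cm: ConfusionMatrix, alpha: float = 0.1) -> np.ndarray:
    """Index of balanced accuracy per one-vs-rest class:
    ``(1 + alpha*(TPR - TNR)) * TPR * TNR``."""
    out = np.zeros(cm.k)
    for j in range(cm.k):
        tpr, tnr = _rates(cm, j)
        out[j] = (1 + alpha * (tpr - tnr)) * tpr * tnr
    return out


def gm_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Geometric mean of one-vs-rest sensitivity and specificity."""
    out = np.zeros(cm.k)
    for j in range(cm.k):
        tpr, tnr = _rates(cm, j)
        out[j] = np.sqrt(tpr * tnr)
    return out


def mcc_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Matthews correlation coefficient of each one-vs-rest 2x2 table;
    0 when any denominator factor vanishes."""
    out = np.zeros(cm.k)
    for j in range(cm.k):
        tp, fn, fp, tn = cm.one_vs_rest(j)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        out[j] = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return out


def round_half_away(x: float, decimals: int = 4) -> float:
    """Round half away from zero (the reporting convention of the printed
    tables; numpy's default rounds half to even)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def class_average(values, decimals: int | None = 4) -> float:
    """Unweighted ("balanced") mean over classes, rounded to the reporting
    precision; ``decimals=None`` returns full precision."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty vector")
    mean = float(values.mean())
    return mean if decimals is None else round_half_away(mean, decimals)


def metric_row(cm: ConfusionMatrix, method_id: int = 0, iba_alpha: float = 0.1) -> pd.Series:
    """All five metrics (per-class and balanced averages) for one method."""
    cen = cen_per_class(cm)
    iba = iba_per_class(cm, iba_alpha)
    gm = gm_per_class(cm)
    mcc = mcc_per_class(cm)
    row: dict[str, float] = {"method_id": method_id, "rci": rci(cm)}
    for name, vec in (("cen", cen), ("iba", iba), ("gm", gm), ("mcc", mcc)):
        for cls, val in zip(cm.class_names, vec):
            row[f"{name}_{cls.lower()}"] = float(val)
    for name, vec in (("cen", cen), ("iba", iba), ("gm", gm), ("mcc", mcc)):
        row[f"avg_{name}"] = class_average(vec, decimals=None)
    return pd.Series(row)
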