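"""Segmentation agreement and paired-measurement statistics.

Dice and AUC quantify agreement between predicted probability maps and
binary annotations; :func:`agreement_stats` bundles the paired statistics
used for derived choroidal metrics (Pearson/Spearman correlation, mean
and median absolute error, ICC(2,1), Bland-Altman limits of agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import UndefinedMetricError

__all__ = ["AgreementReport", "dice_score", "auc_score", "agreement_stats",
           "icc_2_1"]


@dataclass
class AgreementReport:
    pearson: float
    spearman: float
    mae: float
    median_ae: float
    icc: float
    bland_altman: tuple[float, float, float]  # mean diff, lower, upper limit

    def __post_init__(self) -> None:
        _, lo, hi = self.bland_altman
        if not (np.isnan(lo) or np.isnan(hi)) and lo > hi:
            raise ValueError("Bland-Altman limits must be ordered")


def _binarize(arr: np.ndarray, threshold: float) -> np.ndarray:
    return np.asarray(arr, dtype=np.float64) > threshold


def dice_score(pred: np.ndarray, gt: np.ndarray, threshold: float = 0.5) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN) after binarizing at ``threshold``.

    Defined as 1.0 when both masks are empty (perfect agreement on the
    absence of structure).
    """
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    pb, gb = _binarize(p, threshold), _binarize(g, threshold)
    denom = pb.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pb, gb).sum() / denom)


def auc_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Pixelwise area under the ROC curve (rank-based, midrank ties)."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    g = _binarize(gt, 0.5).ravel()
    if g.all() or not g.any():
        raise UndefinedMetricError("AUC undefined: ground truth is single-class")
    return float(roc_auc_score(g, p))


def icc_2_1(x: np.ndarray, y: np.ndarray) -> float:
    """Intraclass correlation, two-way random effects, absolute agreement,
    single measurement — ICC(2,1) — for two raters.

    Computed from the two-way ANOVA mean squares:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with k = 2.
    """
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return np.nan
    return float((msr - mse) / denom)


def agreement_stats(x: np.ndarray, y: np.ndarray) -> AgreementReport:
    """Agreement between two paired series of the same quantity.

    With zero variance in either series the correlation-type fields
    (Pearson, Spearman, ICC) are NaN; absolute errors and Bland-Altman
    limits are always reported. Bland-Altman limits are
    ``mean(d) +/- 1.96 sd(d)`` with the sample (ddof=1) standard
    deviation of the differences ``d = y - x``.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")

    diffs = ya - xa
    mae = float(np.mean(np.abs(diffs)))
    median_ae = float(np.median(np.abs(diffs)))
    md = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    ba = (md, md - 1.96 * sd, md + 1.96 * sd)

    if np.std(xa) == 0 or np.std(ya) == 0:
        return AgreementReport(np.nan, np.nan, mae, median_ae, np.nan, ba)

    pearson = float(stats.pearsonr(xa, ya).statistic)
    spearman = float(stats.spearmanr(xa, ya).statistic)
    return AgreementReport(pearson, spearman, mae, median_ae, icc_2_1(xa, ya), ba)
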