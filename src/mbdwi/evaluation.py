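"""ROC analysis, paired classifier comparison and image-quality metrics.

AUC is the midrank Mann-Whitney statistic normalized by n1*n0 (the
probability that a random malignant case scores above a random benign
case, ties counted half).  Confidence intervals come from a stratified
bootstrap (resampling within each class); operating points are chosen at
the Youden-index maximum; paired method comparisons dichotomize each
method's scores at its own Youden threshold and apply McNemar's test on
the discordant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "roc_auc",
    "auc_ci",
    "roc_curve_points",
    "youden_threshold",
    "operating_point",
    "mcnemar_paired",
    "bonferroni_alpha",
    "image_quality",
    "evaluate_scores",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "malignant").astype(int)
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via midranks (ties get half credit)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_many(scores: np.ndarray, n1: int) -> np.ndarray:
    """Row-wise AUC of (B, n) score matrices whose first n1 columns are the
    positive class."""
    r = rankdata(scores, axis=1)
    n0 = scores.shape[1] - n1
    return (r[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_ci(scores, labels, level: float = 0.95, n_boot: int = 2000,
           seed: int = 0) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC.

    Resamples subjects within each class, so every replicate keeps the
    class balance; the interval is widened if needed to contain the point
    estimate (percentile intervals can sit on one side for degenerate
    separations).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if min(len(pos), len(neg)) < 5:
        import warnings

        warnings.warn("fewer than 5 subjects in a class; the bootstrap "
                      "interval is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    bp = pos[rng.integers(0, len(pos), (n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), (n_boot, len(neg)))]
    aucs = _auc_many(np.concatenate([bp, bn], axis=1), len(pos))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    point = roc_auc(s, y)
    return float(min(lo, point)), float(max(hi, point))


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) over all score cutpoints."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last index of each distinct score (standard ROC convention)
    distinct = np.r_[np.flatnonzero(np.diff(s[order])), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / y.sum()]
    fpr = np.r_[0.0, fps[distinct] / (len(y) - y.sum())]
    thr = np.r_[np.inf, s[order][distinct]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_threshold(scores, labels) -> float:
    """Score cutpoint maximizing sensitivity + specificity - 1."""
    curve = roc_curve_points(scores, labels)
    j = curve.tpr - curve.fpr
    return float(curve.threshold.iloc[int(np.argmax(j.to_numpy()))])


def operating_point(scores, labels) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV at the Youden-optimal threshold."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    thr = youden_threshold(s, y)
    pred = (s >= thr).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "threshold": thr,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def mcnemar_paired(preds_a, preds_b, labels,
                   exact_limit: int = 25) -> float:
    """McNemar's test on two methods' paired classifications.

    Uses the exact binomial test on the discordant counts when there are at
    most ``exact_limit`` discordant pairs, and the continuity-corrected
    chi-square statistic above that.  Zero discordant pairs give P = 1.
    """
    a = np.asarray(preds_a).astype(int)
    b = np.asarray(preds_b).astype(int)
    y = _as_binary(labels)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("prediction vectors must be aligned with labels")
    a_ok = a == y
    b_ok = b == y
    n01 = int((a_ok & ~b_ok).sum())
    n10 = int((~a_ok & b_ok).sum())
    if n01 + n10 == 0:
        return 1.0
    table = [[int((a_ok & b_ok).sum()), n01],
             [n10, int((~a_ok & ~b_ok).sum())]]
    exact = (n01 + n10) <= exact_limit
    res = _sm_mcnemar(np.asarray(table), exact=exact, correction=True)
    return float(res.pvalue)


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def image_quality(volume_3d, lesion_mask, background_mask) -> dict[str, float]:
    """SNR, CNR and lesion contrast of one 3D volume.

    SNR = mean lesion / SD background, CNR = (mean lesion - mean
    background) / SD background, contrast = mean lesion / mean background.
    The background region must not overlap the lesion and must have
    nonzero SD (a noiseless volume has no defined SNR).
    """
    vol = np.asarray(volume_3d, dtype=float)
    les = np.asarray(lesion_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if (les & bg).any():
        raise ValueError("lesion and background regions overlap")
    if not les.any() or not bg.any():
        raise ValueError("lesion and background regions must be non-empty")
    ml = float(vol[les].mean())
    mb = float(vol[bg].mean())
    sb = float(vol[bg].std())
    if sb == 0:
        raise ValueError("background SD is zero; SNR undefined")
    return {
        "snr": ml / sb,
        "cnr": (ml - mb) / sb,
        "contrast": ml / mb if mb != 0 else float("inf"),
    }


@dataclass
class MethodEval:
    """One method's test-set evaluation row."""

    image_set: str
    method: str
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def evaluate_scores(scores, labels, image_set: str, method: str,
                    n_boot: int = 2000, seed: int = 0) -> MethodEval:
    """Full single-method evaluation: AUC, bootstrap CI, operating point."""
    auc = roc_auc(scores, labels)
    lo, hi = auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    op = operating_point(scores, labels)
    return MethodEval(image_set, method, auc, lo, hi,
                      op["sensitivity"], op["specificity"],
                      op["ppv"], op["npv"])
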