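"""Segmentation and denoising quality metrics.

Unsupervised segmentations carry arbitrary class indices, so every
pixel-count metric first applies :func:`match_labels` — the permutation of
predicted classes maximizing total pixel agreement (optimal assignment on the
K x K contingency table).  Reported metrics:

* ``accuracy`` — macro-averaged per-class intersection-over-union, in %
  (the stricter of the two common "accuracy" readings; plain pixel accuracy
  is also available as :func:`pixel_accuracy`).
* ``recall``  — macro-averaged per-class TP / (TP + FN), in %.
* ``dice``    — macro-averaged per-class 2|A∩B| / (|A| + |B|), in %; per
  class this equals the harmonic mean of precision and recall.
* ``psnr``    — 10 log10(peak^2 / MSE), dB.
* ``ssim``    — mean local structural similarity over a 7x7 Gaussian window
  (std 1.5), constants K1 = 0.01, K2 = 0.03 on a dynamic range of 255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionCounts",
    "match_labels",
    "apply_permutation",
    "confusion_counts",
    "accuracy",
    "pixel_accuracy",
    "recall",
    "dice",
    "psnr",
    "ssim",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN pixel counts after optimal label matching."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    matching: np.ndarray  # permutation: predicted class k -> true class matching[k]


def _contingency(pred: np.ndarray, truth: np.ndarray, K: int) -> np.ndarray:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("fields must share a lattice")
    table = np.zeros((K, K), dtype=np.int64)
    np.add.at(table, (pred, truth), 1)
    return table


def _infer_K(pred: np.ndarray, truth: np.ndarray, K: int | None) -> int:
    if K is None:
        K = int(max(np.max(pred), np.max(truth))) + 1
    return K


def match_labels(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> np.ndarray:
    """Permutation of predicted classes maximizing total pixel agreement.

    Returns ``perm`` with ``perm[k]`` the true class assigned to predicted
    class ``k`` (a bijection on {0..K-1}, found by the Hungarian algorithm).
    """
    K = _infer_K(pred, truth, K)
    table = _contingency(pred, truth, K)
    row, col = linear_sum_assignment(-table)
    perm = np.empty(K, dtype=np.int64)
    perm[row] = col
    return perm


def apply_permutation(pred: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return np.asarray(perm)[np.asarray(pred)]


def confusion_counts(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> ConfusionCounts:
    K = _infer_K(pred, truth, K)
    perm = match_labels(pred, truth, K)
    matched = apply_permutation(pred, perm)
    table = _contingency(matched, truth, K)
    tp = np.diag(table).copy()
    fp = table.sum(axis=1) - tp  # predicted as class but truth differs
    fn = table.sum(axis=0) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, matching=perm)


def accuracy(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> float:
    """Macro-averaged per-class IoU after label matching, in percent."""
    cc = confusion_counts(pred, truth, K)
    union = cc.tp + cc.fp + cc.fn
    keep = union > 0
    iou = cc.tp[keep] / union[keep]
    return float(100.0 * iou.mean())


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> float:
    """Plain fraction of pixels agreeing after label matching, in percent."""
    cc = confusion_counts(pred, truth, K)
    total = np.asarray(pred).size
    return float(100.0 * cc.tp.sum() / total)


def recall(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> float:
    """Macro-averaged per-class recall TP/(TP+FN) after matching, in percent.

    Classes absent from the truth are excluded from the average.
    """
    cc = confusion_counts(pred, truth, K)
    present = (cc.tp + cc.fn) > 0
    r = cc.tp[present] / (cc.tp + cc.fn)[present]
    return float(100.0 * r.mean())


def dice(pred: np.ndarray, truth: np.ndarray, K: int | None = None) -> float:
    """Macro-averaged DICE 2|A∩B|/(|A|+|B|) after matching, in percent.

    Classes empty in both fields are excluded.
    """
    cc = confusion_counts(pred, truth, K)
    denom = 2 * cc.tp + cc.fp + cc.fn
    keep = denom > 0
    d = 2.0 * cc.tp[keep] / denom[keep]
    return float(100.0 * d.mean())


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB.

    Returns ``inf`` when the images are identical (zero MSE).
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("images must share a lattice")
    mse = float(((reference - test) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def _ssim_window(size: int = 7, std: float = 1.5) -> np.ndarray:
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * std**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    peak: float = 255.0,
    window_size: int = 7,
    window_std: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Mean local structural similarity index, in [-1, 1]; 1 iff identical.

    Local means, variances and covariance are taken under a Gaussian window
    and combined as ((2 mu_x mu_y + C1)(2 cov + C2)) /
    ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2)) with C1 = (K1 L)^2,
    C2 = (K2 L)^2 on dynamic range L.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must share a lattice")
    if min(x.shape) < window_size:
        raise ValueError(f"image smaller than the {window_size}x{window_size} window")
    w = _ssim_window(window_size, window_std)
    C1 = (K1 * peak) ** 2
    C2 = (K2 * peak) ** 2

    def f(img):
        return ndimage.correlate(img, w, mode="reflect")

    mu_x = f(x)
    mu_y = f(y)
    var_x = f(x * x) - mu_x**2
    var_y = f(y * y) - mu_y**2
    cov = f(x * y) - mu_x * mu_y
    s = ((2 * mu_x * mu_y + C1) * (2 * cov + C2)) / (
        (mu_x**2 + mu_y**2 + C1) * (var_x + var_y + C2)
    )
    return float(s.mean())
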