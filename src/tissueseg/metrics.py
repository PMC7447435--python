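"""Quantitative evaluation of instance segmentations and boundary maps.

Partition-comparison scores (adjusted Rand error, variation of information)
are computed from the joint contingency table of the predicted and
ground-truth labelings, with ground-truth label 0 treated as "unlabelled /
ignore" and excluded — real ground truth often leaves parts of the volume
unannotated.  Boundary-map quality is scored voxel-wise with
precision/recall/F1 over thresholds, and raw-image quality with PSNR and
SSIM.

Conventions that matter when comparing numbers across tools:

* VOI uses the **natural logarithm**; values scale with the log base.
* ARand error is ``1 - AdjustedRandIndex`` (chance-corrected pair counting),
  0 for identical partitions, ~1 for unrelated ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from skimage.metrics import structural_similarity

__all__ = [
    "contingency",
    "arand_error",
    "voi",
    "boundary_pr_curve",
    "boundary_f1",
    "psnr",
    "ssim",
]


def contingency(seg: np.ndarray, gt: np.ndarray) -> sparse.csr_matrix:
    """Joint voxel-count histogram of (segmentation label, ground-truth label).

    Voxels with ground-truth label 0 are excluded.  Returns a sparse matrix
    ``C`` where ``C[i, j]`` counts voxels with segmentation label ``i`` and
    ground-truth label ``j`` (labels index rows/columns directly).
    """
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: seg {seg.shape} vs gt {gt.shape}")
    keep = gt.ravel() != 0
    s = seg.ravel()[keep].astype(np.int64)
    g = gt.ravel()[keep].astype(np.int64)
    if s.size == 0:
        warnings.warn("ground truth contains no labelled voxels; contingency table is empty")
        return sparse.csr_matrix((1, 1), dtype=np.int64)
    data = np.ones(s.size, dtype=np.int64)
    table = sparse.coo_matrix((data, (s, g)), shape=(int(s.max()) + 1, int(g.max()) + 1))
    return table.tocsr()


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def arand_error(seg: np.ndarray, gt: np.ndarray) -> float:
    """Adjusted Rand error, ``1 - AdjRand``, between two labelings.

    AdjRand is the pair-counting Rand index corrected for chance under the
    permutation model.  0 means the segmentation is identical to the ground
    truth (up to label permutation); values near 1 mean no correlation.
    Ground-truth label 0 is ignored.
    """
    table = contingency(seg, gt)
    n = table.sum()
    if n == 0:
        raise ValueError("cannot compute ARand error: no labelled voxels")
    nij = table.data.astype(np.float64)
    a = np.asarray(table.sum(axis=1)).ravel()  # per-seg-label counts
    b = np.asarray(table.sum(axis=0)).ravel()  # per-gt-label counts
    sum_ij = _comb2(nij).sum()
    sum_a = _comb2(a).sum()
    sum_b = _comb2(b).sum()
    total = _comb2(np.float64(n))
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions are single clusters (or singletons): identical ⇒ 0
        return 0.0
    return float(1.0 - (sum_ij - expected) / (max_index - expected))


def voi(seg: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Variation-of-information halves ``(voi_split, voi_merge)``.

    ``voi_split = H(seg | gt)`` quantifies over-segmentation (one true cell
    split across several predicted ones); ``voi_merge = H(gt | seg)``
    quantifies under-segmentation.  Natural-log conditional entropies from
    the contingency table; ground-truth label 0 is ignored.  Identical
    labelings give (0, 0).
    """
    table = contingency(seg, gt)
    n = table.sum()
    if n == 0:
        raise ValueError("cannot compute VOI: no labelled voxels")
    p_ij = table.data.astype(np.float64) / n
    a = np.asarray(table.sum(axis=1)).ravel() / n  # marginal over seg labels
    b = np.asarray(table.sum(axis=0)).ravel() / n  # marginal over gt labels
    h_joint = -np.sum(p_ij * np.log(p_ij))
    h_seg = -np.sum(a[a > 0] * np.log(a[a > 0]))
    h_gt = -np.sum(b[b > 0] * np.log(b[b > 0]))
    voi_split = max(h_joint - h_gt, 0.0)  # H(seg|gt)
    voi_merge = max(h_joint - h_seg, 0.0)  # H(gt|seg)
    return float(voi_split), float(voi_merge)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def boundary_pr_curve(
    pred: np.ndarray,
    gt_boundary: np.ndarray,
    thresholds: "list[float] | np.ndarray" = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
) -> pd.DataFrame:
    """Voxel-wise precision/recall/F1 of a boundary-probability map.

    At each threshold ``t`` the prediction ``pred > t`` is compared with the
    binary ground-truth boundary mask: precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 their harmonic mean (0 when both are 0).
    Matching is strictly voxel-wise (no spatial tolerance); dilate
    ``gt_boundary`` beforehand to emulate a tolerance band.

    Returns a DataFrame with columns threshold/precision/recall/f1.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt_boundary = np.asarray(gt_boundary)
    if pred.shape != gt_boundary.shape:
        raise ValueError("pred and gt_boundary shapes differ")
    uniq = np.unique(gt_boundary)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("gt_boundary must be binary (values 0/1)")
    gt = gt_boundary.astype(bool)
    rows = []
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValueError("thresholds must lie strictly inside (0, 1)")
        pos = pred > t
        tp = int(np.count_nonzero(pos & gt))
        fp = int(np.count_nonzero(pos & ~gt))
        fn = int(np.count_nonzero(~pos & gt))
        precision, recall, f1 = _prf(tp, fp, fn)
        rows.append((float(t), precision, recall, f1))
    return pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1"])


def boundary_f1(pred: np.ndarray, gt_boundary: np.ndarray, threshold: float = 0.5) -> float:
    """F1 of ``pred > threshold`` against a binary boundary mask."""
    return float(boundary_pr_curve(pred, gt_boundary, [threshold])["f1"].iloc[0])


def psnr(image: np.ndarray, reference: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: ``10·log10(data_range² / MSE)``.

    Identical images give ``+inf``.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((image - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def ssim(
    image: np.ndarray,
    reference: np.ndarray,
    window: int = 7,
    data_range: float = 1.0,
) -> float:
    """Mean structural similarity with uniform sliding windows.

    Standard constants ``C1=(0.01·L)²``, ``C2=(0.03·L)²`` with ``L`` the
    data range; window size 7 per axis by default.  1.0 for identical
    images.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    if min(image.shape) < window:
        raise ValueError(f"volume smaller than the {window}-voxel SSIM window")
    return float(
        structural_similarity(
            image,
            reference,
            win_size=window,
            data_range=data_range,
            gaussian_weights=False,
        )
    )
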