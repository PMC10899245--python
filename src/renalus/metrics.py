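"""Segmentation-quality metrics, the ellipsoid volume formula, and the
biomarker agreement evaluator.

Overlap metrics are the usual Dice and Jaccard coefficients; surface
metrics (MAD, HD, SSD) are contour-to-contour nearest-neighbour
distances scaled by the pixel spacing.  Kidney volume uses the ellipsoid
approximation ``V = KL * KW * KT * 0.523`` with lengths in mm and the
result converted to ml (0.523 is the pi/6 prolate-ellipsoid coefficient).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .sagittal import contour_pixels
from .types import as_mask

ELLIPSOID_COEFFICIENT = 0.523


@dataclass
class SegMetrics:
    """Per-case segmentation scores (overlap unitless, distances in mm)."""

    dsc: float
    jc: float
    mad_mm: float
    hd_mm: float
    ssd_mm: float


@dataclass
class AgreementMetrics:
    """Classification-style agreement between predicted and reference biomarkers."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    tolerance_used: float


def kidney_volume(kl_mm: float, kw_mm: float, kt_mm: float) -> float:
    """Ellipsoid kidney volume in ml from the three axis lengths in mm."""
    for name, v in (("kl_mm", kl_mm), ("kw_mm", kw_mm), ("kt_mm", kt_mm)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return kl_mm * kw_mm * kt_mm * ELLIPSOID_COEFFICIENT / 1000.0


def overlap_metrics(pred: np.ndarray, ref: np.ndarray) -> Tuple[float, float]:
    """Dice and Jaccard coefficients of two binary masks."""
    p = as_mask(pred)
    r = as_mask(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    inter = np.count_nonzero(p & r)
    a, b = np.count_nonzero(p), np.count_nonzero(r)
    if a + b == 0:
        _warnings.warn("both masks empty; overlap defined as 1.0")
        return 1.0, 1.0
    dsc = 2.0 * inter / (a + b)
    jc = inter / (a + b - inter)
    return float(dsc), float(jc)


def surface_metrics(pred: np.ndarray, ref: np.ndarray, spacing_mm_per_px: float = 1.0) -> Tuple[float, float, float]:
    """(MAD, HD, SSD) between the contours of two masks, in mm.

    MAD averages the two directed mean nearest distances, HD is the
    classic symmetric Hausdorff maximum, and SSD pools every nearest
    distance from both directions before averaging.
    """
    cp = contour_pixels(pred).astype(float)
    cr = contour_pixels(ref).astype(float)
    d_pr = cKDTree(cr).query(cp)[0]
    d_rp = cKDTree(cp).query(cr)[0]
    mad = 0.5 * (d_pr.mean() + d_rp.mean())
    hd = max(d_pr.max(), d_rp.max())
    ssd = (d_pr.sum() + d_rp.sum()) / (len(d_pr) + len(d_rp))
    s = spacing_mm_per_px
    return float(mad * s), float(hd * s), float(ssd * s)


def _confusion(pred_labels: np.ndarray, ref_labels: np.ndarray):
    tp = int(np.sum(pred_labels & ref_labels))
    tn = int(np.sum(~pred_labels & ~ref_labels))
    fp = int(np.sum(pred_labels & ~ref_labels))
    fn = int(np.sum(~pred_labels & ref_labels))
    return tp, tn, fp, fn


def biomarker_agreement(
    pred: Sequence,
    ref: Sequence,
    field: Optional[str] = None,
    tolerance: float = 0.1,
    ref_labels: Optional[Sequence[bool]] = None,
) -> AgreementMetrics:
    """Agreement of predicted biomarker values with reference values.

    This evaluator is a documented reinterpretation: the source protocol
    never states how continuous dimension agreement was binarised.  Here
    each case scores ``s = 1 - |pred - ref| / ref`` and is called in
    agreement when its relative error is within ``tolerance``.  The
    reference labels default to all-positive (every case is expected to
    agree); an explicit per-case label vector, e.g. an expert's judgement,
    can be supplied instead, in which case AUC sweeps the score against
    those labels.
    """
    if field is not None:
        pred = [getattr(x, field) for x in pred]
        ref = [getattr(x, field) for x in ref]
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("pred and ref must be equal-length 1-D sequences (n >= 2)")
    if np.any(r == 0):
        raise ValueError("reference values must be nonzero")
    err = np.abs(p - r) / np.abs(r)
    score = 1.0 - err
    pred_labels = err <= tolerance
    if ref_labels is None:
        labels = np.ones(len(p), dtype=bool)
    else:
        labels = np.asarray(ref_labels, dtype=bool)
        if labels.shape != p.shape:
            raise ValueError("ref_labels length mismatch")
    tp, tn, fp, fn = _confusion(pred_labels, labels)
    n = len(p)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    if precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    else:
        f1 = float("nan")
    if labels.all() or not labels.any():
        auc = float("nan")
    else:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(labels, score))
    return AgreementMetrics(
        accuracy=float(accuracy),
        auc=auc,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        precision=float(precision),
        f1=float(f1),
        tolerance_used=float(tolerance),
    )
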