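"""Axial-view morphometry: PCA orientation, hilum-aware KT, and KW.

After the capsule mask is rotated so its principal axis is horizontal,
the hilum shows up as a concavity: vertical lines through it cross the
boundary four or more times.  The axial thickness runs from the middle of
the first such line (scanning inward from the hilum side) to the extreme
point on the opposite side; the width is the largest nearest-point
distance between the upper and lower halves of the contour.

A wording note: the source description of the upper/lower nearest-pair
step calls its output "thickness", while the accompanying illustration
labels it KW; KW is adopted here since the hilum caliper already provides
the axial thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .sagittal import TransformRecord, contour_pixels, extract_contour, rotate_to_horizontal  # noqa: F401
from .types import Measurement, Point, as_mask


@dataclass
class OrientationResult:
    """Principal-axis orientation of a binary mask."""

    angle_deg: float
    centroid: Point
    eigenvalue_ratio: float
    warnings: list


def principal_axis_angle(mask: np.ndarray) -> OrientationResult:
    """PCA on foreground pixel coordinates; dominant-axis angle in (-90, 90].

    Near-isotropic shapes (variance ratio < 1.05) get angle 0 by
    convention, with a degeneracy warning.
    """
    m = as_mask(mask)
    pts = np.argwhere(m)
    if len(pts) < 2:
        raise ValueError("principal axis undefined for < 2 foreground pixels")
    centroid = pts.mean(axis=0)
    # y-up coordinates so the angle convention matches the rest of the package
    xy = np.column_stack([pts[:, 1], -pts[:, 0].astype(float)])
    xy = xy - xy.mean(axis=0)
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    ratio = float(evals[1] / max(evals[0], 1e-12))
    warnings = []
    if ratio < 1.05:
        warnings.append("near-isotropic mask: principal axis ill-defined, angle set to 0")
        angle = 0.0
    else:
        vx, vy = evecs[:, 1]
        angle = math.degrees(math.atan2(vy, vx))
        if angle <= -90.0:
            angle += 180.0
        elif angle > 90.0:
            angle -= 180.0
    return OrientationResult(angle, Point(*centroid), ratio, warnings)


def _column_crossings(mask: np.ndarray, col: int) -> np.ndarray:
    """Rows where the boundary crosses the vertical line through ``col``.

    Counts mask run starts and ends, i.e. intersections of the contour
    with the line; a single convex body gives 2, a notched one >= 4.
    """
    column = np.asarray(mask)[:, col].astype(np.int8)
    padded = np.concatenate([[0], column, [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return np.sort(np.concatenate([starts, ends]))


def _first_notch_column(mask: np.ndarray, from_side: str):
    m = as_mask(mask)
    cols = np.nonzero(m.any(axis=0))[0]
    scan = cols if from_side == "left" else cols[::-1]
    for c in scan:
        crossings = _column_crossings(m, c)
        if len(crossings) >= 4:
            return int(c), crossings
    return None, None


def detect_hilum_side(rotated_mask: np.ndarray) -> str:
    """Which side of the horizontal mask carries the hilum concavity.

    Scans columns inward from both ends; the side whose notch signature
    (>= 4 boundary crossings on a vertical line) appears closer to its
    edge wins.
    """
    m = as_mask(rotated_mask)
    cols = np.nonzero(m.any(axis=0))[0]
    left_c, _ = _first_notch_column(m, "left")
    right_c, _ = _first_notch_column(m, "right")
    if left_c is None:
        raise ValueError("no hilum signature; pass --hilum-side explicitly")
    d_left = left_c - cols[0]
    d_right = cols[-1] - right_c
    return "left" if d_left <= d_right else "right"


def kidney_thickness_axial(rotated_mask: np.ndarray, hilum_side: str, spacing_mm_per_px: float) -> Measurement:
    """Axial KT: middle of the first notch line to the opposite extreme point."""
    m = as_mask(rotated_mask)
    if hilum_side not in ("left", "right"):
        raise ValueError("hilum_side must be 'left' or 'right'")
    c1, crossings = _first_notch_column(m, hilum_side)
    if c1 is None:
        raise ValueError("no hilum signature; pass --hilum-side explicitly")
    r1 = int(round(float(np.mean(crossings))))
    p1 = Point(r1, c1)
    rows, cols = np.nonzero(m)
    extreme_col = cols.max() if hilum_side == "left" else cols.min()
    tie_rows = np.sort(rows[cols == extreme_col])
    p2 = Point(int(tie_rows[len(tie_rows) // 2]), int(extreme_col))
    return Measurement("KT_axial", p1, p2, spacing_mm_per_px)


def split_upper_lower(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Separate the contour into its upper and lower parts.

    The upper part is the per-column topmost contour pixel, the lower
    part the per-column bottommost — the outer envelopes of the shape.
    Splitting this way (rather than cutting the traced ring at the
    left/rightmost points) keeps hilum-notch wall pixels out of both
    parts, so the width caliper is not distracted by the concavity.
    """
    m = as_mask(mask)
    rows, cols = np.nonzero(m)
    upper, lower = [], []
    for c in np.unique(cols):
        rr = rows[cols == c]
        upper.append((rr.min(), c))
        lower.append((rr.max(), c))
    return np.array(upper), np.array(lower)


def kidney_width(rotated_mask: np.ndarray, spacing_mm_per_px: float) -> Measurement:
    """KW: largest nearest-point distance from the upper to the lower contour."""
    m = as_mask(rotated_mask)
    rows = np.nonzero(m)[0]
    if rows.max() == rows.min():
        pts = contour_pixels(m)
        p = Point(*map(float, pts[0]))
        return Measurement("KW", p, p, spacing_mm_per_px, ["degenerate single-row mask, width 0"])
    upper, lower = split_upper_lower(m)
    d, idx = cKDTree(lower.astype(float)).query(upper.astype(float))
    i = int(np.argmax(d))
    return Measurement(
        "KW",
        Point(*map(float, upper[i])),
        Point(*map(float, lower[idx[i]])),
        spacing_mm_per_px,
    )


def inverse_rotate_points(points: Sequence[Point], record: TransformRecord) -> List[Point]:
    """Map points measured in the rotated frame back to the original frame."""
    if record is None:
        raise ValueError("a TransformRecord from rotate_to_horizontal is required")
    return record.invert_points(points)
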