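"""Sagittal-view morphometry: KL, tailored crop, rotation, KT, parenchyma.

The chain mirrors how a sonographer measures a longitudinal kidney scan:
find the two poles (farthest contour point pair), crop around that axis,
rotate the kidney horizontal, drop a vertical caliper for the thickness,
and measure the parenchyma as the widest gap between the upper capsule
boundary and the sinus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from skimage.transform import EuclideanTransform, warp

from .types import Measurement, Point, as_mask, axis_angle_deg

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def contour_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour, (n, 2)."""
    m = as_mask(mask)
    if not m.any():
        raise ValueError("empty segmentation")
    boundary = m & ~binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(boundary)


def extract_contour(mask: np.ndarray) -> List[Point]:
    """Contour pixels ordered by tracing along the boundary.

    Pixels are chained greedily through their 8-neighbourhoods starting
    from the topmost-leftmost boundary pixel; disjoint rings (e.g. the
    sinus of a donut-shaped mask) are appended ring by ring.
    """
    pts = contour_pixels(mask)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    remaining = {tuple(p) for p in map(tuple, pts)}
    ordered: List[Tuple[int, int]] = []
    tree = cKDTree(pts)
    cur = tuple(pts[0])
    while remaining:
        if cur not in remaining:
            # jump to the nearest unvisited pixel (next ring or chain break)
            rest = np.array(sorted(remaining))
            i = cKDTree(rest).query(np.array(ordered[-1]))[1] if ordered else 0
            cur = tuple(rest[i])
        remaining.discard(cur)
        ordered.append(cur)
        nxt = None
        for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)):
            cand = (cur[0] + dr, cur[1] + dc)
            if cand in remaining:
                nxt = cand
                break
        cur = nxt if nxt is not None else (-10**9, -10**9)
    del tree
    return [Point(r, c) for r, c in ordered]


def farthest_pair(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Exhaustive search for the farthest point pair (the KL 'grid search')."""
    n = len(points)
    best = (points[0], points[0], 0.0)
    block = 2048
    for i0 in range(0, n, block):
        chunk = points[i0 : i0 + block]
        d2 = np.sum((chunk[:, None, :].astype(float) - points[None, :, :]) ** 2, axis=-1)
        j = np.unravel_index(np.argmax(d2), d2.shape)
        if d2[j] > best[2] ** 2:
            best = (chunk[j[0]], points[j[1]], math.sqrt(d2[j]))
    return best


def kidney_length(capsule: np.ndarray, spacing_mm_per_px: float) -> Measurement:
    """Kidney length: the farthest pair of capsule contour points."""
    pts = contour_pixels(capsule)
    warnings = []
    if len(pts) == 1:
        warnings.append("degenerate mask: single pixel, length 0")
        p = Point(*map(float, pts[0]))
        return Measurement("KL", p, p, spacing_mm_per_px, warnings)
    p1, p2, _ = farthest_pair(pts)
    return Measurement(
        "KL", Point(*map(float, p1)), Point(*map(float, p2)), spacing_mm_per_px, warnings
    )


def tailored_crop(image: np.ndarray, kl: Measurement, margin: float = 0.1):
    """Square crop enclosing the KL endpoints plus a relative margin.

    Returns ``(cropped, (row_offset, col_offset))``; adding the offset to
    cropped coordinates recovers original-frame coordinates.  Crops that
    overrun the image are zero-padded so the output stays square.
    """
    img = np.asarray(image)
    L = kl.length_px
    if L <= 0:
        raise ValueError("zero-length KL cannot define a crop")
    pad = margin * L
    r_lo = min(kl.p1.row, kl.p2.row) - pad
    r_hi = max(kl.p1.row, kl.p2.row) + pad
    c_lo = min(kl.p1.col, kl.p2.col) - pad
    c_hi = max(kl.p1.col, kl.p2.col) + pad
    side = int(math.ceil(max(r_hi - r_lo, c_hi - c_lo))) + 1
    r0 = int(round((r_lo + r_hi) / 2 - side / 2))
    c0 = int(round((c_lo + c_hi) / 2 - side / 2))
    out = np.zeros((side, side), dtype=img.dtype)
    rs, re = max(r0, 0), min(r0 + side, img.shape[0])
    cs, ce = max(c0, 0), min(c0 + side, img.shape[1])
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
    return out, (r0, c0)


@dataclass
class TransformRecord:
    """Affine record of a padding rotation; maps original -> rotated coords."""

    transform: EuclideanTransform
    input_shape: Tuple[int, int]
    output_shape: Tuple[int, int]
    angle_deg: float

    def apply_points(self, points) -> List[Point]:
        arr = np.array([[p.col, p.row] for p in points], dtype=float)
        xy = self.transform(arr)
        return [Point(row=y, col=x) for x, y in xy]

    def invert_points(self, points) -> List[Point]:
        arr = np.array([[p.col, p.row] for p in points], dtype=float)
        xy = self.transform.inverse(arr)
        return [Point(row=y, col=x) for x, y in xy]


def rotate_to_horizontal(array: np.ndarray, angle_deg: float, center: Optional[Tuple[float, float]] = None):
    """Rotate content so an axis at ``angle_deg`` becomes horizontal.

    The canvas is enlarged so nothing is clipped.  Masks (bool / integer)
    use nearest-neighbour interpolation, float images bilinear.  Returns
    ``(rotated, TransformRecord)``; the record maps original (row, col)
    points into the rotated frame and back exactly.
    """
    arr = np.asarray(array)
    rows, cols = arr.shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    cr, cc = center
    # screen coords (x=col, y=row, y down): making a +angle axis horizontal
    # is a rotation by +angle in the y-down sense.
    theta = math.radians(angle_deg)
    rot = EuclideanTransform(rotation=theta)
    shift_in = EuclideanTransform(translation=(-cc, -cr))
    corners = np.array([[0, 0], [cols - 1, 0], [0, rows - 1], [cols - 1, rows - 1]], float)
    moved = (shift_in + rot)(corners)
    min_x, min_y = moved.min(axis=0)
    max_x, max_y = moved.max(axis=0)
    out_shape = (int(math.ceil(max_y - min_y)) + 1, int(math.ceil(max_x - min_x)) + 1)
    full = shift_in + rot + EuclideanTransform(translation=(-min_x, -min_y))
    is_mask = arr.dtype == bool or np.issubdtype(arr.dtype, np.integer)
    rotated = warp(
        arr.astype(float),
        inverse_map=full.inverse,
        output_shape=out_shape,
        order=0 if is_mask else 1,
        preserve_range=True,
    )
    if arr.dtype == bool:
        rotated = rotated > 0.5
    elif np.issubdtype(arr.dtype, np.integer):
        rotated = np.round(rotated).astype(arr.dtype)
    record = TransformRecord(full, (rows, cols), out_shape, angle_deg)
    return rotated, record


def kidney_thickness_sagittal(rotated_capsule: np.ndarray, spacing_mm_per_px: float) -> Measurement:
    """Vertical caliper: topmost pixel down to the bottom pixel in its column."""
    m = as_mask(rotated_capsule)
    if not m.any():
        raise ValueError("empty segmentation")
    rows, cols = np.nonzero(m)
    r_top = int(rows.min())
    # the topmost row is typically a flat run; its median column centres
    # the caliper like the manual measurement does
    run = np.sort(cols[rows == r_top])
    c_top = int(run[len(run) // 2])
    col_rows = rows[cols == c_top]
    r_bot = int(col_rows.max())
    warnings = []
    if r_bot == r_top:
        warnings.append("degenerate mask: single-row column, thickness 0")
    return Measurement(
        "KT", Point(r_top, c_top), Point(r_bot, c_top), spacing_mm_per_px, warnings
    )


def upper_contour(mask: np.ndarray) -> np.ndarray:
    """Per-column minimum-row foreground pixel of the mask, (n, 2)."""
    m = as_mask(mask)
    rows, cols = np.nonzero(m)
    out = []
    for c in np.unique(cols):
        out.append((rows[cols == c].min(), c))
    return np.array(out)


def parenchymal_thickness(capsule: np.ndarray, sinus: np.ndarray, spacing_mm_per_px: float, strategy: str = "maxmin") -> Measurement:
    """Parenchymal thickness between the upper capsule contour and the sinus.

    ``maxmin`` (default): for every upper-contour point take its nearest
    sinus-contour point and keep the pair with the largest such distance —
    the thickest stretch of parenchyma.  ``maxmax`` keeps the literal
    farthest pair between the two contours.
    """
    cap = as_mask(capsule)
    sin = as_mask(sinus)
    if not sin.any():
        raise ValueError("sinus segmentation required")
    warnings = []
    if (sin & ~cap).any():
        warnings.append("sinus extends outside capsule; result may be unreliable")
    up = upper_contour(cap).astype(float)
    sin_contour = contour_pixels(sin).astype(float)
    if strategy == "maxmin":
        d, idx = cKDTree(sin_contour).query(up)
        i = int(np.argmax(d))
        p1, p2 = up[i], sin_contour[idx[i]]
    elif strategy == "maxmax":
        d2 = np.sum((up[:, None, :] - sin_contour[None, :, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        p1, p2 = up[i], sin_contour[j]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Measurement(
        "parenchyma", Point(*p1), Point(*p2), spacing_mm_per_px, warnings
    )


def kl_axis_angle(kl: Measurement) -> float:
    """Orientation of the measured KL axis, degrees from horizontal."""
    return axis_angle_deg(kl.p1, kl.p2)
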