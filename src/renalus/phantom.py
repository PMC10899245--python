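"""Synthetic kidney ultrasound phantoms with analytic biomarker ground truth.

The generator emulates the geometry that the measurement pipeline relies
on rather than ultrasound physics: a bean/ellipse capsule with an enclosed
brighter sinus on the sagittal view, an ellipse with a concave hilum notch
on the axial view, and multiplicative speckle-like grain on top of a smooth
tissue template.  Every biomarker (KL, KT, KW, parenchymal thickness) is
computed from the *continuous* generating curves, independent of the
rasterisation, so measurement code can be validated against it to pixel
tolerance.

Geometry conventions
--------------------
Shapes live in a y-up frame centred on the image centre; ``rotation_deg``
tilts the major axis counterclockwise (screen-up positive).  The hilum
notch is a disc of radius ``hilum_notch_depth * semi_minor`` subtracted at
the medial vertex of the axial ellipse, which produces the >= 4
boundary-intersection signature on vertical lines that the axial
measurement keys on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .types import ScanImage

_BOUNDARY_SAMPLES = 512


@dataclass
class PhantomParams:
    """Generating parameters for one phantom view.

    ``capsule_semi_major_px`` / ``capsule_semi_minor_px`` are the ellipse
    semi-axes in pixels; the sinus is the capsule scaled by ``sinus_scale``
    about the centroid.  ``hilum_notch_depth`` (axial only) is the notch
    disc radius as a fraction of the semi-minor axis.
    """

    capsule_semi_major_px: float = 150.0
    capsule_semi_minor_px: float = 60.0
    rotation_deg: float = 0.0
    sinus_scale: float = 0.5
    hilum_notch_depth: float = 0.4
    spacing_mm_per_px: float = 0.3
    speckle_sigma: float = 0.3
    image_shape: Tuple[int, int] = (320, 480)
    seed: int = 0
    bean_amp: float = 0.0
    hilum_side: str = "left"
    speckle_grain_px: float = 2.0

    def validate(self, view: str) -> None:
        a, b = self.capsule_semi_major_px, self.capsule_semi_minor_px
        if not (a > 0 and b > 0 and a >= b):
            raise ValueError("semi-axes must satisfy semi_major >= semi_minor > 0")
        if not (0.0 < self.sinus_scale < 1.0):
            raise ValueError(f"sinus_scale must lie in (0, 1), got {self.sinus_scale}")
        if view == "axial" and not (0.0 < self.hilum_notch_depth < 0.8):
            raise ValueError(
                f"hilum_notch_depth must lie in (0, 0.8), got {self.hilum_notch_depth}"
            )
        if not (0.05 <= self.spacing_mm_per_px <= 1.0):
            raise ValueError("spacing_mm_per_px out of plausible range")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")
        if self.hilum_side not in ("left", "right"):
            raise ValueError("hilum_side must be 'left' or 'right'")
        rows, cols = self.image_shape
        th = math.radians(self.rotation_deg)
        margin = 2.0
        col_ext = a * abs(math.cos(th)) + b * abs(math.sin(th))
        row_ext = a * abs(math.sin(th)) + b * abs(math.cos(th))
        if col_ext > (cols - 1) / 2 - margin:
            raise ValueError(
                f"capsule too large for image cols: extent {col_ext:.1f} px "
                f"exceeds {(cols - 1) / 2 - margin:.1f} px"
            )
        if row_ext > (rows - 1) / 2 - margin:
            raise ValueError(
                f"capsule too large for image rows: extent {row_ext:.1f} px "
                f"exceeds {(rows - 1) / 2 - margin:.1f} px"
            )


@dataclass
class PhantomGroundTruth:
    """Analytic biomarker values for a generated phantom (mm / ml)."""

    kl_mm: Optional[float] = None
    kw_mm: Optional[float] = None
    kt_mm: Optional[float] = None
    parenchyma_mm: Optional[float] = None
    volume_ml: Optional[float] = None
    rotation_deg: float = 0.0

    def with_volume(self) -> "PhantomGroundTruth":
        if None not in (self.kl_mm, self.kw_mm, self.kt_mm):
            vol = self.kl_mm * self.kw_mm * self.kt_mm * 0.523 / 1000.0
            return replace(self, volume_ml=vol)
        return self


# ---------------------------------------------------------------------------
# analytic boundary helpers (continuous curves, y-up shape frame)
# ---------------------------------------------------------------------------


def _ellipse_boundary(a: float, b: float, bean_amp: float, n: int) -> np.ndarray:
    """Sample the (optionally bean-perturbed) capsule boundary, shape (n, 2)."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    rho = 1.0 + bean_amp * np.sin(t)
    return np.column_stack([a * rho * np.cos(t), b * rho * np.sin(t)])


def _max_chord(points: np.ndarray) -> float:
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(math.sqrt(d2.max()))


def _max_min_upper_to_inner(outer: np.ndarray, inner: np.ndarray) -> float:
    """max over upper-half outer points of the min distance to the inner curve."""
    upper = outer[outer[:, 1] >= -1e-9]
    d2 = np.sum((upper[:, None, :] - inner[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min(axis=1)).max())


def _notch_geometry(a: float, b: float, depth: float):
    """Notch disc (centre, radius) and the column where the two prongs meet.

    The disc sits at the medial vertex (-a, 0) with radius depth*b.  The
    mask's left edge is the column x_c where the ellipse half-height first
    exceeds the disc half-height; left of it the disc swallows the whole
    column.  Returns (disc_centre_x, radius, x_c).
    """
    rho = depth * b

    def f(x):
        e2 = b * b * (1.0 - x * x / (a * a))
        h2 = rho * rho - (x + a) ** 2
        return e2 - h2

    x_c = brentq(f, -a, -a + rho, xtol=1e-10)
    return -a, rho, float(x_c)


# ---------------------------------------------------------------------------
# rasterisation and imaging
# ---------------------------------------------------------------------------


def _shape_frame(image_shape, rotation_deg):
    rows, cols = image_shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    x = cc_grid - cc
    y = -(rr - cr)
    th = math.radians(rotation_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    return u, v


def _fill_ellipse(u, v, a, b, bean_amp):
    if bean_amp == 0.0:
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    t = np.arctan2(v / b, u / a)
    rho = 1.0 + bean_amp * np.sin(t)
    return (u / (a * rho)) ** 2 + (v / (b * rho)) ** 2 <= 1.0


def _speckle(shape, sigma, grain_px, rng):
    g = gaussian_filter(rng.standard_normal(shape), grain_px)
    g = (g - g.mean()) / (g.std() + 1e-12)
    return np.clip(1.0 + sigma * g, 0.05, None)


def _render(template: np.ndarray, sigma: float, grain: float, rng) -> np.ndarray:
    img = gaussian_filter(template, 1.5)
    if sigma > 0:
        img = img * _speckle(template.shape, sigma, grain, rng)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_sagittal_phantom(params: PhantomParams):
    """Generate one sagittal phantom.

    Returns ``(image, capsule_mask, sinus_mask, truth)`` where the truth
    carries KL, KT and parenchymal thickness from the continuous geometry:
    KL is the longest chord, KT the vertical extent after rotating the KL
    axis horizontal, and parenchymal thickness the largest
    nearest-distance from the upper capsule boundary to the sinus
    boundary (attained at a pole for concentric ellipses).
    """
    params.validate("sagittal")
    a, b, s = params.capsule_semi_major_px, params.capsule_semi_minor_px, params.sinus_scale
    sp = params.spacing_mm_per_px
    rng = np.random.default_rng(params.seed)

    u, v = _shape_frame(params.image_shape, params.rotation_deg)
    capsule = _fill_ellipse(u, v, a, b, params.bean_amp)
    sinus = _fill_ellipse(u, v, s * a, s * b, params.bean_amp)

    outer = _ellipse_boundary(a, b, params.bean_amp, _BOUNDARY_SAMPLES)
    inner = s * outer
    kl_px = _max_chord(outer)
    kt_px = float(outer[:, 1].max() - outer[:, 1].min())
    par_px = _max_min_upper_to_inner(outer, inner)

    template = np.full(params.image_shape, 0.15, dtype=np.float64)
    template[capsule] = 0.45
    template[sinus] = 0.8
    image = ScanImage(
        _render(template, params.speckle_sigma, params.speckle_grain_px, rng),
        spacing_mm_per_px=sp,
        view="sagittal",
    )
    truth = PhantomGroundTruth(
        kl_mm=kl_px * sp,
        kt_mm=kt_px * sp,
        parenchyma_mm=par_px * sp,
        rotation_deg=params.rotation_deg,
    )
    return image, capsule, sinus, truth


def generate_axial_phantom(params: PhantomParams):
    """Generate one axial phantom: notched ellipse capsule.

    Truth is recorded from the generating geometry: axial KT is the span
    from the notch meeting column to the opposite vertex — exactly what
    the hilum-aware caliper measures — and KW is the continuum
    upper-to-lower max-of-nearest between the boundary envelopes (equal
    to 2 * semi_minor for elongated shapes, slightly below it when the
    notch brings mid-height boundary closer to the top centre).
    """
    params.validate("axial")
    a, b, d = params.capsule_semi_major_px, params.capsule_semi_minor_px, params.hilum_notch_depth
    sp = params.spacing_mm_per_px
    rng = np.random.default_rng(params.seed)

    cx, rho, x_c = _notch_geometry(a, b, d)
    u, v = _shape_frame(params.image_shape, params.rotation_deg)
    if params.hilum_side == "right":
        u = -u
    ellipse = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    notch = (u - cx) ** 2 + v**2 < rho * rho
    capsule = ellipse & ~notch

    # envelopes of the notched shape are the ellipse arcs right of x_c
    xs = np.linspace(x_c, a, 1024)
    e = b * np.sqrt(np.clip(1.0 - xs**2 / (a * a), 0.0, None))
    up = np.column_stack([xs, e])
    lo = np.column_stack([xs, -e])
    d2 = np.sum((up[:, None, :] - lo[None, :, :]) ** 2, axis=-1)
    kw_px = float(np.sqrt(d2.min(axis=1)).max())
    kt_px = a - x_c

    template = np.full(params.image_shape, 0.15, dtype=np.float64)
    template[capsule] = 0.5
    core = (u / (0.5 * a)) ** 2 + (v / (0.5 * b)) ** 2 <= 1.0
    template[capsule & core] = 0.7
    image = ScanImage(
        _render(template, params.speckle_sigma, params.speckle_grain_px, rng),
        spacing_mm_per_px=sp,
        view="axial",
    )
    truth = PhantomGroundTruth(
        kw_mm=kw_px * sp,
        kt_mm=kt_px * sp,
        rotation_deg=params.rotation_deg,
    )
    return image, capsule, truth


def combine_views(sagittal_truth: PhantomGroundTruth, axial_truth: PhantomGroundTruth) -> PhantomGroundTruth:
    """Merge per-view truths into a full biomarker truth with volume.

    KL, KT and parenchymal thickness come from the sagittal view, KW from
    the axial view; the ellipsoid volume uses KL x KW x KT x 0.523.
    """
    return PhantomGroundTruth(
        kl_mm=sagittal_truth.kl_mm,
        kw_mm=axial_truth.kw_mm,
        kt_mm=sagittal_truth.kt_mm,
        parenchyma_mm=sagittal_truth.parenchyma_mm,
        rotation_deg=sagittal_truth.rotation_deg,
    ).with_volume()


def default_param_ranges(image_shape=(320, 480)) -> dict:
    """Sampling ranges emulating adult kidney dimensions at typical spacing.

    At 0.23-0.36 mm/px a 90-120 mm kidney length maps to semi-major axes
    of roughly 120-175 px in a 320x480 frame; smaller frames scale the
    axes proportionally.
    """
    f = min(image_shape[0] / 320.0, image_shape[1] / 480.0)
    return {
        "spacing_mm_per_px": (0.23, 0.36),
        "rotation_deg": (-25.0, 25.0),
        "speckle_sigma": (0.25, 0.35),
        "sinus_scale": (0.45, 0.6),
        "hilum_notch_depth": (0.3, 0.5),
        "sag_semi_major_px": (120.0 * f, 172.0 * f),
        "sag_aspect": (0.36, 0.5),
        "ax_semi_major_px": (95.0 * f, 130.0 * f),
        "ax_aspect": (0.42, 0.52),
    }


def sample_params(rng: np.random.Generator, view: str, image_shape=(320, 480), ranges: Optional[dict] = None) -> PhantomParams:
    """Draw one PhantomParams for ``view`` from uniform ranges."""
    r = dict(default_param_ranges(image_shape))
    if ranges:
        r.update(ranges)

    def u(key):
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    if view == "sagittal":
        a = u("sag_semi_major_px")
        b = a * u("sag_aspect")
    elif view == "axial":
        a = u("ax_semi_major_px")
        b = a * u("ax_aspect")
    else:
        raise ValueError(f"unknown view {view!r}")
    return PhantomParams(
        capsule_semi_major_px=a,
        capsule_semi_minor_px=b,
        rotation_deg=u("rotation_deg"),
        sinus_scale=u("sinus_scale"),
        hilum_notch_depth=u("hilum_notch_depth"),
        spacing_mm_per_px=u("spacing_mm_per_px"),
        speckle_sigma=u("speckle_sigma"),
        image_shape=tuple(image_shape),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _write_png(path: Path, array: np.ndarray, is_mask: bool) -> None:
    from PIL import Image

    if is_mask:
        data = np.where(array, 255, 0).astype(np.uint8)
    else:
        data = np.clip(np.round(array * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data).save(path)


def generate_dataset(n: int, params_ranges: Optional[dict] = None, seed: int = 0, out_dir="phantoms", image_shape=(320, 480), view: str = "both") -> pd.DataFrame:
    """Write ``n`` phantom studies (images + masks as PNG) plus a manifest CSV.

    Each study row records the file stems, spacing, the combined biomarker
    truth and the generating rotation; generation is deterministic under a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (empty dataset refused)")
    if view not in ("both", "sagittal", "axial"):
        raise ValueError(f"view must be 'both', 'sagittal' or 'axial', got {view!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        stem = f"phantom_{i:04d}"
        row = {"stem": stem, "seed": seed}
        sag_truth = ax_truth = None
        if view in ("both", "sagittal"):
            p = sample_params(rng, "sagittal", image_shape, params_ranges)
            img, cap, sin, sag_truth = generate_sagittal_phantom(p)
            _write_png(out / f"{stem}_sag.png", img.pixels, False)
            _write_png(out / f"{stem}_sag_capsule.png", cap, True)
            _write_png(out / f"{stem}_sag_sinus.png", sin, True)
            row["sag_spacing_mm_per_px"] = p.spacing_mm_per_px
            row["rotation_deg"] = p.rotation_deg
        if view in ("both", "axial"):
            p = sample_params(rng, "axial", image_shape, params_ranges)
            img, cap, ax_truth = generate_axial_phantom(p)
            _write_png(out / f"{stem}_ax.png", img.pixels, False)
            _write_png(out / f"{stem}_ax_capsule.png", cap, True)
            row["ax_spacing_mm_per_px"] = p.spacing_mm_per_px
            row.setdefault("rotation_deg", p.rotation_deg)
        if sag_truth is not None and ax_truth is not None:
            truth = combine_views(sag_truth, ax_truth)
        else:
            truth = sag_truth if sag_truth is not None else ax_truth
        row.update(
            spacing_mm_per_px=row.get("sag_spacing_mm_per_px", row.get("ax_spacing_mm_per_px")),
            kl_mm=truth.kl_mm,
            kw_mm=truth.kw_mm,
            kt_mm=truth.kt_mm,
            parenchyma_mm=truth.parenchyma_mm,
            volume_ml=truth.volume_ml,
        )
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
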