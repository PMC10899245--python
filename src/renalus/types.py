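"""Core value types shared across the measurement pipeline.

Pixel coordinates are ``(row, col)`` with row increasing downward.  Angles
are measured from the image horizontal, positive counterclockwise in the
conventional x-right / y-up sense (so a positive angle tilts a shape's
right-hand end *upward* on screen).  All physical lengths are millimetres,
converted from pixels through an isotropic ``spacing_mm_per_px``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

VIEWS = ("sagittal", "axial")


@dataclass(frozen=True)
class Point:
    """A pixel-center location; fractional coordinates are allowed."""

    row: float
    col: float

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.row - other.row, self.col - other.col)

    def as_list(self) -> list:
        return [float(self.row), float(self.col)]


@dataclass
class ScanImage:
    """A 2-D grayscale ultrasound frame with its physical calibration."""

    pixels: np.ndarray
    spacing_mm_per_px: float
    view: str = "sagittal"
    laterality: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ScanImage expects a 2-D grayscale pixel grid")
        if self.spacing_mm_per_px <= 0:
            raise ValueError("spacing_mm_per_px must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class Measurement:
    """A landmark pair and its length in pixels and millimetres."""

    biomarker: str
    p1: Point
    p2: Point
    spacing_mm_per_px: float
    warnings: list = field(default_factory=list)

    @property
    def length_px(self) -> float:
        return self.p1.distance_to(self.p2)

    @property
    def length_mm(self) -> float:
        return self.length_px * self.spacing_mm_per_px

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "p1": self.p1.as_list(),
            "p2": self.p2.as_list(),
            "length_px": float(self.length_px),
            "length_mm": float(self.length_mm),
            "spacing_mm_per_px": float(self.spacing_mm_per_px),
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class BiomarkerSet:
    """The five renal biomarkers for one kidney (mm and ml).

    Any field may be ``None`` when the view needed to measure it was
    unavailable.  ``volume_ml`` follows the ellipsoid formula
    ``KL * KW * KT * 0.523`` (mm^3 -> ml).
    """

    kl_mm: Optional[float] = None
    kw_mm: Optional[float] = None
    kt_mm: Optional[float] = None
    parenchyma_mm: Optional[float] = None
    volume_ml: Optional[float] = None
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kl_mm": self.kl_mm,
            "kw_mm": self.kw_mm,
            "kt_mm": self.kt_mm,
            "parenchyma_mm": self.parenchyma_mm,
            "volume_ml": self.volume_ml,
            "provenance": {k: m.to_dict() for k, m in self.provenance.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a binary boolean mask (any nonzero is foreground)."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError("masks must be 2-D")
    return a.astype(bool)


def axis_angle_deg(p1: Point, p2: Point) -> float:
    """Angle of the line p1-p2 from horizontal, mapped to (-90, 90].

    Positive counterclockwise with rows increasing downward (screen-up is
    positive).
    """
    dcol = p2.col - p1.col
    drow = p2.row - p1.row
    ang = math.degrees(math.atan2(-drow, dcol))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def points_array(points: Sequence[Point]) -> np.ndarray:
    return np.array([[p.row, p.col] for p in points], dtype=float)
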