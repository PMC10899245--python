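"""Readers/writers, configuration and the study-level measurement pipeline.

A *study* is one kidney with a sagittal and/or axial frame plus the
mm/pixel calibration for each.  ``measure_study`` runs segmentation (a
trained model, or reference masks injected in their place), the sagittal
chain (KL, KT, parenchymal thickness), the axial chain (axial KT and KW),
and combines KL and KT from the sagittal view with KW from the axial view
into the ellipsoid volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import axial as ax
from . import sagittal as sag
from .metrics import kidney_volume, overlap_metrics, surface_metrics
from .network import NetworkConfig, TrainConfig, predict_mask
from .types import BiomarkerSet, Measurement, ScanImage

log = logging.getLogger("renalus")


# ---------------------------------------------------------------------------
# image / mask files
# ---------------------------------------------------------------------------


def read_image(path, spacing_mm_per_px: float, view: str = "sagittal") -> ScanImage:
    """Load an 8-bit grayscale PNG/TIFF as a float image in [0, 1]."""
    img = Image.open(path)
    if img.mode not in ("L", "I;16", "I"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float32)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return ScanImage(arr, spacing_mm_per_px=spacing_mm_per_px, view=view)


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# configuration bundle
# ---------------------------------------------------------------------------


@dataclass
class ConfigBundle:
    """Validated network + training configuration with printed defaults."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> "ConfigBundle":
        self.network.validate()
        self.train.validate()
        return self

    def to_dict(self) -> dict:
        return {"network": asdict(self.network), "train": asdict(self.train)}

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)


def load_config(path) -> ConfigBundle:
    """Parse a YAML/JSON config, fill defaults, validate every invariant.

    Unknown keys are rejected with a message listing each offender.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = [k for k in raw if k not in ("network", "train")]
    errors = [f"unknown top-level key: {k!r}" for k in unknown]
    net_kwargs, train_kwargs = dict(raw.get("network") or {}), dict(raw.get("train") or {})
    for section, kwargs, cls in (
        ("network", net_kwargs, NetworkConfig),
        ("train", train_kwargs, TrainConfig),
    ):
        valid = set(cls.__dataclass_fields__)
        for k in list(kwargs):
            if k not in valid:
                errors.append(f"unknown key {section}.{k!r}")
                kwargs.pop(k)
    if errors:
        raise ValueError("; ".join(errors))
    for key in ("filters_per_level", "input_shape"):
        if key in net_kwargs and net_kwargs[key] is not None:
            net_kwargs[key] = tuple(net_kwargs[key])
    bundle = ConfigBundle(NetworkConfig(**net_kwargs), TrainConfig(**train_kwargs))
    bundle.validate()
    log.info("effective config: %s", bundle.to_dict())
    return bundle


# ---------------------------------------------------------------------------
# study measurement
# ---------------------------------------------------------------------------


@dataclass
class StudyRecord:
    """Pointers to one kidney's frames and calibrations.

    ``*_mask`` entries are optional reference segmentations; when a model
    is absent they stand in for its predictions.
    """

    sagittal_image: Optional[str] = None
    axial_image: Optional[str] = None
    sagittal_spacing: Optional[float] = None
    axial_spacing: Optional[float] = None
    laterality: Optional[str] = None
    sagittal_capsule_mask: Optional[str] = None
    sagittal_sinus_mask: Optional[str] = None
    axial_capsule_mask: Optional[str] = None

    def __post_init__(self):
        if self.sagittal_image is None and self.axial_image is None:
            raise ValueError("a study needs at least one view")
        for name, spacing, img in (
            ("sagittal", self.sagittal_spacing, self.sagittal_image),
            ("axial", self.axial_spacing, self.axial_image),
        ):
            if img is not None and (spacing is None or spacing <= 0):
                raise ValueError(f"{name} view requires a positive spacing")


def _segment(image: ScanImage, model, mask_path, view: str, structure: str) -> np.ndarray:
    if model is not None:
        _, mask = predict_mask(model, image)
    elif mask_path is not None:
        mask = read_mask(mask_path)
    else:
        raise ValueError(f"no model and no reference mask for the {view} {structure}")
    if not mask.any():
        raise ValueError(f"empty segmentation for the {view} view")
    return mask


def measure_sagittal(capsule: np.ndarray, sinus: Optional[np.ndarray], spacing: float) -> dict:
    """KL, KT and (if a sinus mask is available) parenchymal thickness."""
    kl = sag.kidney_length(capsule, spacing)
    angle = sag.kl_axis_angle(kl)
    rot_capsule, record = sag.rotate_to_horizontal(capsule, angle)
    kt_rot = sag.kidney_thickness_sagittal(rot_capsule, spacing)
    p1, p2 = record.invert_points([kt_rot.p1, kt_rot.p2])
    kt = Measurement("KT", p1, p2, spacing, kt_rot.warnings)
    out = {"KL": kl, "KT": kt}
    if sinus is not None and sinus.any():
        rot_sinus, _ = sag.rotate_to_horizontal(sinus, angle)
        par_rot = sag.parenchymal_thickness(rot_capsule, rot_sinus, spacing)
        q1, q2 = record.invert_points([par_rot.p1, par_rot.p2])
        out["parenchyma"] = Measurement("parenchyma", q1, q2, spacing, par_rot.warnings)
    return out


def measure_axial(capsule: np.ndarray, spacing: float, hilum_side: Optional[str] = None) -> dict:
    """Axial KT and KW, reported in the original (unrotated) frame."""
    orient = ax.principal_axis_angle(capsule)
    rotated, record = sag.rotate_to_horizontal(capsule, orient.angle_deg)
    side = hilum_side or ax.detect_hilum_side(rotated)
    kt_rot = ax.kidney_thickness_axial(rotated, side, spacing)
    kw_rot = ax.kidney_width(rotated, spacing)
    kt_p = record.invert_points([kt_rot.p1, kt_rot.p2])
    kw_p = record.invert_points([kw_rot.p1, kw_rot.p2])
    return {
        "KT_axial": Measurement("KT_axial", *kt_p, spacing, kt_rot.warnings),
        "KW": Measurement("KW", *kw_p, spacing, kw_rot.warnings),
        "hilum_side": side,
    }


def measure_study(
    record: StudyRecord,
    capsule_model=None,
    sinus_model=None,
    hilum_side: Optional[str] = None,
) -> BiomarkerSet:
    """Full biomarker set for one study.

    Volume needs KL and KT from the sagittal view and KW from the axial
    view; with only one view present the reachable biomarkers are
    computed and the rest stay ``None`` with a warning.
    """
    bset = BiomarkerSet()
    if record.sagittal_image is not None:
        image = read_image(record.sagittal_image, record.sagittal_spacing, "sagittal")
        capsule = _segment(image, capsule_model, record.sagittal_capsule_mask,
                           "sagittal", "capsule")
        sinus = None
        if sinus_model is not None or record.sagittal_sinus_mask is not None:
            sinus = _segment(image, sinus_model, record.sagittal_sinus_mask,
                             "sagittal", "sinus")
        meas = measure_sagittal(capsule, sinus, record.sagittal_spacing)
        bset.kl_mm = meas["KL"].length_mm
        bset.kt_mm = meas["KT"].length_mm
        bset.provenance["KL"] = meas["KL"]
        bset.provenance["KT"] = meas["KT"]
        if "parenchyma" in meas:
            bset.parenchyma_mm = meas["parenchyma"].length_mm
            bset.provenance["parenchyma"] = meas["parenchyma"]
        else:
            bset.warnings.append("no sinus segmentation: parenchymal thickness skipped")
    if record.axial_image is not None:
        image = read_image(record.axial_image, record.axial_spacing, "axial")
        capsule = _segment(image, capsule_model, record.axial_capsule_mask,
                           "axial", "capsule")
        meas = measure_axial(capsule, record.axial_spacing, hilum_side)
        bset.kw_mm = meas["KW"].length_mm
        bset.provenance["KW"] = meas["KW"]
        bset.provenance["KT_axial"] = meas["KT_axial"]
    else:
        bset.warnings.append("no axial view: KW and volume unavailable")
    if None not in (bset.kl_mm, bset.kw_mm, bset.kt_mm):
        bset.volume_ml = kidney_volume(bset.kl_mm, bset.kw_mm, bset.kt_mm)
    elif bset.volume_ml is None and "volume" not in " ".join(bset.warnings):
        bset.warnings.append("volume requires KL, KT (sagittal) and KW (axial)")
    return bset


# ---------------------------------------------------------------------------
# segmentation evaluation over directories
# ---------------------------------------------------------------------------


def evaluate_segmentation(pred_dir, ref_dir, spacing_mm_per_px: float = 1.0):
    """Per-case DSC/JC/MAD/HD/SSD over matching mask files plus a summary.

    Returns ``(per_case DataFrame, summary dict)`` with mean +/- std per
    metric; unmatched filenames are skipped with a warning.
    """
    pred_dir, ref_dir = Path(pred_dir), Path(ref_dir)
    pred_files = {p.name: p for p in sorted(pred_dir.glob("*.png"))}
    ref_files = {p.name: p for p in sorted(ref_dir.glob("*.png"))}
    common = sorted(set(pred_files) & set(ref_files))
    skipped = sorted(set(pred_files) ^ set(ref_files))
    for name in skipped:
        log.warning("unmatched mask file skipped: %s", name)
    if not common:
        raise ValueError("no matching mask files between directories")
    rows = []
    for name in common:
        pred = read_mask(pred_files[name])
        ref = read_mask(ref_files[name])
        dsc, jc = overlap_metrics(pred, ref)
        mad, hd, ssd = surface_metrics(pred, ref, spacing_mm_per_px)
        rows.append({"case": name, "dsc": dsc, "jc": jc, "mad_mm": mad,
                     "hd_mm": hd, "ssd_mm": ssd})
    frame = pd.DataFrame(rows)
    summary = {
        m: {"mean": float(frame[m].mean()), "std": float(frame[m].std(ddof=0))}
        for m in ("dsc", "jc", "mad_mm", "hd_mm", "ssd_mm")
    }
    return frame, summary
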