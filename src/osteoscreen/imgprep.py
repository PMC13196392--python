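"""Radiograph ingestion, eligibility rules, and the two preprocessing paths.

Coordinate convention throughout the package: row-major, 0-based, half-open
boxes [r0, r1) × [c0, c1).

Two distinct preprocessing paths feed the pipeline:

* segmentation input — intensity windowed to the 0.5/99.5 percentiles,
  mapped to 8-bit, aspect-preserving resize with zero padding to 1024×1024,
  with a :class:`ScaleRecord` to map predicted masks back to native pixels;
* classification ROI — tight bounding box over the assessable vertebrae
  expanded by 10%, resampled to 0.2 mm/px from the spacing metadata, then
  globally histogram-equalised (surrounding soft tissue retained).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
from skimage import exposure, transform

from .labels import DXARecord

SEG_INPUT_SIZE = 1024
CLASSIFICATION_SPACING_MM = 0.2
DXA_GAP_MAX_DAYS = 183  # "within 6 months"
ROI_MARGIN_FRACTION = 0.10

# eligibility reason codes
SPACING_GT_0_2 = "SPACING_GT_0.2"
DXA_GAP_GT_6M = "DXA_GAP_GT_6M"
LT_2_VERTEBRAE = "LT_2_VERTEBRAE"
OVERLAY_BLOCKED = "OVERLAY_BLOCKED"


class SpacingMissingError(ValueError):
    """Raised when no pixel-spacing metadata is available (required for resampling)."""


@dataclass
class Radiograph:
    pixels: np.ndarray
    pixel_spacing_mm: Tuple[float, float]  # (row, col) mm/px
    age_years: Optional[float] = None
    sex: Optional[str] = None  # {F, M}
    acquisition_date: Optional[_dt.date] = None
    subject_id: Optional[str] = None
    image_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not all(s > 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive on both axes")


@dataclass
class EligibilityResult:
    reasons: List[str] = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return not self.reasons


@dataclass
class ScaleRecord:
    """Forward/backward mapping between native pixels and the 1024×1024 grid."""

    native_shape: Tuple[int, int]
    scale: float  # native * scale = content pixels
    pad_top: int
    pad_left: int
    content_shape: Tuple[int, int]

    def box_to_native(self, box: Tuple[int, int, int, int]) -> Tuple[int, int, int, int]:
        r0, r1, c0, c1 = box
        to_n = lambda r, c: ((r - self.pad_top) / self.scale, (c - self.pad_left) / self.scale)
        nr0, nc0 = to_n(r0, c0)
        nr1, nc1 = to_n(r1, c1)
        h, w = self.native_shape
        return (
            int(np.clip(round(nr0), 0, h)),
            int(np.clip(round(nr1), 0, h)),
            int(np.clip(round(nc0), 0, w)),
            int(np.clip(round(nc1), 0, w)),
        )

    def mask_to_native(self, mask: np.ndarray) -> np.ndarray:
        content = mask[
            self.pad_top : self.pad_top + self.content_shape[0],
            self.pad_left : self.pad_left + self.content_shape[1],
        ]
        out = transform.resize(
            content.astype(float), self.native_shape, order=0, preserve_range=True
        )
        return out > 0.5


def _load_png_sidecar(path: Path) -> Radiograph:
    pixels = np.asarray(iio.imread(path))
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SpacingMissingError(f"no JSON sidecar next to {path}; pixel spacing required")
    meta = json.loads(sidecar_path.read_text())
    if "pixel_spacing_mm" not in meta:
        raise SpacingMissingError(f"sidecar {sidecar_path} lacks pixel_spacing_mm")
    sp = meta["pixel_spacing_mm"]
    spacing = (float(sp), float(sp)) if np.isscalar(sp) else (float(sp[0]), float(sp[1]))
    date = meta.get("acquisition_date")
    return Radiograph(
        pixels=pixels,
        pixel_spacing_mm=spacing,
        age_years=float(meta["age"]) if meta.get("age") is not None else None,
        sex=meta.get("sex"),
        acquisition_date=_dt.date.fromisoformat(date) if date else None,
        subject_id=meta.get("subject_id"),
        image_id=path.stem,
    )


def _parse_dicom_age(value) -> Optional[float]:
    if value in (None, ""):
        return None
    s = str(value)
    try:
        if s.endswith(("Y", "y")):
            return float(s[:-1])
        if s.endswith(("M", "m")):
            return float(s[:-1]) / 12.0
        return float(s)
    except ValueError:
        return None


def _load_dicom(path: Path) -> Radiograph:
    import pydicom

    ds = pydicom.dcmread(str(path))
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise SpacingMissingError(f"{path}: neither PixelSpacing nor ImagerPixelSpacing present")
    sex_raw = str(getattr(ds, "PatientSex", "") or "").upper()
    date_raw = str(getattr(ds, "AcquisitionDate", "") or "")
    date = None
    if len(date_raw) == 8:
        date = _dt.date(int(date_raw[:4]), int(date_raw[4:6]), int(date_raw[6:8]))
    return Radiograph(
        pixels=ds.pixel_array,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        age_years=_parse_dicom_age(getattr(ds, "PatientAge", None)),
        sex=sex_raw if sex_raw in ("F", "M") else None,
        acquisition_date=date,
        subject_id=str(getattr(ds, "PatientID", "") or "") or None,
        image_id=path.stem,
    )


def load_radiograph(path) -> Radiograph:
    """Load a radiograph from DICOM or 16-bit PNG + JSON sidecar.

    Missing age/sex stay missing (None), never defaulted; absent spacing
    metadata raises :class:`SpacingMissingError`.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(p)
    return _load_png_sidecar(p)


def check_eligibility(
    radiograph: Radiograph,
    dxa: Optional[DXARecord] = None,
    vertebra_count: Optional[int] = None,
) -> EligibilityResult:
    """Apply the inclusion rules; every violated rule is listed.

    Rules: in-plane spacing ≤ 0.2 mm/px; paired DXA within 6 months (183
    days); at least two assessable lumbar vertebrae.  ``vertebra_count=None``
    defers the vertebra rule (counted after segmentation).
    """
    reasons: List[str] = []
    if max(radiograph.pixel_spacing_mm) > 0.2:
        reasons.append(SPACING_GT_0_2)
    if dxa is not None and dxa.acquisition_date is not None and radiograph.acquisition_date is not None:
        gap = abs((radiograph.acquisition_date - dxa.acquisition_date).days)
        if gap > DXA_GAP_MAX_DAYS:
            reasons.append(DXA_GAP_GT_6M)
    if vertebra_count is not None and vertebra_count < 2:
        reasons.append(LT_2_VERTEBRAE)
    return EligibilityResult(reasons=reasons)


def prepare_segmentation_input(radiograph: Radiograph) -> Tuple[np.ndarray, ScaleRecord]:
    """8-bit 1024×1024 segmentation input with a scale record back to native pixels.

    Intensity is windowed to the 0.5/99.5 percentiles then linearly mapped to
    0–255 (a degenerate window maps to mid-grey 128); the resize preserves
    aspect ratio, padding symmetrically with zeros.
    """
    px = radiograph.pixels.astype(float)
    lo, hi = np.percentile(px, (0.5, 99.5))
    if hi > lo:
        img8 = np.clip((px - lo) / (hi - lo) * 255.0, 0, 255)
    else:
        img8 = np.full(px.shape, 128.0)
    h, w = px.shape
    scale = SEG_INPUT_SIZE / max(h, w)
    content = (int(round(h * scale)), int(round(w * scale)))
    resized = transform.resize(img8, content, order=1, anti_aliasing=scale < 1, preserve_range=True)
    out = np.zeros((SEG_INPUT_SIZE, SEG_INPUT_SIZE), dtype=np.uint8)
    pad_top = (SEG_INPUT_SIZE - content[0]) // 2
    pad_left = (SEG_INPUT_SIZE - content[1]) // 2
    out[pad_top : pad_top + content[0], pad_left : pad_left + content[1]] = np.clip(
        np.round(resized), 0, 255
    ).astype(np.uint8)
    return out, ScaleRecord(
        native_shape=(h, w), scale=scale, pad_top=pad_top, pad_left=pad_left, content_shape=content
    )


@dataclass
class RoiRecord:
    """Geometry of the classification ROI in native pixels and its resampling."""

    native_box: Tuple[int, int, int, int]
    resample_factor: float
    roi_shape: Tuple[int, int]


def prepare_classification_roi(radiograph: Radiograph, assessable) -> Tuple[np.ndarray, RoiRecord]:
    """Classification ROI at 0.2 mm/px, globally histogram-equalised.

    The ROI is the tight bounding box over the union of assessable vertebra
    masks expanded by a fixed 10% margin; surrounding soft tissue inside the
    box is retained (not masked) since peri-vertebral context is informative.
    """
    verts = [i for i in assessable.instances if i.cls == "vertebra"]
    if len(verts) < 2:
        raise ValueError("classification ROI requires at least two assessable vertebrae")
    union = np.zeros(radiograph.pixels.shape, dtype=bool)
    for inst in verts:
        union |= inst.mask
    rows, cols = np.nonzero(union)
    r0, r1, c0, c1 = rows.min(), rows.max() + 1, cols.min(), cols.max() + 1
    mr, mc = int(round(ROI_MARGIN_FRACTION * (r1 - r0))), int(round(ROI_MARGIN_FRACTION * (c1 - c0)))
    h, w = radiograph.pixels.shape
    box = (max(0, r0 - mr), min(h, r1 + mr), max(0, c0 - mc), min(w, c1 + mc))
    crop = radiograph.pixels[box[0] : box[1], box[2] : box[3]].astype(float)
    factor = float(np.mean(radiograph.pixel_spacing_mm)) / CLASSIFICATION_SPACING_MM
    out_shape = (max(1, round(crop.shape[0] * factor)), max(1, round(crop.shape[1] * factor)))
    resampled = transform.resize(crop, out_shape, order=1, anti_aliasing=factor < 1, preserve_range=True)
    if resampled.max() > resampled.min():
        roi = exposure.equalize_hist(resampled)
    else:
        # degenerate window: a constant ROI stays constant (mid-grey in [0,1])
        roi = np.full(out_shape, 0.5)
    return roi, RoiRecord(native_box=box, resample_factor=factor, roi_shape=out_shape)
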