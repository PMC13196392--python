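"""Synthetic lumbar-radiograph phantoms with analytic trabecular-texture ground truth.

Each phantom is an AP lumbar view rendered as 2–4 vertically stacked
rounded-rectangle vertebrae filled with fractional-Brownian-motion (fBm)
texture, on a smooth background gradient with additive noise, optionally
confounded by a bright surgical-implant bar and a text overlay.  The two
generative parameters per subject are the texture roughness (Hurst exponent
H — the log–log variogram slope of an isotropic fBm surface at small lags is
≈ 2H) and a mean-density offset of the vertebrae over the background.

A deterministic affine calibration maps (density, H) to a paired DXA record
(BMD T-score increasing in density, TBS increasing in H), anchored so the
mid-range maps exactly onto the clinical thresholds (t = −1.75, tbs = 1.23).
The reference Bone Fragility Index label therefore follows analytically from
the phantom parameters, which makes every downstream stage testable without
real patient data.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .labels import DXARecord, FragilityLabel, bone_fragility_index

# Calibration anchors: mid-range parameters map to the clinical thresholds.
T_SCORE_ANCHOR = -1.75  # T-score at the density mid-range
T_SCORE_HALF_SPAN = 2.25  # T-score change over half the density range
TBS_ANCHOR = 1.23  # TBS at the Hurst mid-range
TBS_HALF_SPAN = 0.20  # TBS change over half the Hurst range

# Separability margins around the very-high-fragility class boundary in
# parameter space; sampled subjects never land inside the band.
_MARGIN_DENSITY = 0.01
_MARGIN_HURST = 0.02

_BASE_DATE = _dt.date(2023, 6, 15)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom generator (defaults are the conditions)."""

    image_height_px: int = 768
    image_width_px: int = 320
    pixel_spacing_mm: float = 0.143
    n_vertebrae: int = 4
    hurst_range: Tuple[float, float] = (0.2, 0.8)
    density_offset_range: Tuple[float, float] = (0.10, 0.40)  # normalised grey units
    implant_probability: float = 0.08
    text_probability: float = 0.10
    noise_sd: float = 0.005
    texture_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hurst_range[0] < self.hurst_range[1] < 1):
            raise ValueError("hurst_range must lie strictly inside (0, 1)")
        if not (2 <= self.n_vertebrae <= 4):
            raise ValueError("n_vertebrae must be between 2 and 4")
        if self.pixel_spacing_mm <= 0 or self.pixel_spacing_mm > 0.2:
            raise ValueError("pixel_spacing_mm must be in (0, 0.2] for eligible phantoms")
        if self.image_height_px < 32 or self.image_width_px < 32:
            raise ValueError("image must be at least 32x32")
        for p in (self.implant_probability, self.text_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class PhantomSample:
    image: np.ndarray  # uint16 grey image
    masks: Dict[str, np.ndarray]  # {L1..L4, implant} -> bool masks
    true_hurst: List[float]  # per vertebra (shared subject value)
    true_density: List[float]
    age_years: float
    sex: str  # {F, M}
    dxa: DXARecord
    label: FragilityLabel
    subject_id: str = "S0000"
    pixel_spacing_mm: float = 0.143
    acquisition_date: _dt.date = _BASE_DATE

    @property
    def vertebra_levels(self) -> List[str]:
        return [k for k in ("L1", "L2", "L3", "L4") if k in self.masks]


def generate_fbm_texture(shape: Tuple[int, int], hurst: float, seed: int, oversample: int = 4) -> np.ndarray:
    """Isotropic fractional-Brownian surface by Fourier spectral synthesis.

    The spectral amplitude follows |f|^-(H+1), i.e. a power spectral density
    ∝ f^-(2H+2).  Synthesis runs on an ``oversample``-times finer grid that is
    then decimated: without oversampling the spectral cutoff at the Nyquist
    frequency suppresses lag-1 increments and biases the measured variogram
    slope upward for rough (low-H) fields.  The field is standardised to zero
    mean and unit variance; its log–log variogram slope at small lags is ≈ 2H.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    h, w = int(shape[0]), int(shape[1])
    if h < 32 or w < 32:
        raise ValueError("shape must be at least 32x32")
    H2, W2 = oversample * h, oversample * w
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(H2, W2)) + 1j * rng.normal(size=(H2, W2))
    fy = np.fft.fftfreq(H2)[:, None]
    fx = np.fft.fftfreq(W2)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-(hurst + 1.0))
    field = np.fft.ifft2(noise * amp).real[::oversample, ::oversample]
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def calibration_map(
    true_density: float, true_hurst: float, config: Optional[PhantomConfig] = None
) -> Tuple[float, float]:
    """Affine monotone map (density, H) → (BMD T-score, TBS).

    Anchored so the mid-range of each parameter maps exactly to the clinical
    thresholds' neighbourhood: density midpoint → t = −1.75, Hurst midpoint →
    tbs = 1.23.  Deterministic and invertible on the configured ranges.
    """
    cfg = config or PhantomConfig()
    d_lo, d_hi = cfg.density_offset_range
    h_lo, h_hi = cfg.hurst_range
    d_mid, d_half = (d_lo + d_hi) / 2.0, (d_hi - d_lo) / 2.0
    h_mid, h_half = (h_lo + h_hi) / 2.0, (h_hi - h_lo) / 2.0
    t_score = T_SCORE_ANCHOR + (true_density - d_mid) / d_half * T_SCORE_HALF_SPAN
    tbs = TBS_ANCHOR + (true_hurst - h_mid) / h_half * TBS_HALF_SPAN
    return float(t_score), float(tbs)


def inverse_calibration(t_score: float, tbs: float, config: Optional[PhantomConfig] = None) -> Tuple[float, float]:
    """Inverse of :func:`calibration_map` (density, hurst from t-score, tbs)."""
    cfg = config or PhantomConfig()
    d_lo, d_hi = cfg.density_offset_range
    h_lo, h_hi = cfg.hurst_range
    d_mid, d_half = (d_lo + d_hi) / 2.0, (d_hi - d_lo) / 2.0
    h_mid, h_half = (h_lo + h_hi) / 2.0, (h_hi - h_lo) / 2.0
    density = d_mid + (t_score - T_SCORE_ANCHOR) / T_SCORE_HALF_SPAN * d_half
    hurst = h_mid + (tbs - TBS_ANCHOR) / TBS_HALF_SPAN * h_half
    return float(density), float(hurst)


def _vertebra_slots(cfg: PhantomConfig, rng: np.random.Generator) -> List[Tuple[int, int, int, int]]:
    """Half-open (r0, r1, c0, c1) boxes for n stacked vertebrae, 10% gaps."""
    n = cfg.n_vertebrae
    h, w = cfg.image_height_px, cfg.image_width_px
    top, bottom = int(0.05 * h), int(0.95 * h)
    unit = (bottom - top) / (n + 0.1 * (n - 1))
    boxes = []
    for k in range(n):
        r0 = top + int(round(k * unit * 1.1))
        r1 = r0 + int(round(unit))
        width_frac = rng.uniform(0.25, 0.35)
        vw = int(round(width_frac * w))
        jitter = int(rng.integers(-w // 20, w // 20 + 1))
        c_mid = w // 2 + jitter
        c0, c1 = max(0, c_mid - vw // 2), min(w, c_mid + vw // 2)
        boxes.append((r0, r1, c0, c1))
    return boxes


def _rounded_rect_mask(shape: Tuple[int, int], box: Tuple[int, int, int, int]) -> np.ndarray:
    """Superellipse (rounded-rectangle) mask inside a half-open box."""
    r0, r1, c0, c1 = box
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    ry, rx = (r1 - r0) / 2.0, (c1 - c0) / 2.0
    cy, cx = r0 + ry, c0 + rx
    return ((np.abs((rr - cy) / ry) ** 4 + np.abs((cc - cx) / rx) ** 4) <= 1.0) & (rx > 0) & (ry > 0)


def _sample_parameters(
    cfg: PhantomConfig, rng: np.random.Generator, force_vhbf: Optional[bool]
) -> Tuple[float, float]:
    """Sample (density, hurst); optionally force the VHBF class, avoiding the
    margin band around the class boundary so labels are separable by construction."""
    d_lo, d_hi = cfg.density_offset_range
    h_lo, h_hi = cfg.hurst_range
    # VHBF region in parameter space: t <= -2.5 and tbs < 1.23
    d_star, h_star = inverse_calibration(-2.5, TBS_ANCHOR, cfg)
    if force_vhbf is True:
        d = rng.uniform(d_lo, d_star - _MARGIN_DENSITY)
        hexp = rng.uniform(h_lo, h_star - _MARGIN_HURST)
        return float(d), float(hexp)
    while True:
        d = rng.uniform(d_lo, d_hi)
        hexp = rng.uniform(h_lo, h_hi)
        is_vhbf = (d <= d_star) and (hexp < h_star)
        near_d_edge = abs(d - d_star) < _MARGIN_DENSITY and hexp < h_star + _MARGIN_HURST
        near_h_edge = abs(hexp - h_star) < _MARGIN_HURST and d <= d_star + _MARGIN_DENSITY
        if near_d_edge or near_h_edge:
            continue  # inside the separability band around the class boundary
        if force_vhbf is None or force_vhbf == is_vhbf:
            return float(d), float(hexp)


def generate_phantom(
    config: PhantomConfig,
    seed: int,
    subject_id: str = "S0000",
    force_vhbf: Optional[bool] = None,
    density: Optional[float] = None,
    hurst: Optional[float] = None,
) -> PhantomSample:
    """Render one phantom radiograph with its masks, DXA record and label.

    ``density``/``hurst`` override the sampled subject parameters (both must
    be given together or not at all)."""
    cfg = config
    rng = np.random.default_rng(seed)
    h, w = cfg.image_height_px, cfg.image_width_px
    if density is None or hurst is None:
        density, hurst = _sample_parameters(cfg, rng, force_vhbf)

    # background: gentle vertical soft-tissue gradient
    img = np.linspace(0.25, 0.35, h)[:, None] * np.ones((1, w))
    masks: Dict[str, np.ndarray] = {}
    boxes = _vertebra_slots(cfg, rng)
    levels = ["L1", "L2", "L3", "L4"][: cfg.n_vertebrae]
    for level, box in zip(levels, boxes):
        m = _rounded_rect_mask((h, w), box)
        tex = generate_fbm_texture(
            (max(32, box[1] - box[0]), max(32, box[3] - box[2])),
            hurst,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        full = np.zeros((h, w))
        full[box[0] : box[0] + tex.shape[0], box[2] : box[2] + tex.shape[1]] = tex
        img[m] = img[m] + density + cfg.texture_amplitude * full[m]
        masks[level] = m

    if rng.uniform() < cfg.implant_probability:
        target = levels[int(rng.integers(0, len(levels)))]
        r0, r1, c0, c1 = boxes[levels.index(target)]
        bar_h = max(3, int(0.3 * (r1 - r0)))
        br0 = int(rng.integers(r0, max(r0 + 1, r1 - bar_h)))
        implant = np.zeros((h, w), dtype=bool)
        implant[br0 : br0 + bar_h, max(0, c0 - 10) : min(w, c1 + 10)] = True
        img[implant] = 0.95
        masks["implant"] = implant

    if rng.uniform() < cfg.text_probability:
        img[10:26, 10:80] = 0.98  # burned-in text block confounder (not masked)

    img = img + rng.normal(scale=cfg.noise_sd, size=(h, w))
    img16 = np.clip(np.round(img * 65535), 0, 65535).astype(np.uint16)

    t_score, tbs = calibration_map(density, hurst, cfg)
    gap_days = int(rng.integers(-90, 91))
    dxa = DXARecord(
        bmd_t_score=t_score,
        tbs=tbs,
        acquisition_date=_BASE_DATE + _dt.timedelta(days=gap_days),
        subject_id=subject_id,
    )
    return PhantomSample(
        image=img16,
        masks=masks,
        true_hurst=[hurst] * cfg.n_vertebrae,
        true_density=[density] * cfg.n_vertebrae,
        age_years=float(np.round(rng.uniform(50, 85), 1)),
        sex="F" if rng.uniform() < 0.85 else "M",
        dxa=dxa,
        label=bone_fragility_index(dxa),
        subject_id=subject_id,
        pixel_spacing_mm=cfg.pixel_spacing_mm,
        acquisition_date=_BASE_DATE,
    )


def _stratified_split(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """80/10/10 split stratified on the binary label; returns split names."""
    split = np.empty(len(labels), dtype=object)
    for value in (True, False):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        g = len(idx)
        n_test = max(1, int(round(0.1 * g))) if g >= 3 else 0
        n_val = max(1, int(round(0.1 * g))) if g >= 3 else 0
        split[idx[: g - n_val - n_test]] = "train"
        split[idx[g - n_val - n_test : g - n_test]] = "val"
        split[idx[g - n_test :]] = "test"
    return split


def generate_cohort(
    n: int,
    class_mix: float,
    config: Optional[PhantomConfig] = None,
    seed: int = 0,
) -> Tuple[List[PhantomSample], pd.DataFrame]:
    """Generate ``n`` phantoms with an exact VHBF fraction and 80/10/10 splits.

    Exactly ``round(n * class_mix)`` samples are very-high-bone-fragility; the
    split is stratified on that class with one subject per sample, so no
    subject appears in two splits.  Identical (config, seed) reproduce the
    cohort byte for byte.
    """
    cfg = config or PhantomConfig()
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (0.0 < class_mix < 1.0):
        raise ValueError("class_mix must be in (0, 1)")
    n_pos = int(round(n * class_mix))
    if n_pos < 1:
        raise ValueError("class_mix * n must be >= 1")
    master = np.random.default_rng(seed)
    is_vhbf = np.array([True] * n_pos + [False] * (n - n_pos))
    master.shuffle(is_vhbf)
    samples: List[PhantomSample] = []
    for i in range(n):
        sid = f"S{i:05d}"
        sample_seed = int(master.integers(0, 2**31 - 1))
        samples.append(generate_phantom(cfg, sample_seed, subject_id=sid, force_vhbf=bool(is_vhbf[i])))
    split = _stratified_split(is_vhbf, master)
    manifest = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "split": split,
            "t_score": [s.dxa.bmd_t_score for s in samples],
            "tbs": [s.dxa.tbs for s in samples],
            "label": [s.label.category for s in samples],
            "vhbf": [s.label.is_very_high for s in samples],
            "age_years": [s.age_years for s in samples],
            "sex": [s.sex for s in samples],
            "true_density": [s.true_density[0] for s in samples],
            "true_hurst": [s.true_hurst[0] for s in samples],
            "n_vertebrae": [len(s.vertebra_levels) for s in samples],
            "has_implant": ["implant" in s.masks for s in samples],
        }
    )
    return samples, manifest


# ---------------------------------------------------------------------------
# on-disk dialect: 16-bit PNG + JSON sidecar, label-map PNG masks, manifest CSV

MASK_LEGEND = {"0": "background", "1": "L1", "2": "L2", "3": "L3", "4": "L4", "5": "implant"}


def write_phantom(sample: PhantomSample, out_dir) -> Dict[str, str]:
    """Write one phantom (image, sidecar, masks) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = sample.subject_id
    img_path = out / f"{sid}.png"
    iio.imwrite(img_path, sample.image)
    sidecar = {
        "pixel_spacing_mm": sample.pixel_spacing_mm,
        "age": sample.age_years,
        "sex": sample.sex,
        "subject_id": sid,
        "acquisition_date": sample.acquisition_date.isoformat(),
    }
    sidecar_path = out / f"{sid}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    label_map = np.zeros(sample.image.shape, dtype=np.uint8)
    for code, name in sorted(MASK_LEGEND.items()):
        if name in sample.masks and name != "implant":
            label_map[sample.masks[name]] = int(code)
    mask_path = out / f"{sid}_mask.png"
    iio.imwrite(mask_path, label_map)
    paths = {"image": str(img_path), "sidecar": str(sidecar_path), "mask": str(mask_path)}
    if "implant" in sample.masks:
        implant_path = out / f"{sid}_implant.png"
        iio.imwrite(implant_path, sample.masks["implant"].astype(np.uint8) * 5)
        paths["implant"] = str(implant_path)
    legend_path = out / "mask_legend.json"
    if not legend_path.exists():
        legend_path.write_text(json.dumps(MASK_LEGEND, indent=1))
    return paths


def write_cohort(samples: List[PhantomSample], manifest: pd.DataFrame, out_dir) -> str:
    """Write a full cohort and its manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_phantom(s, out / "images")
    dxa = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "date": [s.dxa.acquisition_date.isoformat() for s in samples],
            "bmd_t_score": [s.dxa.bmd_t_score for s in samples],
            "tbs": [s.dxa.tbs for s in samples],
        }
    )
    dxa.to_csv(out / "dxa.csv", index=False)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return str(manifest_path)


def read_mask_label_map(path, implant_path=None) -> Dict[str, np.ndarray]:
    """Read masks back from a label-map PNG (+ optional implant map)."""
    label_map = np.asarray(iio.imread(path))
    masks = {}
    for code, name in MASK_LEGEND.items():
        if name in ("background", "implant"):
            continue
        m = label_map == int(code)
        if m.any():
            masks[name] = m
    if implant_path is not None and Path(implant_path).exists():
        masks["implant"] = np.asarray(iio.imread(implant_path)) > 0
    return masks
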