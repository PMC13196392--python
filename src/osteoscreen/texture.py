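"""Engineered trabecular-texture features: experimental variogram, raw TBS, GLCM.

The experimental variogram γ(d) = Σ (I(x_i) − I(x_i+d))² / (2·N(d)) measures
spatial grey-level variability as a function of lag d; its slope on a log–log
scale over lags 1..15 px at 0.45 mm/px (≈6.75 mm) is the raw trabecular bone
score.  Rougher trabecular texture (lower Hurst exponent H) gives a shallower
slope: for a fractional Brownian surface the slope at small lags is ≈ 2H.

Pair geometry: axis-aligned offsets (0, d) and (d, 0), pooled, with both
endpoints inside the mask — this keeps the integer-lag formula exact and
matches a brute-force all-pairs enumeration bit for bit.

GLCM descriptors are symmetric, normalised co-occurrence statistics
(contrast, correlation, energy, homogeneity) at distances {1, 2, 4} px,
averaged over the four principal angles, on a 32-level quantisation of the
in-mask grey values (so they are invariant to affine shifts of intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import exposure, transform

VARIOGRAM_SPACING_MM = 0.45
DEFAULT_MAX_LAG = 15
GLCM_LEVELS = 32
GLCM_DISTANCES = (1, 2, 4)
GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")


@dataclass
class VariogramProfile:
    """γ(d) with pair counts; lags with no valid pairs are omitted."""

    lags: np.ndarray  # strictly increasing integer lags
    gamma: np.ndarray  # γ(d) >= 0
    n_pairs: np.ndarray  # N(d) > 0 for every reported lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class TextureFeatures:
    raw_tbs: float
    glcm: Dict[str, float]
    per_vertebra_profiles: List[VariogramProfile] = field(default_factory=list)
    per_vertebra_slopes: List[float] = field(default_factory=list)

    def glcm_vector(self, fill: float = 0.0) -> np.ndarray:
        """GLCM descriptors as a fixed-order vector (missing → ``fill``)."""
        return np.array(
            [self.glcm.get(k, fill) if self.glcm.get(k) is not None else fill for k in glcm_feature_names()],
            dtype=float,
        )


def glcm_feature_names() -> List[str]:
    return [f"glcm_{p}_d{d}" for d in GLCM_DISTANCES for p in GLCM_PROPS]


def experimental_variogram(
    roi: np.ndarray, mask: Optional[np.ndarray] = None, d_max: int = DEFAULT_MAX_LAG
) -> VariogramProfile:
    """Experimental variogram over axis-aligned pixel pairs inside ``mask``.

    γ(d) = Σ_pairs (ΔI)² / (2·N(d)) pooling horizontal and vertical offsets.
    Lags with N(d) = 0 are omitted; a mask thinner than ``d_max`` on both axes
    yields a truncated profile with a warning.
    """
    img = np.asarray(roi, dtype=float)
    if img.ndim != 2:
        raise ValueError("roi must be 2-D")
    m = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if m.shape != img.shape:
        raise ValueError("mask shape must match roi")
    if not m.any():
        raise ValueError("mask is empty")

    lags, gammas, counts = [], [], []
    for d in range(1, int(d_max) + 1):
        ssq = 0.0
        n = 0
        if d < img.shape[1]:  # horizontal pairs (0, d)
            valid = m[:, :-d] & m[:, d:]
            diff = img[:, :-d][valid] - img[:, d:][valid]
            ssq += float(np.dot(diff, diff))
            n += int(valid.sum())
        if d < img.shape[0]:  # vertical pairs (d, 0)
            valid = m[:-d, :] & m[d:, :]
            diff = img[:-d, :][valid] - img[d:, :][valid]
            ssq += float(np.dot(diff, diff))
            n += int(valid.sum())
        if n > 0:
            lags.append(d)
            gammas.append(ssq / (2.0 * n))
            counts.append(n)
    if len(lags) < int(d_max):
        warnings.warn(
            f"variogram truncated: only {len(lags)} of {d_max} lags have pairs",
            stacklevel=2,
        )
    return VariogramProfile(np.array(lags), np.array(gammas), np.array(counts))


def variogram_slope(profile: VariogramProfile, estimator: str = "ols") -> float:
    """Log–log slope of a variogram profile over its available lags.

    ``estimator='ols'`` (default): ordinary least-squares fit of log γ(d) on
    log d over all positive-γ lags.  ``estimator='endpoint'``: two-point slope
    between the first and last positive-γ lags.  Lags with γ = 0 are excluded;
    an all-zero profile is undefined (NaN).
    """
    keep = profile.gamma > 0
    if keep.sum() < (2 if estimator == "endpoint" else 3):
        return float("nan")
    x = np.log(profile.lags[keep].astype(float))
    y = np.log(profile.gamma[keep])
    if estimator == "endpoint":
        return float((y[-1] - y[0]) / (x[-1] - x[0]))
    if estimator != "ols":
        raise ValueError(f"unknown estimator {estimator!r}")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def raw_tbs(profiles: Sequence[VariogramProfile], estimator: str = "ols") -> float:
    """Raw trabecular bone score: mean log–log variogram slope across vertebrae.

    Per vertebra the slope is fitted over lags 1..15 (available positive-γ
    lags); the score is the unweighted mean.  Vertebrae with undefined slopes
    (all-zero profiles) are excluded; if none remain the score is NaN.
    """
    if not profiles:
        raise ValueError("at least one variogram profile is required")
    slopes = np.array([variogram_slope(p, estimator=estimator) for p in profiles])
    valid = ~np.isnan(slopes)
    if not valid.any():
        warnings.warn("raw_tbs undefined: every profile degenerate", stacklevel=2)
        return float("nan")
    return float(slopes[valid].mean())


def _quantise(roi: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantise in-mask grey values to ``levels`` bins via in-mask min–max."""
    vals = roi[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(roi.shape, dtype=np.uint8)
    q = np.clip(((roi - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    return q.astype(np.uint8)


def _cooccurrence(q: np.ndarray, mask: np.ndarray, offset: Tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one (dr, dc) offset, in-mask pairs only."""
    dr, dc = offset
    h, w = q.shape
    P = np.zeros((levels, levels), dtype=float)
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    if r0s >= r0e or c0s >= c0e:
        return P
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    np.add.at(P, (a[valid], b[valid]), 1.0)
    return P + P.T  # symmetric


def glcm_features(
    roi: np.ndarray, mask: Optional[np.ndarray] = None, levels: int = GLCM_LEVELS
) -> Dict[str, Optional[float]]:
    """Angle-averaged GLCM descriptors at distances {1, 2, 4} px.

    Co-occurrence matrices are accumulated over the four principal angles
    (0°, 45°, 90°, 135°), symmetrised and normalised; descriptors are the
    standard contrast, correlation, energy and homogeneity.  Distances with no
    valid in-mask pair are reported as None.
    """
    img = np.asarray(roi, dtype=float)
    m = np.ones(img.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    q = _quantise(img, m, levels)
    i_idx, j_idx = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    out: Dict[str, Optional[float]] = {}
    for d in GLCM_DISTANCES:
        offsets = [(0, d), (-d, d), (-d, 0), (-d, -d)]  # 0°, 45°, 90°, 135°
        P = np.zeros((levels, levels), dtype=float)
        for off in offsets:
            P += _cooccurrence(q, m, off, levels)
        total = P.sum()
        if total == 0:
            for p in GLCM_PROPS:
                out[f"glcm_{p}_d{d}"] = None
            continue
        P /= total
        mu_i = float((i_idx * P).sum())
        mu_j = float((j_idx * P).sum())
        var_i = float(((i_idx - mu_i) ** 2 * P).sum())
        var_j = float(((j_idx - mu_j) ** 2 * P).sum())
        contrast = float(((i_idx - j_idx) ** 2 * P).sum())
        energy = float((P**2).sum())
        homogeneity = float((P / (1.0 + (i_idx - j_idx) ** 2)).sum())
        if var_i > 0 and var_j > 0:
            correlation = float((((i_idx - mu_i) * (j_idx - mu_j) * P).sum()) / np.sqrt(var_i * var_j))
        else:
            correlation = 1.0  # constant in-mask image: perfectly correlated
        out[f"glcm_contrast_d{d}"] = contrast
        out[f"glcm_correlation_d{d}"] = correlation
        out[f"glcm_energy_d{d}"] = energy
        out[f"glcm_homogeneity_d{d}"] = homogeneity
    return out


def prepare_vertebra_patch(
    pixels: np.ndarray,
    mask: np.ndarray,
    pixel_spacing_mm: float,
    target_spacing_mm: float = VARIOGRAM_SPACING_MM,
) -> Tuple[np.ndarray, np.ndarray]:
    """Crop a vertebra to its bbox, histogram-normalise, resample to 0.45 mm/px.

    Returns the resampled patch (float in [0, 1]) and its resampled boolean
    mask (nearest-neighbour).  Histogram normalisation is global histogram
    equalisation over the crop, matching the classifier preprocessing path.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("vertebra mask is empty")
    r0, r1, c0, c1 = rows.min(), rows.max() + 1, cols.min(), cols.max() + 1
    patch = np.asarray(pixels, dtype=float)[r0:r1, c0:c1]
    sub = mask[r0:r1, c0:c1]
    if patch.max() > patch.min():
        patch = exposure.equalize_hist(patch)
    else:
        patch = np.full(patch.shape, 0.5)
    scale = float(pixel_spacing_mm) / float(target_spacing_mm)
    out_shape = (max(1, round(patch.shape[0] * scale)), max(1, round(patch.shape[1] * scale)))
    patch_rs = transform.resize(patch, out_shape, order=1, anti_aliasing=scale < 1, preserve_range=True)
    mask_rs = transform.resize(sub.astype(float), out_shape, order=0, preserve_range=True) > 0.5
    if not mask_rs.any():
        mask_rs = np.ones(out_shape, dtype=bool)
    return patch_rs, mask_rs


def compute_texture_block(radiograph, assessable, d_max: int = DEFAULT_MAX_LAG) -> TextureFeatures:
    """Per-case engineered features from the assessable vertebrae.

    Pipeline per vertebra: crop mask bbox → histogram-equalise → resample to
    0.45 mm/px → experimental variogram (lags 1..15) and GLCM descriptors;
    raw TBS and the GLCM vector are averaged across vertebrae.
    """
    verts = [i for i in assessable.instances if i.cls == "vertebra"]
    if len(verts) < 2:
        raise ValueError("at least two assessable vertebrae are required")
    spacing = float(np.mean(radiograph.pixel_spacing_mm))
    profiles: List[VariogramProfile] = []
    glcm_rows: List[Dict[str, Optional[float]]] = []
    for inst in verts:
        patch, m = prepare_vertebra_patch(radiograph.pixels, inst.mask, spacing)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles.append(experimental_variogram(patch, m, d_max=d_max))
        glcm_rows.append(glcm_features(patch, m))
    score = raw_tbs(profiles)
    agg: Dict[str, Optional[float]] = {}
    for key in glcm_feature_names():
        vals = [row[key] for row in glcm_rows if row.get(key) is not None]
        agg[key] = float(np.mean(vals)) if vals else None
    slopes = [variogram_slope(p) for p in profiles]
    return TextureFeatures(raw_tbs=score, glcm=agg, per_vertebra_profiles=profiles, per_vertebra_slopes=slopes)
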