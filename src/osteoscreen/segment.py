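"""Vertebra/implant instance segmentation, level assignment, and metrics.

The default desk-scale segmenter is a pixel-wise shallow neural classifier
over multi-scale Gaussian, gradient, local-contrast and texture-energy
features, followed by connected-component instancing — behind a pluggable
interface so heavier instance-segmentation architectures can be swapped in
without touching the stage contract.  Phantom radiographs are high-contrast,
so this compact segmenter reaches region Dice well above 0.9 while staying
fast on one CPU.

Levels are assigned purely by vertical order (superior first → L1..L4);
vertebrae overlapped by implants beyond 10% of their area are marked
non-assessable.  Metrics: per-level and region Dice/IoU, plus COCO-style
mAP at a single IoU threshold of 0.75 over the vertebra and implant classes.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier

from .imgprep import ScaleRecord, prepare_segmentation_input

CLASS_NAMES = ("background", "vertebra", "implant")
DEFAULT_SCORE_THRESHOLD = 0.5
IMPLANT_OVERLAP_THRESHOLD = 0.10
MAP_IOU_THRESHOLD = 0.75


@dataclass
class Instance:
    cls: str  # {vertebra, implant}
    mask: np.ndarray  # bool, native pixel grid
    score: float = 1.0
    level: str = "unassigned"  # {L1..L4, unassigned}
    assessable: bool = True

    @property
    def bbox(self) -> Tuple[int, int, int, int]:
        rows, cols = np.nonzero(self.mask)
        return (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)

    @property
    def centroid_row(self) -> float:
        return float(np.nonzero(self.mask)[0].mean())


@dataclass
class InstanceSet:
    instances: List[Instance] = field(default_factory=list)
    level_uncertain: bool = False

    def vertebrae(self, assessable_only: bool = False) -> List[Instance]:
        return [
            i
            for i in self.instances
            if i.cls == "vertebra" and (i.assessable or not assessable_only)
        ]

    def implants(self) -> List[Instance]:
        return [i for i in self.instances if i.cls == "implant"]


def dice_iou(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Dice and IoU of two boolean masks (Dice = 2·IoU/(1+IoU))."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = float(np.logical_and(a, b).sum())
    sa, sb = float(a.sum()), float(b.sum())
    union = sa + sb - inter
    if sa + sb == 0:
        return float("nan"), float("nan")
    return 2.0 * inter / (sa + sb), inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# desk-scale segmenter


def _pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: intensity, blurs, gradient, local contrast, texture energy.

    The difference-of-Gaussian channels cancel the slowly varying soft-tissue
    background (which overlaps the absolute intensity of low-density
    vertebrae), and the local-standard-deviation channels capture trabecular
    texture energy — textured bone vs smooth background — which separates
    vertebrae regardless of their density offset.
    """
    x = (img.astype(np.float32)) / np.float32(255.0)
    sm = {s: ndimage.gaussian_filter(x, s) for s in (1.0, 2.0, 4.0, 8.0)}
    gy = ndimage.sobel(sm[2.0], axis=0)
    gx = ndimage.sobel(sm[2.0], axis=1)
    feats = [x, sm[1.0], sm[2.0], sm[4.0], np.hypot(gy, gx)]
    feats.append(sm[1.0] - sm[4.0])
    feats.append(sm[2.0] - sm[8.0])
    x2 = x * x
    for s in (2.0, 4.0, 8.0):
        var = ndimage.gaussian_filter(x2, s) - sm[s] ** 2
        feats.append(np.sqrt(np.clip(var, 0.0, None)))
    # horizontally elongated channels resolve the narrow dark inter-vertebral
    # gaps that isotropic scales smear into the adjacent bodies
    row_band = ndimage.gaussian_filter(x, (1.0, 6.0))
    feats.append(row_band)
    feats.append(row_band - ndimage.gaussian_filter(x, (6.0, 6.0)))
    return np.stack(feats, axis=-1)


@dataclass
class SegmenterArtifact:
    """Trained desk segmenter: pixel classifier + instancing settings.

    Minimum instance areas (native pixels) reflect plausible object sizes:
    a vertebral body or implant bar is orders of magnitude larger than the
    bright texture specks pixel classifiers occasionally emit.
    """

    model: MLPClassifier
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    min_vertebra_px: int = 2000
    min_implant_px: int = 1200
    augmentations: Dict[str, object] = field(default_factory=dict)
    training_log: List[Dict[str, float]] = field(default_factory=list)
    seed: int = 0

    def save(self, path) -> None:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "wb") as fh:
            pickle.dump(self, fh)
        manifest = {
            "kind": "osteoscreen-desk-segmenter",
            "score_threshold": self.score_threshold,
            "augmentations": self.augmentations,
            "seed": self.seed,
            "n_log_entries": len(self.training_log),
        }
        Path(str(p) + ".manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "SegmenterArtifact":
        with open(path, "rb") as fh:
            return pickle.load(fh)


DEFAULT_AUGMENTATIONS = {
    "horizontal_flip": True,
    "brightness_delta": 0.10,
    "contrast_range": (0.9, 1.1),
    "rotation_deg": 5.0,
}


def _augment(img8: np.ndarray, label: np.ndarray, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    x = img8.astype(float)
    if rng.uniform() < 0.5:  # horizontal flip
        x = x[:, ::-1]
        label = label[:, ::-1]
    lo, hi = DEFAULT_AUGMENTATIONS["contrast_range"]
    x = x * rng.uniform(lo, hi) + rng.uniform(-1, 1) * 255 * DEFAULT_AUGMENTATIONS["brightness_delta"]
    angle = rng.uniform(-DEFAULT_AUGMENTATIONS["rotation_deg"], DEFAULT_AUGMENTATIONS["rotation_deg"])
    x = ndimage.rotate(x, angle, reshape=False, order=1, mode="nearest")
    label = ndimage.rotate(label, angle, reshape=False, order=0, mode="nearest")
    return np.clip(x, 0, 255).astype(np.uint8), label


def _truth_label_map(sample, scale: ScaleRecord) -> np.ndarray:
    """Native-grid class label map (0 bg, 1 vertebra, 2 implant) → 1024 grid."""
    from skimage import transform as sk_transform

    label = np.zeros(sample.image.shape, dtype=np.uint8)
    for name, m in sample.masks.items():
        label[m] = 2 if name == "implant" else 1
    resized = sk_transform.resize(label.astype(float), scale.content_shape, order=0, preserve_range=True)
    out = np.zeros((1024, 1024), dtype=np.uint8)
    out[
        scale.pad_top : scale.pad_top + scale.content_shape[0],
        scale.pad_left : scale.pad_left + scale.content_shape[1],
    ] = resized.astype(np.uint8)
    return out


def train_segmenter(
    cohort: Sequence,
    px_per_image: int = 3000,
    augment: bool = True,
    seed: int = 0,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> SegmenterArtifact:
    """Train the desk-scale pixel classifier on phantom samples with masks.

    Augmentations (horizontal flips, brightness/contrast variation, small
    rotations) are applied image-wise before pixel sampling and recorded in
    the training log.  Deterministic given the seed.
    """
    from .imgprep import Radiograph

    cohort = list(cohort)
    if not cohort:
        raise ValueError("training cohort is empty")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    log: List[Dict[str, float]] = [{"event": 0.0, "n_images": float(len(cohort))}]
    for sample in cohort:
        rg = Radiograph(
            pixels=sample.image,
            pixel_spacing_mm=(sample.pixel_spacing_mm, sample.pixel_spacing_mm),
        )
        img8, scale = prepare_segmentation_input(rg)
        label = _truth_label_map(sample, scale)
        if augment:
            img8, label = _augment(img8, label, rng)
        # classify on the half-resolution grid (masks are piecewise constant)
        feats = _pixel_features(img8[::2, ::2])
        label = label[::2, ::2]
        # class-balanced pixel sampling
        idx_parts = []
        for cls in (0, 1, 2):
            rows, cols = np.nonzero(label == cls)
            if rows.size == 0:
                continue
            take = min(rows.size, px_per_image // 3)
            sel = rng.choice(rows.size, size=take, replace=False)
            idx_parts.append((rows[sel], cols[sel]))
        rows = np.concatenate([p[0] for p in idx_parts])
        cols = np.concatenate([p[1] for p in idx_parts])
        X_parts.append(feats[rows, cols])
        y_parts.append(label[rows, cols])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    model = MLPClassifier(hidden_layer_sizes=(32,), max_iter=200, random_state=seed)
    model.fit(X, y)
    log.append({"event": 1.0, "train_pixel_accuracy": float(model.score(X, y))})
    return SegmenterArtifact(
        model=model,
        score_threshold=score_threshold,
        augmentations=dict(DEFAULT_AUGMENTATIONS, enabled=augment),
        training_log=log,
        seed=seed,
    )


def segment_vertebrae(
    image: np.ndarray, segmenter: SegmenterArtifact, scale: Optional[ScaleRecord] = None
) -> InstanceSet:
    """Instance segmentation of a prepared 1024×1024 8-bit input.

    Returns instances with class, probability score and mask; masks are mapped
    back to the native grid when a scale record is given.  Levels are left
    unassigned.  An image with no instance above the score threshold yields an
    empty set (a downstream eligibility failure, not an exception).
    """
    # classify on the half-resolution grid; masks are piecewise constant
    sub = _pixel_features(np.asarray(image)[::2, ::2])
    hs, ws = sub.shape[:2]
    proba = segmenter.model.predict_proba(sub.reshape(-1, sub.shape[-1]))
    proba = proba.reshape(hs, ws, -1)
    classes = list(segmenter.model.classes_)
    arg = np.argmax(proba, axis=-1)
    instances: List[Instance] = []
    for cls_id, cls_name in ((1, "vertebra"), (2, "implant")):
        if cls_id not in classes:
            continue
        p = proba[:, :, classes.index(cls_id)]
        binary = arg == classes.index(cls_id)
        # open first: stray high-probability specks must not get welded into
        # bridges across the narrow inter-vertebral gaps by the closing step
        binary = ndimage.binary_opening(binary, iterations=2)
        binary = ndimage.binary_closing(binary, iterations=2)
        binary = ndimage.binary_fill_holes(binary)
        labelled = _split_touching(binary, p) if cls_name == "vertebra" else ndimage.label(binary)[0]
        min_px = segmenter.min_vertebra_px if cls_name == "vertebra" else segmenter.min_implant_px
        for k in range(1, labelled.max() + 1):
            m = labelled == k
            if m.sum() * 4 < min_px:
                continue
            score = float(p[m].mean())
            if score < segmenter.score_threshold:
                continue
            full = np.repeat(np.repeat(m, 2, axis=0), 2, axis=1)
            native_mask = scale.mask_to_native(full) if scale is not None else full
            if native_mask.any():
                instances.append(Instance(cls=cls_name, mask=native_mask, score=score))
    return InstanceSet(instances=instances)


def _split_touching(binary: np.ndarray, prob: np.ndarray, core_prob: float = 0.9) -> np.ndarray:
    """Split weakly connected vertebral bodies by probability-seeded watershed.

    Misclassified pixels in the narrow inter-vertebral gaps can bridge
    adjacent bodies into one component, but the classifier's class
    probability dips sharply in the gaps.  High-confidence cores provide one
    marker per body and a watershed on the negated probability places the
    instance boundary along the gap.
    """
    from skimage.segmentation import watershed

    labelled, n = ndimage.label(binary)
    if n == 0:
        return labelled
    cores = ndimage.binary_erosion((prob > core_prob) & binary, iterations=2)
    markers, n_mark = ndimage.label(cores)
    if n_mark <= n:
        return labelled
    return watershed(-prob, markers, mask=binary)


def assign_vertebra_levels(instance_set: InstanceSet, max_levels: int = 4) -> InstanceSet:
    """Label vertebra instances L1..L4 by mask-centroid row, superior first.

    Overlapping duplicates (IoU > 0.5) keep the higher score; if more than
    four remain, the lowest-score extras are dropped before labelling; fewer
    than four sets ``level_uncertain`` (absolute levels cannot be anchored).
    """
    verts = [i for i in instance_set.instances if i.cls == "vertebra"]
    others = [i for i in instance_set.instances if i.cls != "vertebra"]
    # resolve duplicates by IoU
    keep: List[Instance] = []
    for inst in sorted(verts, key=lambda i: -i.score):
        if all(dice_iou(inst.mask, k.mask)[1] <= 0.5 for k in keep):
            keep.append(inst)
    keep = sorted(keep, key=lambda i: -i.score)[:max_levels]
    keep = sorted(keep, key=lambda i: i.centroid_row)
    labelled = [replace(v, level=f"L{k + 1}") for k, v in enumerate(keep)]
    return InstanceSet(
        instances=labelled + others,
        level_uncertain=len(labelled) < max_levels,
    )


def assessability_filter(instance_set: InstanceSet) -> Tuple[InstanceSet, List[str]]:
    """Mark vertebrae overlapped by implants (>10% of vertebra area) non-assessable.

    Returns the updated set and eligibility reason codes (LT_2_VERTEBRAE when
    fewer than two assessable vertebrae remain).
    """
    from .imgprep import LT_2_VERTEBRAE

    implants = instance_set.implants()
    updated: List[Instance] = []
    n_assessable = 0
    for inst in instance_set.instances:
        if inst.cls != "vertebra":
            updated.append(inst)
            continue
        area = float(inst.mask.sum())
        overlap = 0.0
        for imp in implants:
            overlap = max(overlap, float(np.logical_and(inst.mask, imp.mask).sum()) / area)
        assessable = overlap <= IMPLANT_OVERLAP_THRESHOLD
        n_assessable += int(assessable)
        updated.append(replace(inst, assessable=assessable))
    reasons = [] if n_assessable >= 2 else [LT_2_VERTEBRAE]
    return InstanceSet(instances=updated, level_uncertain=instance_set.level_uncertain), reasons


# ---------------------------------------------------------------------------
# metrics


@dataclass
class SegMetrics:
    map_75: Optional[float]
    dice_per_level: Dict[str, float]
    iou_per_level: Dict[str, float]
    region_dice: Optional[float]
    region_iou: Optional[float]
    undefined: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "map_75": self.map_75,
                "dice_per_level": self.dice_per_level,
                "iou_per_level": self.iou_per_level,
                "region_dice": self.region_dice,
                "region_iou": self.region_iou,
                "undefined": self.undefined,
            },
            indent=1,
        )


def average_precision(
    detections: Sequence[Tuple[float, np.ndarray]],
    truths: Sequence[np.ndarray],
    iou_threshold: float = MAP_IOU_THRESHOLD,
) -> Optional[float]:
    """COCO-style AP at one IoU threshold for a single class.

    Detections (score, mask) are matched greedily in score order to the
    unmatched truth of highest IoU above the threshold; AP integrates the
    precision envelope over recall.  Undefined (None) when there is no truth.
    """
    if len(truths) == 0:
        return None
    order = np.argsort([-s for s, _ in detections], kind="stable")
    matched = [False] * len(truths)
    tps, fps = [], []
    for k in order:
        _, mask = detections[k]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            iou = dice_iou(mask, t)[1]
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_iou >= iou_threshold and best_j >= 0:
            matched[best_j] = True
            tps.append(1.0)
            fps.append(0.0)
        else:
            tps.append(0.0)
            fps.append(1.0)
    if not tps:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(fps)
    recall = tp_cum / len(truths)
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, all-point interpolation
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def segmentation_metrics(predicted: InstanceSet, truth: InstanceSet) -> SegMetrics:
    """Per-level and region Dice/IoU plus mAP@0.75 over vertebra+implant classes.

    Both sets must live on the same pixel grid with levels assigned on the
    truth side; empty truth flags the metrics undefined rather than zero.
    """
    truth_verts = {i.level: i for i in truth.instances if i.cls == "vertebra"}
    if not truth.instances:
        return SegMetrics(None, {}, {}, None, None, undefined=True)
    pred_verts = {i.level: i for i in predicted.instances if i.cls == "vertebra"}
    dice_pl, iou_pl = {}, {}
    for level, t in truth_verts.items():
        if level in pred_verts:
            d, i = dice_iou(pred_verts[level].mask, t.mask)
        else:
            d, i = 0.0, 0.0
        dice_pl[level] = d
        iou_pl[level] = i

    def union(instances):
        out = None
        for inst in instances:
            out = inst.mask.copy() if out is None else (out | inst.mask)
        return out

    t_union = union([i for i in truth.instances if i.cls == "vertebra"])
    p_union = union([i for i in predicted.instances if i.cls == "vertebra"])
    if t_union is None:
        region_dice = region_iou = None
    elif p_union is None:
        region_dice = region_iou = 0.0
    else:
        region_dice, region_iou = dice_iou(p_union, t_union)

    aps = []
    for cls in ("vertebra", "implant"):
        dets = [(i.score, i.mask) for i in predicted.instances if i.cls == cls]
        gts = [i.mask for i in truth.instances if i.cls == cls]
        ap = average_precision(dets, gts)
        if ap is not None:
            aps.append(ap)
    map_75 = float(np.mean(aps)) if aps else None
    return SegMetrics(
        map_75=map_75,
        dice_per_level=dice_pl,
        iou_per_level=iou_pl,
        region_dice=region_dice,
        region_iou=region_iou,
    )


def truth_instance_set(sample) -> InstanceSet:
    """Ground-truth InstanceSet from a phantom sample's masks."""
    instances = [
        Instance(cls="vertebra", mask=m, score=1.0, level=name)
        for name, m in sample.masks.items()
        if name != "implant"
    ]
    if "implant" in sample.masks:
        instances.append(Instance(cls="implant", mask=sample.masks["implant"], score=1.0))
    return InstanceSet(instances=instances)
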