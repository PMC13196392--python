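"""Very-high-bone-fragility classifier: training regime and decision rule.

The model (see :mod:`osteoscreen.nn`) is a pooling-token-mixer backbone with
two parallel 16-unit fully-connected heads supervised for osteoporosis and
degraded TBS; their activations are fused with standardised age, sex, GLCM
descriptors and the raw-TBS variogram slope, ending in a 2-way softmax.

Optimisation is SGD with momentum 0.9 and weight decay 1e-4.  Early stopping
monitors validation accuracy: training stops when the best value has not
improved by at least 0.005 for 40 consecutive epochs, and the best-epoch
weights are restored.  The operating point is the smallest threshold on
p(very_high) whose validation specificity reaches the configured target —
the specificity-prioritised decision rule of an opportunistic screening
tool; without a target, argmax applies.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import transform as sk_transform

from .nn import ArchConfig, PoolMixerNet, SGD
from .texture import TextureFeatures, glcm_feature_names

N_ENGINEERED = 17  # age, sex, 2 missingness flags, raw_tbs, 12 GLCM descriptors


@dataclass
class TrainConfig:
    """Optimisation settings; defaults are the full-scale regime, the desk
    profile scales them for from-scratch training on one CPU."""

    learning_rate: float = 1e-4
    batch_size: int = 128
    momentum: float = 0.9
    weight_decay: float = 1e-4
    early_stop_min_delta: float = 0.005
    early_stop_patience_epochs: int = 40
    max_epochs: int = 500
    aux_loss_weight: float = 0.5
    lr_schedule: str = "cosine"  # {constant, cosine}
    seed: int = 0
    lr_grid: Tuple[float, ...] = (0.01, 0.001, 0.0001, 0.00003, 0.000001, 0.0000003)
    batch_grid: Tuple[int, ...] = (16, 32, 64, 128, 256, 512, 1024)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning rate and batch size must be positive")
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")

    @classmethod
    def desk_profile(cls, seed: int = 0, max_epochs: int = 100) -> "TrainConfig":
        """Desk-scale settings: lr 0.01 (from the search grid) and batch 32,
        suited to a small from-scratch backbone on a few hundred phantoms."""
        return cls(learning_rate=0.01, batch_size=32, max_epochs=max_epochs, seed=seed)


@dataclass
class FusionInput:
    """One classification case: equalised ROI at 0.2 mm/px plus fusion scalars.

    ``vertebra_centers`` are (row, col) centroids of the assessable vertebrae
    in ROI coordinates; they guide native-resolution texture sampling for the
    network input."""

    roi: np.ndarray
    age_years: Optional[float]
    sex: Optional[str]  # {F, M}
    texture: TextureFeatures
    vertebra_centers: Optional[List[Tuple[int, int]]] = None

    def engineered_raw(self) -> Tuple[np.ndarray, np.ndarray]:
        """Unstandardised scalar vector and missingness flags (age, sex)."""
        age_missing = self.age_years is None
        sex_missing = self.sex not in ("F", "M")
        age = float("nan") if age_missing else float(self.age_years)
        sex_code = float("nan") if sex_missing else (1.0 if self.sex == "F" else 0.0)
        vec = np.concatenate([[age, sex_code, self.texture.raw_tbs], self.texture.glcm_vector()])
        return vec, np.array([float(age_missing), float(sex_missing)])


@dataclass
class FeatureScaler:
    """Train-split standardisation for the fusion scalars.

    Missing age/sex are imputed with the train-split median age / majority
    sex; the missingness flags ride along unscaled.  A version stamp guards
    against predicting with a mismatched scaler.
    """

    mean: np.ndarray
    std: np.ndarray
    impute_age: float
    impute_sex: float
    version: str = "v1"

    @classmethod
    def fit(cls, raw_vectors: np.ndarray) -> "FeatureScaler":
        v = np.asarray(raw_vectors, dtype=float)
        ages, sexes = v[:, 0], v[:, 1]
        impute_age = float(np.nanmedian(ages)) if np.isfinite(ages).any() else 65.0
        impute_sex = float(np.round(np.nanmean(sexes))) if np.isfinite(sexes).any() else 1.0
        filled = cls._impute_static(v, impute_age, impute_sex)
        mean = filled.mean(axis=0)
        std = filled.std(axis=0)
        std[std < 1e-9] = 1.0
        return cls(mean=mean, std=std, impute_age=impute_age, impute_sex=impute_sex)

    @staticmethod
    def _impute_static(v: np.ndarray, impute_age: float, impute_sex: float) -> np.ndarray:
        out = v.copy()
        out[np.isnan(out[:, 0]), 0] = impute_age
        out[np.isnan(out[:, 1]), 1] = impute_sex
        out[:, 2:] = np.nan_to_num(out[:, 2:], nan=0.0)
        return out

    def transform(self, raw_vectors: np.ndarray, flags: np.ndarray) -> np.ndarray:
        v = self._impute_static(np.atleast_2d(raw_vectors), self.impute_age, self.impute_sex)
        return np.concatenate([(v - self.mean) / self.std, np.atleast_2d(flags)], axis=1)


def _crop_at(roi: np.ndarray, center: Tuple[int, int], size: int) -> np.ndarray:
    r0 = max(0, int(center[0]) - size // 2)
    c0 = max(0, int(center[1]) - size // 2)
    crop = roi[r0 : r0 + size, c0 : c0 + size]
    if crop.shape != (size, size):
        crop = np.pad(crop, ((0, size - crop.shape[0]), (0, size - crop.shape[1])), mode="edge")
    return crop


def roi_to_input(
    roi: np.ndarray,
    input_size: int,
    centers: Optional[Sequence[Tuple[int, int]]] = None,
) -> np.ndarray:
    """Two-plane network input from an equalised ROI (values in [0, 1]).

    Plane 0 is the whole ROI resized to the square input (global bone vs
    soft-tissue contrast); plane 1 samples trabecular texture at the ROI's
    native 0.2 mm/px resolution, which whole-ROI downscaling would low-pass
    away: a 2×2 mosaic of half-size crops centred on the assessable
    vertebrae when their centres are known (cycled if fewer than four),
    otherwise one ROI-centre crop.  Crops beyond the border are edge-padded.
    """
    roi = np.asarray(roi, dtype=float)
    context = sk_transform.resize(
        roi, (input_size, input_size), order=1, anti_aliasing=True, preserve_range=True
    )
    if centers:
        half = input_size // 2
        tiles = [_crop_at(roi, c, half) for c in list(centers)[:4]]
        while len(tiles) < 4:
            tiles.append(tiles[len(tiles) % len(centers)])
        texture = np.block([[tiles[0], tiles[1]], [tiles[2], tiles[3]]])
    else:
        texture = _crop_at(roi, (roi.shape[0] // 2, roi.shape[1] // 2), input_size)
    return np.stack([context, texture])


def build_model(
    arch: Optional[ArchConfig] = None, seed: int = 0, head_width_override: Optional[int] = None
) -> PoolMixerNet:
    """Instantiate the dual-head fusion network (head width 16 unless overridden)."""
    return PoolMixerNet(arch or ArchConfig(), seed=seed, head_width_override=head_width_override)


# ---------------------------------------------------------------------------
# early stopping (pure function of the monitored sequence)


def early_stop_epoch(
    monitor: Sequence[float], min_delta: float = 0.005, patience: int = 40
) -> Tuple[Optional[int], int]:
    """(stop_epoch, best_epoch) for a monitored validation sequence.

    The best epoch is the earliest epoch whose value all later epochs fail to
    exceed by ``min_delta``; training stops at the first epoch lying
    ``patience`` epochs after the current best without such an improvement.
    ``stop_epoch`` is None when the criterion never fires within the sequence.
    Epochs are 0-based indices into ``monitor``.
    """
    best_val = -math.inf
    best_epoch = 0
    for e, val in enumerate(monitor):
        if val >= best_val + min_delta or e == 0:
            best_val = val
            best_epoch = e
        elif e - best_epoch >= patience:
            return e, best_epoch
    return None, best_epoch


# ---------------------------------------------------------------------------
# training


@dataclass
class Dataset:
    """Arrays for one split: network inputs, fusion scalars, and the three labels."""

    images: np.ndarray  # (N, S, S)
    engineered: np.ndarray  # (N, n_engineered) — standardised
    y_vhbf: np.ndarray
    y_osteo: np.ndarray
    y_degraded: np.ndarray
    subject_ids: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class TrainedClassifier:
    model: PoolMixerNet
    scaler: FeatureScaler
    config: TrainConfig
    history: List[Dict[str, float]] = field(default_factory=list)
    operating_threshold: Optional[float] = None
    best_epoch: int = 0

    def save(self, path) -> None:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "arch": asdict(self.model.cfg),
            "state": self.model.state_dict(),
            "scaler": self.scaler,
            "config": asdict(self.config),
            "history": self.history,
            "operating_threshold": self.operating_threshold,
            "best_epoch": self.best_epoch,
            "seed": self.model.seed,
        }
        with open(p, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        cfg = TrainConfig(**payload["config"])
        model = PoolMixerNet(ArchConfig(**payload["arch"]), seed=payload["seed"])
        model.load_state_dict(payload["state"])
        out = cls(model=model, scaler=payload["scaler"], config=cfg)
        out.history = payload["history"]
        out.operating_threshold = payload["operating_threshold"]
        out.best_epoch = payload["best_epoch"]
        return out


def train_classifier(
    train: Dataset,
    val: Dataset,
    config: Optional[TrainConfig] = None,
    arch: Optional[ArchConfig] = None,
    scaler: Optional[FeatureScaler] = None,
) -> TrainedClassifier:
    """SGD training with stratified shuffling, early stopping and best-epoch restore.

    The total loss is the very-high softmax cross-entropy plus 0.5-weighted
    binary cross-entropies on the osteoporosis and degraded-TBS heads.
    Deterministic given the config seed.
    """
    cfg = config or TrainConfig()
    if len(set(train.y_vhbf.tolist())) < 2:
        raise ValueError("training split must contain both classes")
    arch = arch or ArchConfig()
    model = PoolMixerNet(arch, seed=cfg.seed)
    opt = SGD(model.params, lr=cfg.learning_rate, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train)
    history: List[Dict[str, float]] = []
    best_state = model.state_dict()
    monitor: List[float] = []
    for epoch in range(cfg.max_epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1.0 + math.cos(math.pi * epoch / cfg.max_epochs))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(
                train.images[idx],
                train.engineered[idx],
                train.y_vhbf[idx],
                train.y_osteo[idx],
                train.y_degraded[idx],
                aux_weight=cfg.aux_loss_weight,
            )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        out = model.forward(val.images, val.engineered)
        val_acc = float((np.argmax(out["probs"], axis=1) == val.y_vhbf).mean())
        val_loss = float(-np.log(out["probs"][np.arange(len(val)), val.y_vhbf] + 1e-12).mean())
        monitor.append(val_acc)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(1, n_batches),
                "val_accuracy": val_acc,
                "val_loss": val_loss,
            }
        )
        stop, best = early_stop_epoch(monitor, cfg.early_stop_min_delta, cfg.early_stop_patience_epochs)
        if best == epoch:
            best_state = model.state_dict()
        if stop is not None:
            break
    _, best_epoch = early_stop_epoch(monitor, cfg.early_stop_min_delta, cfg.early_stop_patience_epochs)
    model.load_state_dict(best_state)
    trained = TrainedClassifier(
        model=model,
        scaler=scaler if scaler is not None else FeatureScaler(
            mean=np.zeros(N_ENGINEERED - 2), std=np.ones(N_ENGINEERED - 2), impute_age=65.0, impute_sex=1.0
        ),
        config=cfg,
        history=history,
        best_epoch=best_epoch,
    )
    return trained


def grid_search(
    train: Dataset,
    val: Dataset,
    base_config: Optional[TrainConfig] = None,
    lr_subset: Optional[Sequence[float]] = None,
    batch_subset: Optional[Sequence[int]] = None,
    arch: Optional[ArchConfig] = None,
) -> Tuple[TrainedClassifier, List[Dict[str, float]]]:
    """Search a subset of the (learning rate × batch size) grid.

    Candidates default to the configured ``lr_grid``/``batch_grid``; pass
    subsets to keep desk runs short.  Returns the model with the best final
    validation accuracy and the per-combination leaderboard.
    """
    base = base_config or TrainConfig()
    lrs = tuple(lr_subset) if lr_subset is not None else base.lr_grid
    batches = tuple(batch_subset) if batch_subset is not None else base.batch_grid
    best: Optional[TrainedClassifier] = None
    best_acc = -1.0
    leaderboard: List[Dict[str, float]] = []
    for lr in lrs:
        for bs in batches:
            cfg = TrainConfig(
                **{
                    **{f: getattr(base, f) for f in (
                        "momentum", "weight_decay", "early_stop_min_delta",
                        "early_stop_patience_epochs", "max_epochs", "aux_loss_weight",
                        "lr_schedule", "seed", "lr_grid", "batch_grid",
                    )},
                    "learning_rate": lr,
                    "batch_size": int(bs),
                }
            )
            trained = train_classifier(train, val, cfg, arch=arch)
            acc = max(h["val_accuracy"] for h in trained.history)
            leaderboard.append({"learning_rate": lr, "batch_size": float(bs), "val_accuracy": acc})
            if acc > best_acc:
                best_acc, best = acc, trained
    return best, leaderboard


def predict(trained: TrainedClassifier, dataset: Dataset) -> Dict[str, np.ndarray]:
    """Class and per-head probabilities for a prepared dataset.

    Applies the persisted operating threshold when present, argmax otherwise.
    """
    out = trained.model.forward(dataset.images, dataset.engineered)
    p_vhbf = out["probs"][:, 1]
    if trained.operating_threshold is not None:
        decision = (p_vhbf >= trained.operating_threshold).astype(int)
    else:
        decision = np.argmax(out["probs"], axis=1)
    return {
        "p_vhbf": p_vhbf,
        "p_not": out["probs"][:, 0],
        "p_osteoporosis_head": out["p_headA"],
        "p_degraded_head": out["p_headB"],
        "decision": decision,
    }


def select_operating_threshold(
    val_scores: Sequence[float], val_labels: Sequence[int], min_specificity: float = 0.90
) -> Tuple[float, Dict[str, float]]:
    """Smallest threshold achieving the target specificity on validation.

    Decisions are positive at score >= threshold.  Returns the threshold and
    the (specificity, sensitivity) achieved at it; an unattainable target
    returns threshold 1.0 (allowing only scores exactly 1.0 through) with a
    warning entry in the diagnostics.
    """
    s = np.asarray(val_scores, dtype=float)
    y = np.asarray(val_labels).astype(bool)
    if len(s) == 0 or not y.any() or y.all():
        raise ValueError("validation scores must contain both classes")
    neg, pos = s[~y], s[y]
    candidates = np.concatenate([[0.0], np.unique(s)])
    for th in candidates:
        spec = float((neg < th).mean())
        if spec >= min_specificity:
            sens = float((pos >= th).mean())
            return float(th), {"specificity": spec, "sensitivity": sens, "attained": 1.0}
    return 1.0, {
        "specificity": float((neg < 1.0).mean()),
        "sensitivity": float((pos >= 1.0).mean()),
        "attained": 0.0,
    }
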