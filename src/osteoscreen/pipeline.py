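"""End-to-end orchestration: phantom cohort → segmentation → features →
training → specificity-prioritised evaluation → explainability.

Each stage is usable on its own; :func:`run_pipeline` chains them on a
phantom cohort and writes all artifacts (manifest, features, predictions,
metrics, attrition, checkpoints, resolved config) into a run directory.
Classifier training consumes reference (ground-truth) vertebra masks — the
annotation-equivalent path — while the held-out evaluation can run fully
automatically through the trained segmenter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classifier as clf
from . import evaluate as ev
from . import segment as seg
from .imgprep import Radiograph, check_eligibility, prepare_classification_roi, prepare_segmentation_input
from .nn import ArchConfig
from .phantom import PhantomConfig, PhantomSample, generate_cohort
from .texture import compute_texture_block, glcm_feature_names


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    n_phantoms: int = 200
    class_mix: float = 0.2
    seed: int = 0
    min_specificity: float = 0.90
    seg_train_n: int = 40
    input_size: int = 64
    max_epochs: int = 100
    use_segmenter_for_test: bool = True
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def to_dict(self) -> Dict:
        d = asdict(self)
        return d


def sample_to_radiograph(sample: PhantomSample) -> Radiograph:
    return Radiograph(
        pixels=sample.image,
        pixel_spacing_mm=(sample.pixel_spacing_mm, sample.pixel_spacing_mm),
        age_years=sample.age_years,
        sex=sample.sex,
        acquisition_date=sample.acquisition_date,
        subject_id=sample.subject_id,
        image_id=sample.subject_id,
    )


def segment_sample(sample: PhantomSample, segmenter: seg.SegmenterArtifact) -> seg.InstanceSet:
    """Automatic path: prepare → segment → assign levels (native-grid masks)."""
    rg = sample_to_radiograph(sample)
    img8, scale = prepare_segmentation_input(rg)
    instances = seg.segment_vertebrae(img8, segmenter, scale)
    return seg.assign_vertebra_levels(instances)


def extract_case(
    sample: PhantomSample,
    segmenter: Optional[seg.SegmenterArtifact] = None,
) -> Optional[clf.FusionInput]:
    """Full per-case feature extraction; None when the case is not assessable.

    With ``segmenter=None`` the reference masks are used (annotation path);
    otherwise segmentation runs automatically.
    """
    rg = sample_to_radiograph(sample)
    if segmenter is None:
        instances = seg.truth_instance_set(sample)
        instances = seg.assign_vertebra_levels(instances)
    else:
        instances = segment_sample(sample, segmenter)
    assessable, reasons = seg.assessability_filter(instances)
    eligibility = check_eligibility(rg, sample.dxa, len(assessable.vertebrae(assessable_only=True)))
    if reasons or not eligibility.eligible:
        return None
    keep = seg.InstanceSet(
        instances=[i for i in assessable.instances if i.cls == "vertebra" and i.assessable],
        level_uncertain=assessable.level_uncertain,
    )
    roi, rec = prepare_classification_roi(rg, keep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        texture = compute_texture_block(rg, keep)
    centers = []
    for inst in sorted(keep.instances, key=lambda i: i.level):
        rows, cols = np.nonzero(inst.mask)
        centers.append(
            (
                int((rows.mean() - rec.native_box[0]) * rec.resample_factor),
                int((cols.mean() - rec.native_box[2]) * rec.resample_factor),
            )
        )
    return clf.FusionInput(
        roi=roi, age_years=rg.age_years, sex=rg.sex, texture=texture, vertebra_centers=centers
    )


def build_datasets(
    samples: Sequence[PhantomSample],
    manifest: pd.DataFrame,
    input_size: int = 64,
    segmenter_for_test: Optional[seg.SegmenterArtifact] = None,
) -> Tuple[Dict[str, clf.Dataset], clf.FeatureScaler, pd.DataFrame]:
    """Assemble per-split datasets; the scaler is fitted on the train split only."""
    cases: Dict[str, List] = {"train": [], "val": [], "test": []}
    rows = []
    by_id = {s.subject_id: s for s in samples}
    for _, row in manifest.iterrows():
        sample = by_id[row["subject_id"]]
        segm = segmenter_for_test if (segmenter_for_test is not None and row["split"] == "test") else None
        fusion = extract_case(sample, segm)
        if fusion is None:
            rows.append({"subject_id": sample.subject_id, "split": row["split"], "included": False})
            continue
        raw, flags = fusion.engineered_raw()
        cases[row["split"]].append(
            {
                "image": clf.roi_to_input(fusion.roi, input_size, fusion.vertebra_centers),
                "raw": raw,
                "flags": flags,
                "y_vhbf": int(sample.label.is_very_high),
                "y_osteo": int(sample.label.osteoporosis),
                "y_degraded": int(sample.label.degraded_tbs),
                "subject_id": sample.subject_id,
                "raw_tbs": float(fusion.texture.raw_tbs),
            }
        )
        rows.append({"subject_id": sample.subject_id, "split": row["split"], "included": True})
    if not cases["train"]:
        raise ValueError("no assessable training cases")
    scaler = clf.FeatureScaler.fit(np.array([c["raw"] for c in cases["train"]]))
    datasets = {}
    for split, items in cases.items():
        if not items:
            datasets[split] = None
            continue
        eng = scaler.transform(
            np.array([c["raw"] for c in items]), np.array([c["flags"] for c in items])
        )
        datasets[split] = clf.Dataset(
            images=np.stack([c["image"] for c in items]),
            engineered=eng,
            y_vhbf=np.array([c["y_vhbf"] for c in items]),
            y_osteo=np.array([c["y_osteo"] for c in items]),
            y_degraded=np.array([c["y_degraded"] for c in items]),
            subject_ids=[c["subject_id"] for c in items],
        )
    return datasets, scaler, pd.DataFrame(rows)


def features_table(datasets: Dict[str, clf.Dataset]) -> pd.DataFrame:
    """Engineered-feature table (one row per case) for CSV export."""
    recs = []
    for split, ds in datasets.items():
        if ds is None:
            continue
        for i, sid in enumerate(ds.subject_ids):
            rec = {"subject_id": sid, "split": split, "y_vhbf": int(ds.y_vhbf[i])}
            scalars = ds.engineered[i]
            names = ["age_std", "sex_std", "raw_tbs_std"] + [n + "_std" for n in glcm_feature_names()] + [
                "age_missing",
                "sex_missing",
            ]
            rec.update({n: float(v) for n, v in zip(names, scalars)})
            recs.append(rec)
    return pd.DataFrame(recs)


def run_pipeline(config: RunConfig, out_dir) -> Dict:
    """Run the whole desk-scale study and write artifacts; returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    try:
        import yaml

        (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    except Exception:
        (out / "resolved_config.json").write_text(json.dumps(cfg.to_dict(), default=str, indent=1))

    samples, manifest = generate_cohort(cfg.n_phantoms, cfg.class_mix, cfg.phantom, seed=cfg.seed)
    manifest.to_csv(out / "manifest.csv", index=False)

    train_samples = [s for s, sp in zip(samples, manifest["split"]) if sp == "train"]
    segmenter = seg.train_segmenter(train_samples[: cfg.seg_train_n], seed=cfg.seed)
    segmenter.save(out / "segmenter.pkl")

    # segmentation quality on the held-out split
    seg_metrics_list = []
    test_samples = [s for s, sp in zip(samples, manifest["split"]) if sp == "test"]
    for s in test_samples[: min(len(test_samples), 20)]:
        pred = segment_sample(s, segmenter)
        truth = seg.truth_instance_set(s)
        m = seg.segmentation_metrics(pred, truth)
        if not m.undefined:
            seg_metrics_list.append(m)
    region_dice = float(np.mean([m.region_dice for m in seg_metrics_list])) if seg_metrics_list else None
    map75_vals = [m.map_75 for m in seg_metrics_list if m.map_75 is not None]
    map_75 = float(np.mean(map75_vals)) if map75_vals else None

    arch = ArchConfig(input_size=cfg.input_size)
    datasets, scaler, inclusion = build_datasets(
        samples,
        manifest,
        input_size=cfg.input_size,
        segmenter_for_test=segmenter if cfg.use_segmenter_for_test else None,
    )
    inclusion.to_csv(out / "inclusion.csv", index=False)
    features_table(datasets).to_csv(out / "features.csv", index=False)

    train_cfg = clf.TrainConfig.desk_profile(seed=cfg.seed, max_epochs=cfg.max_epochs)
    trained = clf.train_classifier(datasets["train"], datasets["val"], train_cfg, arch=arch, scaler=scaler)
    val_pred = clf.predict(trained, datasets["val"])
    threshold, op_diag = clf.select_operating_threshold(
        val_pred["p_vhbf"], datasets["val"].y_vhbf, cfg.min_specificity
    )
    trained.operating_threshold = threshold
    trained.save(out / "classifier.pkl")
    pd.DataFrame(trained.history).to_csv(out / "training_history.csv", index=False)

    test_ds = datasets["test"]
    pred = clf.predict(trained, test_ds)
    pd.DataFrame(
        {
            "subject_id": test_ds.subject_ids,
            "p_vhbf": pred["p_vhbf"],
            "p_osteoporosis_head": pred["p_osteoporosis_head"],
            "p_degraded_head": pred["p_degraded_head"],
            "decision": pred["decision"],
        }
    ).to_csv(out / "predictions.csv", index=False)

    report = ev.metrics_report(test_ds.y_vhbf, pred["decision"], scores=pred["p_vhbf"])
    zones = (
        manifest.set_index("subject_id").loc[test_ds.subject_ids, "label"].tolist()
    )
    nmp = ev.near_miss_precision(pred["decision"].astype(bool), zones)
    attrition = ev.flow_accounting(
        [
            ("generated", cfg.n_phantoms),
            ("not_assessable", int((~inclusion["included"]).sum())),
        ]
    )
    pd.DataFrame(attrition).to_csv(out / "attrition.csv", index=False)

    summary = {
        "n_phantoms": cfg.n_phantoms,
        "seg_region_dice": region_dice,
        "seg_map_75": map_75,
        "operating_threshold": threshold,
        "operating_diagnostics": op_diag,
        "test_metrics": report[0],
        "near_miss_precision": nmp,
        "best_epoch": trained.best_epoch,
        "n_epochs_run": len(trained.history),
    }
    (out / "metrics.json").write_text(json.dumps(summary, default=_json_default, indent=1))
    return {
        "summary": summary,
        "trained": trained,
        "segmenter": segmenter,
        "datasets": datasets,
        "samples": samples,
        "manifest": manifest,
    }


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)
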