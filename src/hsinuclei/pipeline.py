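"""End-to-end orchestration with config, logging, and run manifests.

``run_pipeline`` drives the six stages — calibrate, register, segment,
extract, classify, image-wise — over a simulated cohort (the package
ships no patient data), records per-stage timings and record counts, and
writes CSV result tables plus a JSON manifest sufficient to reproduce
the run bit-identically for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnn import (
    CNNConfig,
    build_model,
    predict_proba,
    select_threshold,
    standardize_patches,
    train,
)
from .cube_io import calibrate_transmittance
from .imagewise import (
    DEFAULT_THRESHOLD_CANDIDATES,
    ConfusionCounts,
    classify_image,
    compute_metrics,
    select_image_threshold,
)
from .registration import AffineTransform, apply_affine, estimate_affine, to_grayscale
from .segmentation import DEFAULT_MIN_AREA, DEFAULT_PATCH_SIZE, extract_patches, segment_cube
from .simulate import (
    SceneSpec,
    generate_calibration_target,
    generate_patient_set,
    misalign_rgb,
)
from .spectra import SpectrumRecord, SVMGrid, fit_svm, grid_search, mean_nucleus_spectrum

__all__ = ["RunConfig", "StageError", "run_pipeline", "configure_logging"]

logger = logging.getLogger(__name__)


def configure_logging(level: int = logging.INFO) -> None:
    """Stage-granular logging to stderr, idempotent."""
    root = logging.getLogger("hsinuclei")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trippable."""

    output_dir: str = "hsinuclei_run"
    seed: int = 0
    # simulated cohort
    n_patients: int = 4
    images_per_patient: int = 4
    scene_shape: tuple[int, int] = (256, 256)
    nuclei_per_image: int = 25
    reversed_fraction: float = 0.0
    tilt_amplitude: float = 0.035
    # session camera misalignment (moving RGB -> fixed HSI), x/y px + deg
    rgb_shift: tuple[float, float] = (6.0, -4.0)
    rgb_rotation_deg: float = 1.0
    #: re-estimate the transform from every slide image pair instead of
    #: reusing the session calibration-target transform
    per_image_registration: bool = False
    # segmentation
    seg_threshold: float = 0.0
    min_area: int = DEFAULT_MIN_AREA
    patch_size: int = DEFAULT_PATCH_SIZE
    # classification
    classifier: str = "svm"  # svm / cnn-rgb / cnn-hsi
    train_patients: list[str] = field(default_factory=list)
    val_patients: list[str] = field(default_factory=list)
    test_patients: list[str] = field(default_factory=list)
    cnn_width_multiplier: float = 1 / 32
    cnn_learning_rate: float = 1e-3
    cnn_max_epochs: int = 10
    # image-wise
    image_threshold_candidates: tuple[float, ...] = DEFAULT_THRESHOLD_CANDIDATES

    def validate(self) -> None:
        if self.classifier not in ("svm", "cnn-rgb", "cnn-hsi"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        parts = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise ValueError(
                        f"patients {sorted(overlap)} appear in more than one partition"
                    )
        if self.min_area < 1 or self.patch_size % 2 == 0:
            raise ValueError("min_area must be >= 1 and patch_size odd")

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("scene_shape", "rgb_shift", "image_threshold_candidates"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("scene_shape", "rgb_shift", "image_threshold_candidates"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _session_transform(config: RunConfig) -> AffineTransform:
    theta = np.deg2rad(config.rgb_rotation_deg)
    dx, dy = config.rgb_shift
    m = np.array([
        [np.cos(theta), -np.sin(theta), dx],
        [np.sin(theta), np.cos(theta), dy],
    ])
    return AffineTransform(m)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> calibrate -> register -> segment -> extract ->
    classify -> image-wise; returns the manifest dict.

    Partition overlaps abort before any stage runs.  On stage failure a
    :class:`StageError` is raised; outputs of completed stages remain in
    ``config.output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                logger.info("stage %s started", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                elapsed = time.perf_counter() - self_inner.t0
                if exc is None:
                    manifest["stages"][name] = {"status": "complete",
                                                "seconds": round(elapsed, 3)}
                    logger.info("stage %s complete (%.2fs)", name, elapsed)
                    return False
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise StageError(name, str(exc)) from exc

        return _Ctx()

    with _stage("simulate"):
        base = SceneSpec(shape=config.scene_shape, n_nuclei=config.nuclei_per_image,
                         tilt_amplitude=config.tilt_amplitude)
        patients = generate_patient_set(
            config.n_patients, config.images_per_patient,
            reversed_fraction=config.reversed_fraction,
            base_spec=base, seed=config.seed,
        )
        t_session = _session_transform(config)
        for p in patients:
            for scene in p.scenes:
                misalign_rgb(scene, t_session)
        manifest["n_patients"] = len(patients)
        manifest["n_images"] = sum(len(p.scenes) for p in patients)

    with _stage("calibrate"):
        calibrated = {}
        for p in patients:
            for i, scene in enumerate(p.scenes):
                calibrated[(p.patient_id, i)] = calibrate_transmittance(
                    scene.raw, scene.references)

    with _stage("register"):
        fixed_t, moving_t = generate_calibration_target(
            config.scene_shape, t_session, seed=config.seed + 17)
        t_est = estimate_affine(to_grayscale(fixed_t), to_grayscale(moving_t),
                                seed=config.seed)
        t_est.to_json(out / "registration.json")
        manifest["registration_inlier_ratio"] = t_est.inlier_ratio
        registered = {}
        margins = {}
        for p in patients:
            for i, scene in enumerate(p.scenes):
                t_use = t_est
                if config.per_image_registration:
                    t_use = estimate_affine(
                        to_grayscale(calibrated[(p.patient_id, i)]),
                        to_grayscale(scene.rgb), seed=config.seed)
                reg, margin = apply_affine(scene.rgb, t_use, config.scene_shape)
                registered[(p.patient_id, i)] = reg
                margins[(p.patient_id, i)] = margin

    with _stage("segment"):
        records = []
        image_rows = []
        for p in patients:
            for i, scene in enumerate(p.scenes):
                key = (p.patient_id, i)
                mask, diff, _ = segment_cube(
                    calibrated[key], threshold=config.seg_threshold,
                    min_area=config.min_area)
                recs = extract_patches(
                    calibrated[key], registered[key], mask,
                    margin_mask=margins[key], size=config.patch_size,
                    label=scene.label, patient_id=p.patient_id,
                    image_id=f"{p.patient_id}-img{i}",
                )
                records.extend(recs)
                image_rows.append({
                    "image_id": f"{p.patient_id}-img{i}",
                    "patient_id": p.patient_id,
                    "truth": scene.label,
                    "n_segmented": mask.n_nuclei,
                    "n_records": len(recs),
                })
        if not records:
            raise RuntimeError("no nucleus records extracted")
        manifest["n_nucleus_records"] = len(records)
        pd.DataFrame(image_rows).to_csv(out / "images.csv", index=False)

    with _stage("classify"):
        if config.classifier == "svm":
            preds = _classify_svm(records, config)
        else:
            preds = _classify_cnn(records, config)
        preds.to_csv(out / "nucleus_predictions.csv", index=False)
        manifest["n_predictions"] = len(preds)

    with _stage("imagewise"):
        image_results, summary = _imagewise(preds, config)
        image_results.to_csv(out / "imagewise.csv", index=False)
        manifest["imagewise"] = summary

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _holdout_split(patients: list[str], config: RunConfig) -> tuple[set, set]:
    """Validation patients for threshold selection vs evaluation patients."""
    if config.val_patients:
        val = set(config.val_patients)
        rest = set(config.test_patients) or (set(patients) - val - set(config.train_patients))
        return val, rest
    half = max(1, len(patients) // 2)
    return set(patients[:half]), set(patients[half:])


def _classify_svm(records, config: RunConfig) -> pd.DataFrame:
    spectra = [
        SpectrumRecord.from_raw(
            mean_nucleus_spectrum(r.hsi_patch, r.mask_patch),
            r.label, r.patient_id, r.image_id, r.nucleus_id,
        )
        for r in records
        if r.mask_patch.any()
    ]
    patients = sorted({s.patient_id for s in spectra})
    rows = []
    grid = SVMGrid()
    for patient in patients:  # leave-one-patient-out predictions
        train_set = [s for s in spectra if s.patient_id != patient]
        held = [s for s in spectra if s.patient_id == patient]
        (C, g), _ = grid_search(train_set, grid, seed=config.seed)
        model = fit_svm(train_set, C, g)
        x = np.stack([s.normalized for s in held])
        pred = model.predict(x)
        for s, yhat in zip(held, pred):
            rows.append({
                "patient_id": s.patient_id, "image_id": s.image_id,
                "nucleus_id": s.nucleus_id, "truth": s.label,
                "predicted": "cancerous" if yhat == 1 else "normal",
                "probability": float(yhat),
            })
    return pd.DataFrame(rows)


def _classify_cnn(records, config: RunConfig) -> pd.DataFrame:
    modality = "hsi" if config.classifier == "cnn-hsi" else "rgb"
    patients = sorted({r.patient_id for r in records})
    train_ids = set(config.train_patients) or set(patients[: max(1, len(patients) // 2)])
    val_ids = set(config.val_patients) or set(
        p for p in patients if p not in train_ids
    )
    def patch(r):
        return r.hsi_patch if modality == "hsi" else r.rgb_patch

    x_train = np.stack([patch(r) for r in records if r.patient_id in train_ids]).astype(np.float32)
    y_train = np.array([r.label == "cancerous" for r in records
                        if r.patient_id in train_ids], dtype=np.float32)
    val_records = [r for r in records if r.patient_id in val_ids]
    x_val = np.stack([patch(r) for r in val_records]).astype(np.float32)
    y_val = np.array([r.label == "cancerous" for r in val_records], dtype=np.float32)
    x_train, x_val = standardize_patches(x_train, x_val)

    cfg = CNNConfig(
        input_channels=x_train.shape[3],
        patch_size=config.patch_size,
        width_multiplier=config.cnn_width_multiplier,
        learning_rate=config.cnn_learning_rate,
        max_epochs=config.cnn_max_epochs,
        kernel_init="he_normal",
        seed=config.seed,
        allow_any_channels=True,
    )
    model = build_model(cfg)
    train(model, x_train, y_train, x_val, y_val,
          train_patients=train_ids, val_patients=val_ids)
    probs = predict_proba(model, x_val)
    thr = select_threshold(probs, y_val > 0.5)
    rows = []
    for r, prob in zip(val_records, probs):
        rows.append({
            "patient_id": r.patient_id, "image_id": r.image_id,
            "nucleus_id": r.nucleus_id, "truth": r.label,
            "predicted": "cancerous" if prob >= thr else "normal",
            "probability": float(prob),
        })
    return pd.DataFrame(rows)


def _imagewise(preds: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict]:
    per_image = []
    for image_id, group in preds.groupby("image_id"):
        calls = (group["predicted"] == "cancerous").to_numpy()
        per_image.append({
            "image_id": image_id,
            "patient_id": group["patient_id"].iloc[0],
            "truth": group["truth"].iloc[0],
            "n_cancer": int(calls.sum()),
            "n_total": int(calls.size),
            "fraction": float(calls.mean()) if calls.size else np.nan,
        })
    table = pd.DataFrame(per_image)
    patients = sorted(table["patient_id"].unique())
    val_ids, eval_ids = _holdout_split(patients, config)
    val_tab = table[table["patient_id"].isin(val_ids)]
    thr = select_image_threshold(
        val_tab["fraction"].to_numpy(),
        (val_tab["truth"] == "cancerous").to_numpy(),
        candidates=config.image_threshold_candidates,
    )
    decisions = []
    for _, row in table.iterrows():
        res = classify_image([True] * row["n_cancer"] + [False] * (row["n_total"] - row["n_cancer"]),
                             thr, image_id=row["image_id"])
        decisions.append(res.decision)
    table["decision"] = decisions
    table["threshold"] = thr
    eval_tab = table[table["patient_id"].isin(eval_ids)]
    truth_pos = eval_tab["truth"] == "cancerous"
    called_pos = eval_tab["decision"] == "cancerous"
    counts = ConfusionCounts(
        tp=int((truth_pos & called_pos).sum()),
        fp=int((~truth_pos & called_pos).sum()),
        tn=int((~truth_pos & ~called_pos).sum()),
        fn=int((truth_pos & ~called_pos).sum()),
    )
    metrics = compute_metrics(counts)
    summary = {
        "threshold": thr,
        "n_eval_images": int(len(eval_tab)),
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
    }
    return table, summary
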