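"""End-to-end orchestration: simulate -> preprocess -> train -> predict -> evaluate.

Each stage writes its artifacts plus the resolved run configuration and the
package version into its own subdirectory of the output directory, so a
completed run is self-describing and reproducible from the single global
seed. Per-stage seeds are derived from the global seed by fixed offsets.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .metrics import MetricReport, RoiSample, evaluate_cohort
from .nn.unet import ModelConfig, build_model, load_checkpoint, predict, save_checkpoint
from .phantom import PhantomSpec, generate_cohort
from .preprocess import PreprocessConfig, preprocess_cohort
from .train import LossConfig, make_folds, split_validation_subjects, train_model
from .volumes import Cohort, Modality, Volume, conform, load_cohort, read_volume, write_volume

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "train", "predict", "evaluate", "all")

# fixed per-stage seed offsets (logged with each stage)
_SEED_OFFSETS = {"simulate": 0, "preprocess": 1000, "train": 2000, "predict": 3000, "evaluate": 4000}

logger = logging.getLogger("petsynth")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    out_dir: str = "petsynth_run"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    # cohort simulation
    n_subjects: int = 20
    max_sessions: int = 3
    group_mix: dict = field(default_factory=lambda: {"HC": 0.3, "KOA": 0.35, "CLB": 0.35})
    genotype_mix: dict = field(default_factory=lambda: {"HAB": 0.6, "MAB": 0.4})
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    # preprocessing
    preprocess: dict = field(default_factory=dict)  # PreprocessConfig overrides
    # model / training; the default overrides are the desk-scale model used
    # for 32-cube phantom studies (the full-size configuration is
    # ModelConfig() with a 96-cube grid)
    model: dict = field(
        default_factory=lambda: {
            "base_channels": 8,
            "n_levels": 3,
            "norm_groups": 8,
            "residual_blocks_per_level": 1,
            "head_kernel": 1,
        }
    )
    alpha: float = 0.5
    k_folds: int = 5
    fold_index: int = 0
    epochs: int = 20
    batch_size: int = 1
    learning_rate: float = 5e-3
    n_restarts: int = 2  # seeded restarts; best final training loss wins
    val_fraction: float = 0.1
    # evaluation
    roi_samples: int = 1000
    roi_shape: tuple[int, int, int] = (4, 4, 3)
    manifest: str = ""  # external cohort manifest; empty -> use simulated cohort
    verbosity: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @staticmethod
    def from_json(s: str) -> "RunConfig":
        d = json.loads(s)
        for key in ("grid_shape", "roi_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return RunConfig(**d)

    # resolved sub-configs -------------------------------------------------
    def phantom_spec(self) -> PhantomSpec:
        kwargs = dict(self.phantom)
        for key in ("shape", "voxel_size_mm", "mri_class_means", "pet_class_uptake"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("shape", tuple(self.grid_shape))
        kwargs.setdefault("seed", self.seed + _SEED_OFFSETS["simulate"])
        return PhantomSpec(**kwargs)

    def preprocess_config(self) -> PreprocessConfig:
        kwargs = dict(self.preprocess)
        if "percentiles" in kwargs:
            kwargs["percentiles"] = tuple(kwargs["percentiles"])
        return PreprocessConfig(**kwargs)

    def model_config(self) -> ModelConfig:
        kwargs = dict(self.model)
        for key in ("channel_multipliers", "attention_levels", "input_shape"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("input_shape", tuple(self.grid_shape))
        return ModelConfig(**kwargs)


def _setup_logging(out_dir: Path, verbosity: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    level = logging.DEBUG if verbosity > 1 else logging.INFO if verbosity == 1 else logging.WARNING
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _write_stage_meta(stage_dir: Path, config: RunConfig, files: list[str]) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "run_config.json").write_text(config.to_json())
    (stage_dir / "artifacts.json").write_text(
        json.dumps({"version": __version__, "files": sorted(files)}, indent=2)
    )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "cohort"
    spec = config.phantom_spec()
    # deterministic repeat-scan structure: subjects cycle through 1..max_sessions
    # sessions, mirroring a cohort where some subjects are scanned once and
    # others have two or three repeat sessions
    sessions = [(i % config.max_sessions) + 1 for i in range(config.n_subjects)]
    logger.info("simulate: %d subjects, %d scans, grid %s", config.n_subjects, sum(sessions), spec.shape)
    generate_cohort(config.n_subjects, sessions, config.group_mix, config.genotype_mix, spec, out)
    _write_stage_meta(out, config, [p.name for p in out.iterdir()])
    return out / "manifest.tsv"


def _load_input_cohort(config: RunConfig) -> Cohort:
    if config.manifest:
        manifest = Path(config.manifest)
        if not manifest.exists():
            raise FileNotFoundError(f"manifest {manifest} not found")
    else:
        manifest = _require(Path(config.out_dir) / "cohort" / "manifest.tsv", "simulate")
    return load_cohort(manifest)


def stage_preprocess(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "preproc"
    cohort = _load_input_cohort(config)
    # conform all volumes onto the run grid
    conformed = []
    for s in cohort:
        conformed.append(
            dataclasses.replace(
                s,
                mri=conform(s.mri, config.grid_shape),
                pet=conform(s.pet, config.grid_shape),
                mask=conform(s.mask, config.grid_shape),
                labels=conform(s.labels, config.grid_shape) if s.labels is not None else None,
            )
        )
    cohort = Cohort(conformed, cohort.manifest_path)
    folds = make_folds(cohort, k=config.k_folds, seed=config.seed + _SEED_OFFSETS["preprocess"])
    train_keys = folds.train_keys[config.fold_index]
    pcfg = config.preprocess_config()
    processed, _adj = preprocess_cohort(cohort, pcfg, training_keys=train_keys)
    logger.info(
        "preprocess: %d scans conformed to %s, genotype adjustment fitted on fold %d training set",
        len(processed), tuple(config.grid_shape), config.fold_index,
    )

    out.mkdir(parents=True, exist_ok=True)
    rows, files = [], []
    for scan in processed:
        stem = f"{scan.subject_id}_ses-{scan.session}"
        names = {"mri": f"{stem}_mri.nii.gz", "pet": f"{stem}_pet.nii.gz", "mask": f"{stem}_mask.nii.gz"}
        write_volume(scan.mri, out / names["mri"])
        write_volume(scan.pet, out / names["pet"])
        write_volume(scan.mask, out / names["mask"])
        row = {
            "subject_id": scan.subject_id,
            "session": scan.session,
            "group": scan.group.value,
            "genotype": scan.genotype.value,
            **names,
            "labels": "",
        }
        if scan.labels is not None:
            row["labels"] = f"{stem}_labels.nii.gz"
            write_volume(scan.labels, out / row["labels"])
        rows.append(row)
        files.extend(names.values())
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "folds.json").write_text(
        json.dumps(
            {
                "k": folds.k,
                "fold_index": config.fold_index,
                "assignments": folds.assignments,
                "test_keys": folds.test_keys,
                "train_keys": folds.train_keys,
            }
        )
    )
    _write_stage_meta(out, config, files + ["manifest.tsv", "folds.json"])
    return out / "manifest.tsv"


def _load_preprocessed(config: RunConfig) -> tuple[Cohort, dict]:
    out = Path(config.out_dir) / "preproc"
    manifest = _require(out / "manifest.tsv", "preprocess")
    folds = json.loads(_require(out / "folds.json", "preprocess").read_text())
    return load_cohort(manifest), folds


def stage_train(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "model"
    cohort, folds = _load_preprocessed(config)
    train_keys = {tuple(k) for k in folds["train_keys"][config.fold_index]}
    train_all = [s for s in cohort if (s.subject_id, s.session) in train_keys]
    tr, val = split_validation_subjects(
        train_all, config.val_fraction, seed=config.seed + _SEED_OFFSETS["train"]
    )
    logger.info(
        "train: fold %d/%d, %d train scans, %d val scans, %d epochs",
        config.fold_index, folds["k"], len(tr), len(val), config.epochs,
    )
    model, record = train_model(
        tr,
        val,
        config.model_config(),
        LossConfig(config.alpha),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed + _SEED_OFFSETS["train"],
        n_restarts=config.n_restarts,
    )
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model, out / "model.npz")
    (out / "train_record.json").write_text(record.to_json())
    (out / "fold_assignments.json").write_text(json.dumps(folds["assignments"]))
    _write_stage_meta(out, config, ["model.npz", "train_record.json", "fold_assignments.json"])
    return out / "model.npz"


def stage_predict(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "pred"
    model_path = _require(Path(config.out_dir) / "model" / "model.npz", "train")
    model = load_checkpoint(model_path)
    cohort, folds = _load_preprocessed(config)
    test_keys = [tuple(k) for k in folds["test_keys"][config.fold_index]]
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for s in cohort:
        if (s.subject_id, s.session) not in test_keys:
            continue
        recon = predict(model, s.mri)
        name = f"{s.subject_id}_ses-{s.session}_pred.nii.gz"
        write_volume(recon, out / name)
        files.append(name)
    logger.info("predict: wrote %d test-fold reconstructions", len(files))
    _write_stage_meta(out, config, files)
    return out


def stage_evaluate(config: RunConfig) -> Path:
    out = Path(config.out_dir) / "report"
    pred_dir = _require(Path(config.out_dir) / "pred", "predict")
    cohort, _folds = _load_preprocessed(config)
    predictions = {}
    for s in cohort:
        path = pred_dir / f"{s.subject_id}_ses-{s.session}_pred.nii.gz"
        if path.exists():
            predictions[s.key] = read_volume(path, Modality.PET)
    if not predictions:
        raise FileNotFoundError(f"no predictions found in {pred_dir}; run the 'predict' stage first")
    report = evaluate_cohort(
        predictions,
        cohort,
        roi_sample=RoiSample(
            roi_shape=tuple(config.roi_shape),
            n_samples=config.roi_samples,
            seed=config.seed + _SEED_OFFSETS["evaluate"],
        ),
    )
    out.mkdir(parents=True, exist_ok=True)
    (out / "metric_report.json").write_text(report.to_json())
    files = ["metric_report.json"]
    if report.region_table is not None:
        report.region_table.to_csv(out / "region_table.csv", index=False)
        files.append("region_table.csv")
    logger.info("evaluate: %d predictions, summary %s", len(predictions), report.summary())
    _write_stage_meta(out, config, files)
    return out / "metric_report.json"


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "predict": stage_predict,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig, command: str = "all") -> Path:
    """Run one stage or the full chain; returns the last stage's key artifact."""
    if command not in STAGES:
        raise ValueError(f"unknown command {command!r}; expected one of {STAGES}")
    _setup_logging(Path(config.out_dir), config.verbosity)
    logger.info("pipeline %s: seed=%d out=%s version=%s", command, config.seed, config.out_dir, __version__)
    if command == "all":
        result: Path = Path(config.out_dir)
        for stage in STAGES[:-1]:
            result = _STAGE_FUNCS[stage](config)
        return result
    return _STAGE_FUNCS[command](config)
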