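"""Hybrid BCE+MSE loss, subject-level stratified cross-validation, training loop.

Fold assignment happens at the subject level so repeated sessions of one
subject never straddle the train/test boundary (no leakage), with diagnostic
groups stratified across folds. Training optimizes the hybrid loss
L = alpha * BCE + (1 - alpha) * MSE with Adam, fully seeded.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn.autodiff import Tensor, no_grad
from .nn.optim import Adam
from .nn.unet import ModelConfig, UNet3D, build_model
from .volumes import Cohort, PairedScan

__all__ = [
    "LossConfig",
    "FoldSplit",
    "TrainRecord",
    "hybrid_loss",
    "make_folds",
    "train_model",
    "split_validation_subjects",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weighting of the hybrid loss: alpha * BCE + (1 - alpha) * MSE."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


def hybrid_loss(y_true, y_pred, cfg: LossConfig = LossConfig()):
    """Hybrid reconstruction loss, mean-reduced over all voxels (and batch).

    BCE treats the target as a soft label: -[y ln p + (1-y) ln(1-p)], with the
    prediction clamped to [1e-7, 1 - 1e-7]. Accepts numpy arrays (returns a
    float) or autodiff Tensors (returns a Tensor for backprop).
    """
    tensor_mode = isinstance(y_pred, Tensor) or isinstance(y_true, Tensor)
    yt = y_true if isinstance(y_true, Tensor) else Tensor(np.asarray(y_true, dtype=np.float32))
    yp = y_pred if isinstance(y_pred, Tensor) else Tensor(np.asarray(y_pred, dtype=np.float32))
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: y_true {yt.shape} vs y_pred {yp.shape}")
    a = float(cfg.alpha)
    p = yp.clip(_EPS, 1.0 - _EPS)
    bce = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    mse = (yp - yt) ** 2.0
    loss = bce.mean() * a + mse.mean() * (1.0 - a)
    return loss if tensor_mode else float(loss.data)


@dataclass
class FoldSplit:
    """Subject-level k-fold assignment with per-fold scan key lists."""

    k: int
    assignments: dict[str, int]
    test_keys: list[list[tuple[str, int]]]
    train_keys: list[list[tuple[str, int]]]

    def __post_init__(self) -> None:
        all_test = [key for fold in self.test_keys for key in fold]
        if len(set(all_test)) != len(all_test):
            raise ValueError("folds do not partition the cohort: duplicated test scans")
        for fold_idx, keys in enumerate(self.test_keys):
            for sid, _ in keys:
                if self.assignments[sid] != fold_idx:
                    raise ValueError(f"subject {sid} straddles folds")

    def test_scans(self, cohort: Cohort, fold: int) -> list[PairedScan]:
        wanted = set(self.test_keys[fold])
        return [s for s in cohort if s.key in wanted]

    def train_scans(self, cohort: Cohort, fold: int) -> list[PairedScan]:
        wanted = set(self.train_keys[fold])
        return [s for s in cohort if s.key in wanted]


def make_folds(cohort: Cohort, k: int = 5, seed: int = 0) -> FoldSplit:
    """Subject-level, diagnostic-group-stratified k-fold split.

    Subjects are shuffled with the seed, grouped by diagnostic group, ordered
    within each group by descending scan count, and assigned greedily to the
    currently smallest fold (by scan count) -- a round-robin deal when counts
    are equal. Every scan of a subject lands in exactly one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    subjects = cohort.subjects
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = list(np.array(subjects, dtype=object)[rng.permutation(len(subjects))])
    scan_counts = {sid: len(cohort.scans_of(sid)) for sid in subjects}
    group_of = {s.subject_id: s.group for s in cohort}

    fold_sizes = [0] * k
    assignments: dict[str, int] = {}
    groups_in_order: list = []
    for sid in order:
        g = group_of[sid]
        if g not in groups_in_order:
            groups_in_order.append(g)
    for g in groups_in_order:
        members = [sid for sid in order if group_of[sid] == g]
        members.sort(key=lambda sid: -scan_counts[sid])  # stable: keeps shuffle order on ties
        for sid in members:
            fold = int(np.argmin(fold_sizes))
            assignments[sid] = fold
            fold_sizes[fold] += scan_counts[sid]

    test_keys: list[list[tuple[str, int]]] = [[] for _ in range(k)]
    for s in cohort:
        test_keys[assignments[s.subject_id]].append(s.key)
    train_keys = [
        [s.key for s in cohort if assignments[s.subject_id] != fold] for fold in range(k)
    ]
    return FoldSplit(k=k, assignments=assignments, test_keys=test_keys, train_keys=train_keys)


@dataclass
class TrainRecord:
    """Loss history and run metadata for one training run."""

    train_loss_per_step: list[float]
    val_loss_per_epoch: list[float]
    seed: int
    epochs: int
    batch_size: int
    learning_rate: float
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if len(self.val_loss_per_epoch) not in (0, self.epochs):
            raise ValueError("validation series length inconsistent with epochs")

    def epoch_mean_train_loss(self) -> list[float]:
        if self.epochs == 0 or not self.train_loss_per_step:
            return []
        per_epoch = len(self.train_loss_per_step) // self.epochs
        return [
            float(np.mean(self.train_loss_per_step[i * per_epoch : (i + 1) * per_epoch]))
            for i in range(self.epochs)
        ]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @staticmethod
    def from_json(s: str) -> "TrainRecord":
        return TrainRecord(**json.loads(s))


def _stack_batch(scans: Sequence[PairedScan]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.mri.data for s in scans])[:, None].astype(np.float32)
    y = np.stack([s.pet.data for s in scans])[:, None].astype(np.float32)
    return x, y


def split_validation_subjects(
    train_scans: Sequence[PairedScan], fraction: float = 0.1, seed: int = 0
) -> tuple[list[PairedScan], list[PairedScan]]:
    """Carve a subject-level validation set out of a training set.

    At least one subject goes to validation when fraction > 0 and there are
    two or more training subjects.
    """
    subjects: list[str] = []
    for s in train_scans:
        if s.subject_id not in subjects:
            subjects.append(s.subject_id)
    if fraction <= 0 or len(subjects) < 2:
        return list(train_scans), []
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(fraction * len(subjects))))
    val_subjects = set(np.array(subjects, dtype=object)[rng.permutation(len(subjects))][:n_val])
    train = [s for s in train_scans if s.subject_id not in val_subjects]
    val = [s for s in train_scans if s.subject_id in val_subjects]
    return train, val


def train_model(
    train_scans: Sequence[PairedScan],
    val_scans: Sequence[PairedScan],
    model_cfg: ModelConfig,
    loss_cfg: LossConfig = LossConfig(),
    epochs: int = 50,
    batch_size: int = 2,
    learning_rate: float = 1e-3,
    seed: int = 0,
    lr_schedule: str = "cosine",
    grad_clip_norm: Optional[float] = 1.0,
    n_restarts: int = 1,
) -> tuple[UNet3D, TrainRecord]:
    """Train the network with Adam on preprocessed ([0, 1]) scan pairs.

    Raises before any optimization if a subject appears in both the training
    and validation sets (leakage guard). With epochs = 0 the returned model
    equals its seeded initialization and the loss series are empty.
    ``lr_schedule`` is "cosine" (default: decay to 5% of the base rate over
    the run, which settles the late-phase oscillation of a constant rate) or
    "constant". Gradients are clipped to a global norm of ``grad_clip_norm``
    (None disables clipping).

    With ``n_restarts`` > 1, the run is repeated from ``n_restarts`` seeded
    initializations (seed, seed + 10000, ...) and the restart with the lowest
    mean training loss over its final epoch is returned — a standard remedy
    for init-dependent optimization variance that never looks at held-out
    data. Restarts multiply the runtime accordingly.
    """
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr_schedule {lr_schedule!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if n_restarts > 1 and epochs > 0:
        best: Optional[tuple[float, UNet3D, TrainRecord]] = None
        for r in range(n_restarts):
            model, record = train_model(
                train_scans,
                val_scans,
                model_cfg,
                loss_cfg,
                epochs=epochs,
                batch_size=batch_size,
                learning_rate=learning_rate,
                seed=seed + 10000 * r,
                lr_schedule=lr_schedule,
                grad_clip_norm=grad_clip_norm,
                n_restarts=1,
            )
            score = record.epoch_mean_train_loss()[-1]
            if best is None or score < best[0]:
                best = (score, model, record)
        return best[1], best[2]
    train_subjects = {s.subject_id for s in train_scans}
    val_subjects = {s.subject_id for s in val_scans}
    overlap = train_subjects & val_subjects
    if overlap:
        raise ValueError(f"subject leakage between train and validation sets: {sorted(overlap)}")
    if not train_scans:
        raise ValueError("no training scans")
    for s in list(train_scans) + list(val_scans):
        if s.mri.shape != model_cfg.input_shape:
            raise ValueError(
                f"scan {s.key} shape {s.mri.shape} does not match model input "
                f"{model_cfg.input_shape}; conform first"
            )

    model = build_model(model_cfg, seed=seed)
    optimizer = Adam(model.parameters(), learning_rate=learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)

    train_losses: list[float] = []
    val_losses: list[float] = []
    n = len(train_scans)
    steps_per_epoch = math.ceil(n / batch_size)
    total_steps = max(1, int(epochs) * steps_per_epoch)
    step = 0
    for _epoch in range(int(epochs)):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, batch_size):
            if lr_schedule == "cosine":
                optimizer.lr = learning_rate * (
                    0.05 + 0.95 * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))
                )
            batch = [train_scans[i] for i in order[start : start + batch_size]]
            x, y = _stack_batch(batch)
            pred = model(Tensor(x))
            loss = hybrid_loss(Tensor(y), pred, loss_cfg)
            optimizer.zero_grad()
            loss.backward()
            if grad_clip_norm is not None:
                _clip_grad_norm(optimizer.params, grad_clip_norm)
            optimizer.step()
            train_losses.append(float(loss.data))
            step += 1
        val_losses.append(_evaluate_loss(model, val_scans, loss_cfg, batch_size))

    record = TrainRecord(
        train_loss_per_step=train_losses,
        val_loss_per_epoch=val_losses,
        seed=int(seed),
        epochs=int(epochs),
        batch_size=int(batch_size),
        learning_rate=float(learning_rate),
    )
    return model, record


def _clip_grad_norm(params, max_norm: float) -> None:
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _evaluate_loss(
    model: UNet3D,
    scans: Sequence[PairedScan],
    loss_cfg: LossConfig,
    batch_size: int,
) -> float:
    if not scans:
        return float("nan")
    total, count = 0.0, 0
    with no_grad():
        for start in range(0, len(scans), batch_size):
            batch = scans[start : start + batch_size]
            x, y = _stack_batch(batch)
            pred = model(Tensor(x))
            total += hybrid_loss(y, pred.data) * len(batch)
            count += len(batch)
    return total / count
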