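"""Optional plot helpers (require matplotlib, installed via the 'plot' extra)."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .metrics import bland_altman
from .train import TrainRecord

__all__ = ["bland_altman_plot", "loss_curve_plot"]


def bland_altman_plot(x, y, out_path: str | Path, title: str = "Bland-Altman"):
    """Scatter of pairwise means vs differences with the limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_diff, lo, hi = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, x - y, s=18, alpha=0.7)
    ax.axhline(mean_diff, color="tab:blue", label=f"mean {mean_diff:.4f}")
    for lim in (lo, hi):
        ax.axhline(lim, color="tab:red", linestyle="--")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def loss_curve_plot(record: TrainRecord, out_path: str | Path):
    """Per-step training loss and per-epoch validation loss."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    steps = np.arange(1, len(record.train_loss_per_step) + 1)
    ax.plot(steps, record.train_loss_per_step, lw=0.8, label="train (per step)")
    if record.val_loss_per_epoch and record.epochs:
        per_epoch = len(record.train_loss_per_step) / record.epochs
        xs = per_epoch * np.arange(1, record.epochs + 1)
        ax.plot(xs, record.val_loss_per_epoch, "o-", ms=3, label="validation (per epoch)")
    ax.set_xlabel("optimization step")
    ax.set_ylabel("hybrid loss")
    ax.legend(frameon=False)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
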