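"""Confusion-matrix heat maps and hypnogram comparison plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signal_io import STAGES


def plot_confusion(cm: pd.DataFrame, path, title: str = "Confusion matrix") -> None:
    """Heat map of a 5x5 confusion matrix with per-cell counts."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    m = cm.to_numpy()
    im = ax.imshow(m, cmap="Blues")
    ax.set_xticks(range(len(cm.columns)), cm.columns)
    ax.set_yticks(range(len(cm.index)), cm.index)
    ax.set_xlabel("Predicted stage")
    ax.set_ylabel("True stage")
    ax.set_title(title)
    thresh = m.max() / 2 if m.max() else 0.5
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(
                j, i, str(m[i, j]),
                ha="center", va="center",
                color="white" if m[i, j] > thresh else "black",
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hypnogram_comparison(
    y_true, y_pred, path, window: int = 100, title: str = "Expert vs model staging"
) -> None:
    """Step plot of true and predicted stage sequences over the first
    ``window`` epochs (deep sleep at the bottom, wake at the top)."""
    order = ["N3", "N2", "N1", "REM", "W"]
    level = {s: i for i, s in enumerate(order)}
    t = np.asarray(y_true, dtype=object)[:window]
    p = np.asarray(y_pred, dtype=object)[:window]
    x = np.arange(t.size)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.step(x, [level[s] for s in t], where="post", label="expert/truth", lw=1.5)
    ax.step(x, [level[s] for s in p], where="post", label="model", lw=1.0, alpha=0.8)
    ax.set_yticks(range(len(order)), order)
    ax.set_xlabel("Epoch (30 s)")
    ax.set_title(title)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
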