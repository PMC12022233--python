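"""Figure export: confusion matrices, OvR curves, SHAP heatmaps.

Thin matplotlib wrappers over the data structures produced by
:mod:`myodx.evaluate` and :mod:`myodx.explain`; each function writes one
image file and returns its path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_confusion(matrix: np.ndarray, classes, path: str | Path,
                   normalized: bool = True) -> Path:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(0.6 * len(classes) + 2,) * 2)
    im = ax.imshow(matrix, cmap="Blues",
                   vmin=0, vmax=1 if normalized else None)
    ax.set_xticks(range(len(classes)), classes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(classes)), classes, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("ground truth")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ovr_curves(curves: dict, path: str | Path,
                    kind: str = "prc") -> Path:
    """One-vs-rest curves per class (blue) with the micro average area in
    the legend.  ``kind`` is "prc" or "roc"."""
    if kind not in ("prc", "roc"):
        raise ValueError(f"kind must be 'prc' or 'roc', got {kind!r}")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, data in curves["per_class"].items():
        if kind == "roc":
            x, y = data["roc"]
        else:
            precision, recall = data["prc"]
            x, y = recall, precision
        ax.plot(x, y, color="steelblue", alpha=0.5, lw=1)
    area_key = "auroc" if kind == "roc" else "auprc"
    ax.set_title(f"micro {area_key} = {curves['micro'][area_key]:.3f}, "
                 f"macro = {curves['macro'][area_key]:.3f}", fontsize=9)
    ax.set_xlabel("FPR" if kind == "roc" else "recall")
    ax.set_ylabel("TPR" if kind == "roc" else "precision")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_heatmap(matrix: pd.DataFrame, path: str | Path,
                 title: str = "") -> Path:
    """Clustered matrix (mean |SHAP| or interactions) as a heatmap; expects
    rows/columns already in cluster order."""
    path = Path(path)
    fig, ax = plt.subplots(
        figsize=(0.25 * matrix.shape[1] + 2, 0.3 * matrix.shape[0] + 2))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90,
                  fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
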