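"""Plot helpers: outline superposition, PCA scatter, landmark wireframes."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landmarks import ConnectionSpec, ProcrustesResult
from .outline_efd import EFDSet, mean_outline, reconstruct_outline
from .stats import PCAResult


def superposition_plot(
    efds: Sequence[EFDSet], out_path: str | Path, n_points: int = 256
) -> None:
    """All normalized outlines overlaid, with the population mean on top."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for e in efds:
        pts = reconstruct_outline(e, n_points)
        ax.plot(*np.vstack([pts, pts[:1]]).T, color="0.6", lw=0.5, alpha=0.5)
    mean = mean_outline(list(efds), n_points)
    ax.plot(*np.vstack([mean, mean[:1]]).T, color="crimson", lw=2, label="mean")
    ax.set_aspect("equal")
    ax.legend(frameon=False)
    ax.set_title(f"Outline superposition (n={len(efds)})")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def pca_scatter(result: PCAResult, out_path: str | Path) -> None:
    """PC1 vs PC2 scores, colored by group label when available."""
    fig, ax = plt.subplots(figsize=(5, 4))
    scores = result.scores
    pc2 = scores[:, 1] if scores.shape[1] > 1 else np.zeros(len(scores))
    if result.group_labels:
        labels = np.asarray(result.group_labels)
        for grp in dict.fromkeys(labels):
            sel = labels == grp
            ax.scatter(scores[sel, 0], pc2[sel], s=12, alpha=0.7, label=str(grp))
        ax.legend(frameon=False)
    else:
        ax.scatter(scores[:, 0], pc2, s=12, alpha=0.7)
    ev = result.explained_fraction
    ax.set_xlabel(f"PC1 ({ev[0]:.1%})")
    ax.set_ylabel(f"PC2 ({ev[1]:.1%})" if len(ev) > 1 else "PC2")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def wireframe_plot(
    result: ProcrustesResult,
    connections: ConnectionSpec | None,
    out_path: str | Path,
) -> None:
    """Aligned landmarks plus mean shape, with connection segments."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for cfg in result.aligned_sets:
        ax.scatter(cfg[:, 0], cfg[:, 1], s=4, color="0.7", alpha=0.5)
    mean = result.mean_shape
    ax.scatter(mean[:, 0], mean[:, 1], s=30, color="crimson", zorder=3)
    for k, (x, y) in enumerate(mean, start=1):
        ax.annotate(str(k), (x, y), fontsize=7, xytext=(2, 2),
                    textcoords="offset points")
    if connections:
        for i, j in connections.pairs:
            seg = mean[[i - 1, j - 1]]
            ax.plot(seg[:, 0], seg[:, 1], color="steelblue", lw=1)
    ax.set_aspect("equal")
    ax.set_title("Procrustes mean shape")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def debug_montage(stages: dict[str, np.ndarray], out_path: str | Path) -> None:
    """Side-by-side panels of processing stages (gray, binary, aligned...)."""
    n = len(stages)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3))
    if n == 1:
        axes = [axes]
    for ax, (name, img) in zip(axes, stages.items()):
        ax.imshow(img, cmap="gray")
        ax.set_title(name, fontsize=8)
        ax.axis("off")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
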