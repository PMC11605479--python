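"""Figure helpers: cohort lesion-frequency map, along-tract profile plots
with significance bars, and state-centroid heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profiles import PointwiseResult
from .volumes import Volume


def plot_probability_map(vol: Volume, path: str | Path) -> Path:
    """Mid-slice montage of the cohort lesion-frequency volume."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, axis in zip(axes, range(3)):
        idx = vol.shape[axis] // 2
        sl = np.take(vol.values, idx, axis=axis)
        im = ax.imshow(sl.T, origin="lower", cmap="hot", vmin=0, vmax=max(vol.values.max(), 1e-9))
        ax.set_title(f"axis {axis} slice {idx}")
        ax.axis("off")
    fig.colorbar(im, ax=axes, fraction=0.025, label="lesion frequency")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_profile(
    node_means: dict[str, np.ndarray],
    result: PointwiseResult,
    path: str | Path,
    title: str = "",
) -> Path:
    """Group mean FA profiles with significant-range bars per contrast."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for g, prof in node_means.items():
        ax.plot(np.arange(1, len(prof) + 1), prof, label=g)
    y0 = min(p.min() for p in node_means.values())
    for i, ((a, b), ranges) in enumerate(sorted(result.ranges.items())):
        for lo, hi in ranges:
            ax.hlines(y0 - 0.01 * (i + 1), lo, hi, lw=4,
                      color=f"C{i + 3}", label=f"{a} vs {b}" if (lo, hi) == ranges[0] else None)
    ax.set_xlabel("node")
    ax.set_ylabel("FA")
    ax.set_title(title)
    ax.legend(fontsize=8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_centroids(centroids: np.ndarray, n_rois: int, path: str | Path) -> Path:
    """Heatmaps of the state centroids as ROI x ROI matrices."""
    k = centroids.shape[0]
    fig, axes = plt.subplots(1, k, figsize=(4 * k, 3.5))
    axes = np.atleast_1d(axes)
    iu = np.triu_indices(n_rois, k=1)
    for j, ax in enumerate(axes):
        mat = np.zeros((n_rois, n_rois))
        mat[iu] = centroids[j]
        mat = mat + mat.T
        im = ax.imshow(mat, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"state {j + 1}")
    fig.colorbar(im, ax=list(axes), fraction=0.025, label="Fisher z")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
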