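"""Kymographs and quick-look physiology plots (matplotlib, headless)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import BinnedCorrelation
from .track import CellRecord

__all__ = ["kymograph", "plot_binned"]


def kymograph(stack: np.ndarray, cells: list[CellRecord] | None = None,
              path: str | Path | None = None, max_frames: int = 400):
    """Montage of one channel's crops over time (x = time, y = channel axis).

    With tracked cells, lineage traces are overlaid: solid lines follow a
    cell's centroid through time; dashed verticals mark divisions.
    """
    stack = np.asarray(stack)
    n, h, w = stack.shape
    n = min(n, max_frames)
    montage = np.concatenate([stack[t] for t in range(n)], axis=1)
    fig, ax = plt.subplots(figsize=(min(24, n * w / 40), 4), dpi=120)
    ax.imshow(montage, cmap="gray", aspect="auto", interpolation="nearest")
    if cells:
        cmap = plt.get_cmap("tab20")
        for i, cell in enumerate(cells):
            ts = np.array(cell.frames)
            keep = ts < n
            if not keep.any():
                continue
            xs = ts[keep] * w + w / 2.0
            ys = np.array([f.centroid_y for f in cell.features])[keep]
            color = cmap(i % 20)
            ax.plot(xs, ys, "-", color=color, lw=1)
            if cell.division_frame is not None and cell.division_frame < n:
                ax.axvline(cell.division_frame * w, color=color, ls="--", lw=0.5)
    ax.set_xlabel("time (frames)")
    ax.set_ylabel("position along channel (px)")
    ax.set_yticks([])
    ax.set_xticks([])
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_binned(bc: BinnedCorrelation, path: str | Path | None = None):
    """Binned-mean correlation plot with SEM error bars."""
    fig, ax = plt.subplots(figsize=(4, 3), dpi=120)
    ax.errorbar(bc.centers, bc.means, yerr=bc.sems, fmt="o", capsize=2)
    ax.set_xlabel(bc.x_name)
    ax.set_ylabel(bc.y_name)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
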