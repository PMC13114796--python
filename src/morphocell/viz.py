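"""Optional figure output: morphospace scatter and simulation outlines."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_morphospace", "plot_outline_evolution"]


def plot_morphospace(embedding: np.ndarray, labels, path: str | Path,
                     title: str = "morphospace") -> Path:
    """2-D embedding scatter coloured by cluster/category label."""
    path = Path(path)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for lab in np.unique(labels):
        sel = labels == lab
        ax.scatter(embedding[sel, 0], embedding[sel, 1], s=12, label=str(lab))
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_outline_evolution(trajectory, path: str | Path, every: int = 25) -> Path:
    """Overlay of sampled cell outlines colour-coded by time."""
    path = Path(path)
    states = trajectory.states[::every]
    times = trajectory.times[::every]
    cmap = plt.get_cmap("viridis")
    t0, t1 = times[0], times[-1]
    fig, ax = plt.subplots(figsize=(5, 5))
    for st, t in zip(states, times):
        v = np.vstack([st.vertices, st.vertices[:1]])
        ax.plot(v[:, 0], v[:, 1], color=cmap((t - t0) / max(t1 - t0, 1e-9)), lw=0.8)
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(t0, t1))
    fig.colorbar(sm, ax=ax, label="time (s)")
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
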