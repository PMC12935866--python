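"""Gait-tube figures: 3D tube in velocity state space and 2D projections."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from gaittube.core import GaitTube

__all__ = ["tube_ring_points", "plot_tube_3d", "plot_tube_projections"]

_PROJECTIONS = {
    "sagittal": (0, 2, "AP velocity (mm/s)", "VT velocity (mm/s)"),
    "transverse": (0, 1, "AP velocity (mm/s)", "ML velocity (mm/s)"),
    "frontal": (1, 2, "ML velocity (mm/s)", "VT velocity (mm/s)"),
}


def tube_ring_points(tube: GaitTube, index: int, n_points: int = 40) -> np.ndarray:
    """3D points of the cross-section ellipse at one phase index."""
    e = tube.cross_sections[index]
    theta = np.linspace(0, 2 * np.pi, n_points)
    ca, sa = np.cos(e.angle), np.sin(e.angle)
    u = e.semi_axes[0] * np.cos(theta)
    v = e.semi_axes[1] * np.sin(theta)
    local_n = u * ca - v * sa
    local_b = u * sa + v * ca
    center = tube.mean_trajectory[index]
    return (
        center[None, :]
        + local_n[:, None] * tube.frames.normal[index]
        + local_b[:, None] * tube.frames.binormal[index]
    )


def plot_tube_3d(
    tubes: dict[str, GaitTube],
    out: str | Path | None = None,
    ring_every: int = 5,
    colors: dict[str, str] | None = None,
):
    """Mean velocity loop with variability rings for one or more groups."""
    palette = colors or {}
    default_colors = ["black", "tab:red", "tab:blue", "tab:green"]
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for i, (name, tube) in enumerate(tubes.items()):
        c = palette.get(name, default_colors[i % len(default_colors)])
        M = tube.mean_trajectory
        ax.plot(M[:, 0], M[:, 1], M[:, 2], color=c, lw=2, label=name)
        for j in range(0, M.shape[0], ring_every):
            ring = tube_ring_points(tube, j)
            ax.plot(ring[:, 0], ring[:, 1], ring[:, 2], color=c, lw=0.5, alpha=0.5)
    ax.set_xlabel("AP velocity (mm/s)")
    ax.set_ylabel("ML velocity (mm/s)")
    ax.set_zlabel("VT velocity (mm/s)")
    ax.legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_tube_projections(
    tubes: dict[str, GaitTube],
    out: str | Path | None = None,
    ring_every: int = 5,
    colors: dict[str, str] | None = None,
):
    """Sagittal, transverse and frontal 2D views of the gait tubes."""
    palette = colors or {}
    default_colors = ["black", "tab:red", "tab:blue", "tab:green"]
    fig, axes = plt.subplots(1, 3, figsize=(15, 5))
    for ax, (view, (ix, iy, lx, ly)) in zip(axes, _PROJECTIONS.items()):
        for i, (name, tube) in enumerate(tubes.items()):
            c = palette.get(name, default_colors[i % len(default_colors)])
            M = tube.mean_trajectory
            ax.plot(M[:, ix], M[:, iy], color=c, lw=2, label=name)
            for j in range(0, M.shape[0], ring_every):
                ring = tube_ring_points(tube, j)
                ax.plot(ring[:, ix], ring[:, iy], color=c, lw=0.5, alpha=0.5)
        ax.set_xlabel(lx)
        ax.set_ylabel(ly)
        ax.set_title(view)
        ax.set_aspect("equal", adjustable="datalim")
    axes[0].legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
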