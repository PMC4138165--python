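"""Cosmetic plotting helpers: niche-plane densities and profile overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .niche import NicheGrid
from .profiles import OccupancyProfile

__all__ = ["plot_niche_grid", "plot_profiles"]


def plot_niche_grid(
    grid: NicheGrid, path: str | Path, title: str = "", cmap: str = "Blues"
) -> None:
    """Occupancy density with 100% (solid) and 75% (dashed) envelope lines."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    extent = [*grid.axis1_range, *grid.axis2_range]
    ax.imshow(
        grid.z.T, origin="lower", extent=extent, aspect="auto", cmap=cmap
    )
    x = np.linspace(*grid.axis1_range, grid.R)
    y = np.linspace(*grid.axis2_range, grid.R)
    ax.contour(x, y, grid.envelope_100.T.astype(float), levels=[0.5],
               colors="k", linewidths=1.0, linestyles="solid")
    ax.contour(x, y, grid.envelope_75.T.astype(float), levels=[0.5],
               colors="k", linewidths=1.0, linestyles="dashed")
    ax.set_xlabel("PCA axis 1")
    ax.set_ylabel("PCA axis 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profiles(
    profiles: dict[str, OccupancyProfile], path: str | Path, xlabel: str = "covariate"
) -> None:
    """Overlay of occupancy profiles, one curve per projection."""
    fig, ax = plt.subplots(figsize=(5.5, 3.6))
    for label, p in profiles.items():
        mid = 0.5 * (p.bin_edges[:-1] + p.bin_edges[1:])
        ax.plot(mid, p.mass, label=f"{label} (mean {p.weighted_mean:.0f})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("suitability mass")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
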