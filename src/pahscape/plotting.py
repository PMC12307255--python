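"""Landscape rendering: 2D heatmaps with peak marker and 50%-activity contour.

A power-law color normalization (exponent ``gamma`` < 1) stretches the low
end of the activity scale so reduced-activity peaks in the 5-20 %WT band stay
visible next to the wild type; ``gamma = 1`` is linear scaling.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import PowerNorm

from .model import GaussianFit, smooth_landscape
from .plates import ActivityLandscape


def render_landscape(
    landscape: ActivityLandscape,
    fit: GaussianFit | None = None,
    gamma: float = 0.4,
    upsample: int = 6,
    sigma: float = 1.5,
    path: str | Path | None = None,
    surface_3d: bool = False,
):
    """Render a smoothed 2D heatmap; overlay peak and 50% contour when fitted.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    dense, phe_d, bh4_d = smooth_landscape(landscape, upsample=upsample, sigma=sigma)
    fig = plt.figure(figsize=(7, 4) if not surface_3d else (11, 4))
    ax = fig.add_subplot(1, 2 if surface_3d else 1, 1)
    vmax = max(dense.max(), 1e-9)
    mesh = ax.pcolormesh(
        phe_d, bh4_d, dense.T, norm=PowerNorm(gamma=gamma, vmin=0, vmax=vmax), shading="gouraud", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label=f"activity ({landscape.units})")
    ax.set_xlabel("[Phe] (uM)")
    ax.set_ylabel("[BH4] (uM)")
    ax.set_title(landscape.genotype_id)

    if fit is not None and fit.converged and fit.a > 0:
        px, py = math.exp(fit.mx_prime), math.exp(fit.my_prime)
        ax.plot([px], [py], marker="x", color="deeppink", markersize=10, mew=2)
        # 50%-of-maximum contour of the fitted surface
        pp, bb = np.meshgrid(np.maximum(phe_d, 1e-9), np.maximum(bh4_d, 1e-9), indexing="ij")
        model = fit.predict(pp, bb)
        ax.contour(phe_d, bh4_d, model.T, levels=[0.5 * fit.a], colors="deeppink", linewidths=1.5)

    if surface_3d:
        ax3 = fig.add_subplot(1, 2, 2, projection="3d")
        pp, bb = np.meshgrid(phe_d, bh4_d, indexing="ij")
        ax3.plot_surface(pp, bb, dense, cmap="viridis", norm=PowerNorm(gamma=gamma, vmin=0, vmax=vmax))
        ax3.set_xlabel("[Phe]")
        ax3.set_ylabel("[BH4]")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
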