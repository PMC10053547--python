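"""Plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .patterns import HeatMap, PointPattern


def plot_heatmap(
    heatmap: HeatMap,
    path,
    pattern: PointPattern | None = None,
    vmax: float = 0.06,
    title: str | None = None,
) -> None:
    """Render a tank density surface to an image file.

    The colour scale is fixed (default 0 to 0.06 ind/cm²) so panels from
    different times or tanks are comparable.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    extent = (
        heatmap.x_centers[0], heatmap.x_centers[-1],
        heatmap.y_centers[0], heatmap.y_centers[-1],
    )
    im = ax.imshow(
        heatmap.density, origin="lower", extent=extent, vmin=0.0, vmax=vmax,
        cmap="viridis",
    )
    if pattern is not None:
        ax.plot(pattern.points[:, 0], pattern.points[:, 1], "w.", ms=4)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="individuals / cm$^2$", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
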