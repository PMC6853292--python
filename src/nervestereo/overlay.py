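"""Audit overlays: section image + cycloid grid + marked counts as PNG."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import shapely

from .grid import CountTally, CycloidGrid, SectionPlane, mask_to_polygon

__all__ = ["save_overlay"]


def save_overlay(
    section: SectionPlane,
    grid: CycloidGrid,
    target_label: int,
    path: str | Path,
    tally: CountTally | None = None,
) -> Path:
    """Render the grid cast over the section for visual inspection.

    Intersections of the arcs with the target boundary are marked as dots on
    the surface; test points inside the target are highlighted.
    """
    path = Path(path)
    dx, dy = section.spacing
    ny, nx = section.image.shape
    fig, ax = plt.subplots(figsize=(6, 6 * ny * dy / (nx * dx)))
    ax.imshow(
        section.image,
        cmap="tab10",
        interpolation="nearest",
        extent=(0, nx * dx, ny * dy, 0),
        vmin=0,
        vmax=9,
        alpha=0.6,
    )
    mask = np.asarray(section.image) == target_label
    geom = mask_to_polygon(mask, section.spacing)
    if geom is not None:
        shapely.prepare(geom)
    for arc in grid.arcs:
        ax.plot(arc[:, 0], arc[:, 1], color="white", lw=0.6)
        if geom is not None:
            inside = shapely.contains_xy(geom, arc[:, 0], arc[:, 1])
            flips = np.nonzero(inside[1:] != inside[:-1])[0]
            if len(flips):
                mid = 0.5 * (arc[flips] + arc[flips + 1])
                ax.plot(mid[:, 0], mid[:, 1], "o", color="tab:blue", ms=3)
    if len(grid.points):
        hit = (
            shapely.contains_xy(geom, grid.points[:, 0], grid.points[:, 1])
            if geom is not None
            else np.zeros(len(grid.points), dtype=bool)
        )
        ax.plot(grid.points[~hit, 0], grid.points[~hit, 1], "+", color="0.7", ms=4)
        ax.plot(grid.points[hit, 0], grid.points[hit, 1], "o", color="tab:green", ms=4)
    if section.lamina_trace is not None:
        ax.plot(
            section.lamina_trace[:, 0], section.lamina_trace[:, 1], color="red", lw=0.8
        )
    title = f"label {target_label}"
    if tally is not None:
        title += f"  I={tally.I}  P={tally.P}" + ("  (restricted)" if tally.restricted else "")
    ax.set_title(title, fontsize=9)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
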