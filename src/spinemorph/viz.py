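"""Debug rendering: corner overlays and region-area plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .corners import CornerSet
from .io import LabelImage, Point


def save_corner_overlay(
    label_image: LabelImage,
    corner_sets: Mapping[str, CornerSet],
    path: str | Path,
) -> Path:
    """Write a PNG of the label raster with detected corners marked."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(label_image.pixels, cmap="tab10", interpolation="nearest")
    for name, cs in corner_sets.items():
        xs = [p.x for p in cs.points()]
        ys = [p.y for p in cs.points()]
        ax.scatter(xs, ys, s=18, c="white", edgecolors="black", zorder=3)
        ax.annotate(name, (xs[0], ys[0]), color="white", fontsize=8)
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_region_plot(
    label_image: LabelImage, polygon: Sequence[Point], area_px: float, path: str | Path
) -> Path:
    """Write a PNG of the centroid polygon over the label raster."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(label_image.pixels, cmap="gray", interpolation="nearest")
    xs = [p.x for p in polygon] + [polygon[0].x]
    ys = [p.y for p in polygon] + [polygon[0].y]
    ax.fill(xs, ys, alpha=0.4, color="tab:orange")
    ax.plot(xs, ys, "o-", color="tab:red", ms=4)
    ax.set_title(f"region area = {area_px:.0f} px²")
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
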