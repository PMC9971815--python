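"""Quality-control figures: mask overlays and spark/T50 summary images.

These are diagnostic aids, not analysis outputs: each function renders one
PNG so a recording's segmentation, detected sparks or T50 map can be eyeballed
quickly after a pipeline run.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_mask_overlay", "save_spark_overlay", "save_t50_map"]


def save_mask_overlay(
    mean_image: np.ndarray,
    cell_mask: np.ndarray,
    path: str | Path,
    tubule_mask: np.ndarray | None = None,
    title: str = "segmentation",
) -> Path:
    """Temporal-mean image with the cell outline (and optionally tubules)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(mean_image, cmap="gray")
    ax.contour(cell_mask, levels=[0.5], colors="cyan", linewidths=0.8)
    if tubule_mask is not None:
        ax.contour(tubule_mask, levels=[0.5], colors="orange", linewidths=0.4)
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_spark_overlay(
    mean_image: np.ndarray,
    events,
    path: str | Path,
    title: str = "spark centres of mass",
) -> Path:
    """Spark COM markers over the temporal-mean calcium image."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(mean_image, cmap="gray")
    if events:
        xs = [e.com_xy[0] for e in events]
        ys = [e.com_xy[1] for e in events]
        ax.scatter(xs, ys, s=12, c="red", marker="x")
    ax.set_title(f"{title} (n={len(events)})")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_t50_map(t50_map, path: str | Path, title: str = "mean T50 (ms)") -> Path:
    """Aggregate T50 map with undefined pixels blanked."""
    fig, ax = plt.subplots(figsize=(8, 4))
    img = np.where(t50_map.valid_mask, t50_map.mean_ms, np.nan)
    im = ax.imshow(img, cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.7, label="ms")
    ax.set_title(title)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
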