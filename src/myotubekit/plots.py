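"""PNG output surfaces: overlays, cluster plots, labeled masks.

These mirror the visual outputs a bench scientist checks after each step:
a colored labeled mask, nucleus centroid overlays on the blue and blue+red
composites, the per-cluster colored scatter with unclustered nuclei in red
("-1"), the skeleton/branch-point overlay, and the distance-transform image
used for diameter measurements.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from PIL import Image
from scipy import ndimage

from .clustering import ClusterAssignment, UNCLUSTERED
from .mask import MyotubeMask
from .myotube_features import BranchPointSet, Skeleton
from .nuclei import NucleusSet
from .preprocessing import ChannelImage

__all__ = [
    "save_labels_png",
    "save_nuclei_overlay",
    "save_cluster_plot",
    "save_skeleton_overlay",
    "save_distance_transform",
]

# fixed categorical palette, cycled after 20 labels, so re-runs are identical
_PALETTE = (plt.get_cmap("tab20")(np.linspace(0, 1, 20))[:, :3] * 255).astype(np.uint8)


def save_labels_png(mask: MyotubeMask, path: str | Path) -> Path:
    """Write the labeled mask with one palette color per myotube."""
    rgb = np.zeros((*mask.labels.shape, 3), dtype=np.uint8)
    for k in range(1, mask.n_myotubes + 1):
        rgb[mask.labels == k] = _PALETTE[(k - 1) % len(_PALETTE)]
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path


def _composite(blue: ChannelImage, red: ChannelImage | None) -> np.ndarray:
    rgb = np.zeros((*blue.shape, 3))
    rgb[:, :, 2] = blue.pixels
    if red is not None:
        rgb[:, :, 0] = red.pixels
    return rgb


def save_nuclei_overlay(
    nuclei: NucleusSet,
    blue: ChannelImage,
    path: str | Path,
    red: ChannelImage | None = None,
) -> Path:
    """Centroid markers over the blue (or blue+red) composite.

    In-myotube nuclei are drawn as yellow asterisks, out-of-myotube as cyan,
    marker-positive nuclei get a red edge ring.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6 * blue.shape[0] / blue.shape[1]))
    ax.imshow(_composite(blue, red))
    if len(nuclei):
        inside = nuclei.in_myotube
        ax.plot(nuclei.centroids[inside, 1], nuclei.centroids[inside, 0], "*", color="yellow", ms=6)
        ax.plot(nuclei.centroids[~inside, 1], nuclei.centroids[~inside, 0], "*", color="cyan", ms=6)
        if nuclei.has_marker and nuclei.marker_positive.any():
            mk = nuclei.marker_positive
            ax.plot(
                nuclei.centroids[mk, 1], nuclei.centroids[mk, 0], "o",
                mfc="none", mec="red", ms=10,
            )
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_cluster_plot(
    nuclei: NucleusSet,
    assignment: ClusterAssignment,
    path: str | Path,
    red: ChannelImage | None = None,
) -> Path:
    """Per-cluster colored centroids with a legend; unclustered in red (-1)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    if red is not None:
        ax.imshow(red.pixels, cmap="Reds")
    for k in range(1, assignment.n_clusters + 1):
        idx = assignment.members(k)
        color = _PALETTE[(k - 1) % len(_PALETTE)] / 255.0
        ax.plot(nuclei.centroids[idx, 1], nuclei.centroids[idx, 0], "o", color=color, label=str(k))
    loose = assignment.labels == UNCLUSTERED
    if loose.any():
        ax.plot(nuclei.centroids[loose, 1], nuclei.centroids[loose, 0], "o", color="red", label="-1")
    if len(nuclei):
        ax.legend(loc="upper right", fontsize=7, ncol=2)
    if red is None:
        ax.invert_yaxis()
        ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_skeleton_overlay(
    mask: MyotubeMask,
    skeleton: Skeleton,
    branch_points: BranchPointSet,
    path: str | Path,
) -> Path:
    """Mask in red, skeleton in white, branch points as green circles."""
    path = Path(path)
    rgb = np.zeros((*mask.labels.shape, 3))
    rgb[:, :, 0] = mask.binary.pixels * 0.6
    rgb[skeleton.pixels] = 1.0
    fig, ax = plt.subplots(figsize=(6, 6 * rgb.shape[0] / rgb.shape[1]))
    ax.imshow(rgb)
    if branch_points.count:
        ax.plot(
            branch_points.points[:, 1], branch_points.points[:, 0], "o",
            mfc="none", mec="lime", ms=10,
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_distance_transform(mask: MyotubeMask, path: str | Path) -> Path:
    """The distance-transform raster used for diameter point selection."""
    dt = ndimage.distance_transform_edt(mask.binary.pixels)
    scaled = (255 * dt / dt.max()).astype(np.uint8) if dt.max() > 0 else dt.astype(np.uint8)
    path = Path(path)
    Image.fromarray(scaled, mode="L").save(path)
    return path
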