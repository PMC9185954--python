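"""Skeleton-based myotube morphology: branching, coverage, diameter.

The labeled myotube mask is thinned to a 1-px-wide, topology-preserving
skeleton.  Skeleton pixels with three or more skeleton neighbours
(8-connectivity) are branch candidates; thinning typically leaves 2-3
adjacent junction pixels at a real branching, so adjacent candidates are
merged into one branch point snapped back onto the skeleton.  The branch
point total over all myotubes in an image is the "number of branching
points" parameter.

Myotube coverage is the percentage of image pixels inside the mask, total
and split per labeled myotube (the per-object contributions partition the
total exactly).

Diameters come from the Euclidean distance transform of the mask: on the
skeleton, the transform value is the local myotube radius, so doubling the
transform at the skeleton pixel nearest to a user-chosen sample point
estimates the local diameter.  Snapping to the skeleton removes the error a
slightly off-center click would otherwise introduce; sampling near
junctions remains the caller's responsibility, since there the nearest
background pixel is no longer perpendicular to the myotube axis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import morphology

from .errors import NoMatchError, OffMyotubeError
from .mask import MyotubeMask
from .nuclei import NucleusSet

__all__ = [
    "Skeleton",
    "BranchPointSet",
    "DiameterMeasurement",
    "CoverageReport",
    "skeletonize_mask",
    "find_branch_points",
    "edit_branch_points",
    "coverage",
    "measure_diameters",
    "myotube_feature_summary",
]


@dataclasses.dataclass
class Skeleton:
    """1-px-wide medial skeleton of a myotube mask (boolean raster)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (row, col) skeleton pixel coordinates."""
        return np.argwhere(self.pixels)

    def __len__(self) -> int:
        return int(self.pixels.sum())


@dataclasses.dataclass
class BranchPointSet:
    """Merged skeleton junction points, (row, col) per point."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def count(self) -> int:
        return len(self.points)


@dataclasses.dataclass(frozen=True)
class DiameterMeasurement:
    """One local diameter estimate.

    ``skeleton_point`` is the skeleton pixel nearest the raw sample point;
    the diameter is twice the distance-transform value there, in microns.
    """

    sample_point: tuple[int, int]
    skeleton_point: tuple[int, int]
    diameter_um: float
    diameter_px: float


@dataclasses.dataclass
class CoverageReport:
    """Myotube coverage as % of image pixels, total and per myotube."""

    total_pct: float
    per_myotube_pct: np.ndarray  # index k-1 -> contribution of myotube k

    def __post_init__(self) -> None:
        self.per_myotube_pct = np.asarray(self.per_myotube_pct, dtype=float)


def skeletonize_mask(mask: MyotubeMask) -> Skeleton:
    """Thin the mask to a 1-px topology-preserving skeleton."""
    return Skeleton(morphology.skeletonize(mask.binary.pixels))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0)


def _prune_spurs(skel: np.ndarray, length: int) -> np.ndarray:
    """Iteratively strip endpoint pixels ``length`` times, removing short spurs.

    Only pixels with exactly one skeleton neighbour are removed per pass, so
    closed loops and through-paths survive; a spur of <= length pixels is
    consumed entirely.
    """
    out = skel.copy()
    for _ in range(length):
        endpoints = out & (_neighbor_counts(out) == 1)
        if not endpoints.any():
            break
        out &= ~endpoints
    return out


def find_branch_points(skeleton: Skeleton, min_branch_length: int = 0) -> BranchPointSet:
    """Locate merged junction points of the skeleton.

    Candidates are skeleton pixels with >= 3 skeleton neighbours; adjacent
    candidates (8-connected) merge into one point at their centroid snapped
    to the nearest skeleton pixel.  ``min_branch_length`` prunes spurs
    shorter than that many pixels before detection (default 0: no pruning,
    spurious points are expected to be removed by editing).
    """
    skel = skeleton.pixels
    if min_branch_length > 0:
        skel = _prune_spurs(skel, int(min_branch_length))
    candidates = skel & (_neighbor_counts(skel) >= 3)
    if not candidates.any():
        return BranchPointSet(np.empty((0, 2)))
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    centroids = np.asarray(
        ndimage.center_of_mass(candidates, labels, index=np.arange(1, n + 1)), dtype=float
    ).reshape(-1, 2)
    skel_coords = np.argwhere(skel)
    tree = cKDTree(skel_coords)
    _, idx = tree.query(centroids)
    return BranchPointSet(skel_coords[idx].astype(float))


def edit_branch_points(
    points: BranchPointSet,
    add: Sequence[tuple[float, float]] = (),
    remove: Sequence[tuple[float, float]] = (),
    capture_radius_px: float = 5.0,
) -> BranchPointSet:
    """Add or remove branch points (capture-radius removal, as for nuclei)."""
    pts = list(map(tuple, points.points))
    for p in add:
        pts.append((float(p[0]), float(p[1])))
    for p in remove:
        if not pts:
            raise NoMatchError(f"no branch point within capture radius of {tuple(p)}")
        arr = np.asarray(pts, dtype=float)
        d = np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])
        idx = int(np.argmin(d))
        if d[idx] > capture_radius_px:
            raise NoMatchError(f"no branch point within capture radius of {tuple(p)}")
        pts.pop(idx)
    return BranchPointSet(np.asarray(pts, dtype=float).reshape(-1, 2))


def coverage(mask: MyotubeMask) -> CoverageReport:
    """Percentage of image pixels covered by myotubes, total and per object."""
    n_pixels = mask.binary.pixels.size
    if mask.n_myotubes:
        areas = np.bincount(mask.labels.ravel(), minlength=mask.n_myotubes + 1)[1:]
    else:
        areas = np.zeros(0, dtype=int)
    per = 100.0 * areas / n_pixels
    return CoverageReport(total_pct=float(per.sum()), per_myotube_pct=per)


def measure_diameters(
    mask: MyotubeMask,
    skeleton: Skeleton,
    sample_points: Sequence[tuple[float, float]],
) -> list[DiameterMeasurement]:
    """Estimate local myotube diameters at the given sample points.

    Each sample point must lie on mask foreground; it is snapped to the
    nearest skeleton pixel and the diameter is twice the Euclidean distance
    transform there, converted to microns.
    """
    dt = ndimage.distance_transform_edt(mask.binary.pixels)
    skel_coords = skeleton.coordinates
    if len(skel_coords) == 0:
        raise OffMyotubeError("skeleton is empty; nothing to measure")
    tree = cKDTree(skel_coords)
    mpp = mask.binary.calibration.microns_per_pixel
    out = []
    for p in sample_points:
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < mask.binary.shape[0] and 0 <= c < mask.binary.shape[1]) or not mask.binary.pixels[r, c]:
            raise OffMyotubeError(f"sample point ({p[0]}, {p[1]}) is not on a myotube")
        _, idx = tree.query([r, c])
        sr, sc = skel_coords[idx]
        d_px = 2.0 * float(dt[sr, sc])
        out.append(
            DiameterMeasurement(
                sample_point=(r, c),
                skeleton_point=(int(sr), int(sc)),
                diameter_um=d_px * mpp,
                diameter_px=d_px,
            )
        )
    return out


def myotube_feature_summary(
    mask: MyotubeMask,
    branch_points: BranchPointSet,
    cov: CoverageReport,
    nuclei: NucleusSet | None = None,
) -> dict:
    """Aggregate the descriptive myotube parameters for one image set.

    Branch points are assigned to the myotube label beneath them; nuclei
    per myotube come from the classified nucleus set when available.
    """
    per_tube_branches = np.zeros(mask.n_myotubes, dtype=int)
    for r, c in branch_points.points.astype(int):
        label = mask.labels[r, c]
        if label > 0:
            per_tube_branches[label - 1] += 1
    summary = {
        "n_myotubes": mask.n_myotubes,
        "n_branch_points": branch_points.count,
        "branch_points_per_myotube": per_tube_branches,
        "coverage_pct": cov.total_pct,
        "coverage_per_myotube_pct": cov.per_myotube_pct,
    }
    if nuclei is not None and len(nuclei):
        per_tube_nuclei = np.bincount(
            nuclei.myotube_label[nuclei.myotube_label > 0], minlength=mask.n_myotubes + 1
        )[1:]
        summary["nuclei_per_myotube"] = per_tube_nuclei
    else:
        summary["nuclei_per_myotube"] = np.zeros(mask.n_myotubes, dtype=int)
    return summary


def summary_frame(summary: dict) -> pd.DataFrame:
    """Per-myotube table for the workbook's summary sheet."""
    n = summary["n_myotubes"]
    return pd.DataFrame(
        {
            "myotube": np.arange(1, n + 1),
            "branch_points": summary["branch_points_per_myotube"],
            "coverage_pct": summary["coverage_per_myotube_pct"],
            "nuclei": summary["nuclei_per_myotube"],
        }
    )
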