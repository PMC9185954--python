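"""Nucleus clustering and cluster-linearity scoring.

In differentiated cultures myonuclei co-localize into elongated chains along
the myotube axis.  Two parameters quantify this: the number of nucleus
clusters and the average linearity of those clusters.

Clustering is agglomerative single linkage on centroid-to-centroid distances
in microns: starting from singletons, the two clusters with the shortest
nearest-pair distance merge, and merging stops once that distance exceeds a
fixed cutoff.  The cutoff is the sum of the nucleus diameter (10 um) and the
largest allowed edge-to-edge gap between neighbouring nuclei (4 um), i.e.
14 um by default; a pair exactly at the cutoff still merges.  Because of the
chaining property of single linkage, nuclei further apart than the cutoff
can share a cluster as long as a chain of within-cutoff neighbours connects
them — equivalently, the final partition is exactly the connected components
of the graph with an edge wherever two centroids are within the cutoff.
Groups with fewer than four nuclei are not clusters; their members get the
sentinel label -1.

Each cluster's linearity is the RMSE of orthogonal regression (total least
squares): the line through the cluster centroid along the principal axis of
the point scatter, scored by the root mean square of perpendicular point-to-
line distances, in microns.  Perfectly chained nuclei give RMSE 0; the
larger the RMSE, the less linear the cluster.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateClusterError
from .nuclei import NucleusSet

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "TrendlineFit",
    "ClusterSummary",
    "UNCLUSTERED",
    "cluster_nuclei",
    "fit_trendline",
    "summarize_clusters",
    "analyze_clusters",
]

UNCLUSTERED = -1


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Clustering parameters, all in microns except ``min_size``.

    ``cutoff`` is derived: nucleus diameter + maximum edge-to-edge gap.
    """

    nucleus_diameter_um: float = 10.0
    max_edge_gap_um: float = 4.0
    min_size: int = 4

    def __post_init__(self) -> None:
        if self.nucleus_diameter_um <= 0 or self.max_edge_gap_um <= 0:
            raise ValueError("nucleus diameter and edge gap must be positive")
        if self.min_size < 2:
            raise ValueError(f"min_size must be >= 2, got {self.min_size}")

    @property
    def cutoff_um(self) -> float:
        return self.nucleus_diameter_um + self.max_edge_gap_um


@dataclasses.dataclass
class ClusterAssignment:
    """Per-nucleus cluster labels: 1..n_clusters, or -1 for unclustered.

    Clusters are numbered by the index of their first member, so the
    assignment is deterministic and stable under input order.
    """

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        valid = set(range(1, self.n_clusters + 1)) | {UNCLUSTERED}
        if not set(np.unique(self.labels)).issubset(valid):
            raise ValueError("labels must be -1 or 1..n_clusters")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclasses.dataclass(frozen=True)
class TrendlineFit:
    """Orthogonal-regression line fit for one cluster.

    The line passes through ``centroid_um`` along the unit ``direction``;
    ``rmse_um`` is the root mean square perpendicular distance of the
    cluster's points to that line.
    """

    centroid_um: tuple[float, float]
    direction: tuple[float, float]
    rmse_um: float
    n_points: int


@dataclasses.dataclass
class ClusterSummary:
    """Per-image cluster statistics: count, per-cluster rows, average RMSE.

    ``average_rmse_um`` is the unweighted mean over clusters and is None
    (reported as missing, not 0) when there are no clusters.
    """

    n_clusters: int
    per_cluster: pd.DataFrame
    average_rmse_um: float | None


def cluster_nuclei(nuclei: NucleusSet, params: ClusterParams | None = None) -> ClusterAssignment:
    """Single-linkage clustering of nucleus centroids with a distance cutoff.

    Returns one label per nucleus: -1 for nuclei in groups smaller than
    ``params.min_size``, otherwise a cluster id in 1..n_clusters.
    """
    params = params or ClusterParams()
    points = nuclei.centroids_um
    n = len(points)
    if n == 0:
        return ClusterAssignment(np.empty(0, dtype=int), 0)
    if n == 1:
        return ClusterAssignment(np.full(1, UNCLUSTERED), 0)

    merged = fcluster(linkage(pdist(points), method="single"), t=params.cutoff_um, criterion="distance")

    labels = np.full(n, UNCLUSTERED, dtype=int)
    next_id = 1
    seen_small: set[int] = set()
    for i in range(n):
        g = merged[i]
        if labels[i] != UNCLUSTERED or g in seen_small:
            continue
        members = merged == g
        if members.sum() >= params.min_size:
            labels[members] = next_id
            next_id += 1
        else:
            seen_small.add(g)
    return ClusterAssignment(labels, next_id - 1)


def fit_trendline(points_um: Sequence[Sequence[float]] | np.ndarray) -> TrendlineFit:
    """Fit the orthogonal-regression (total least squares) line to 2-D points.

    The fitted line is the principal axis of the centered point scatter;
    the RMSE is sqrt(mean squared perpendicular distance), which equals
    sqrt(lambda_min / n) for the smaller eigenvalue of the 2x2 scatter
    matrix.  For isotropic scatter the axis closer to the x-axis is chosen.
    """
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError(f"need >= 2 points, got {len(pts)}")
    center = pts.mean(axis=0)
    dev = pts - center
    if np.allclose(dev, 0.0):
        raise DegenerateClusterError("all points coincident; trendline undefined")
    scatter = dev.T @ dev
    eigvals, eigvecs = np.linalg.eigh(scatter)  # ascending eigenvalues
    if np.isclose(eigvals[0], eigvals[1]):
        # isotropic scatter: tie broken toward the x (column) axis
        direction = np.array([0.0, 1.0])
    else:
        direction = eigvecs[:, 1]
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction  # canonical orientation
    lam = max(float(eigvals[0]), 0.0)
    if lam < 1e-12 * float(eigvals[1]):
        lam = 0.0  # numerically collinear
    rmse = float(np.sqrt(lam / len(pts)))
    return TrendlineFit(
        centroid_um=(float(center[0]), float(center[1])),
        direction=(float(direction[0]), float(direction[1])),
        rmse_um=max(rmse, 0.0),
        n_points=len(pts),
    )


def summarize_clusters(
    assignment: ClusterAssignment, fits: Sequence[TrendlineFit]
) -> ClusterSummary:
    """Aggregate per-cluster fits into the per-image cluster parameters."""
    if len(fits) != assignment.n_clusters:
        raise ValueError(
            f"expected {assignment.n_clusters} fits, got {len(fits)}"
        )
    rows = []
    for k, fit in enumerate(fits, start=1):
        rows.append(
            {
                "cluster": k,
                "size": int((assignment.labels == k).sum()),
                "rmse_um": fit.rmse_um,
                "centroid_y_um": fit.centroid_um[0],
                "centroid_x_um": fit.centroid_um[1],
                "direction_y": fit.direction[0],
                "direction_x": fit.direction[1],
            }
        )
    per_cluster = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "size",
            "rmse_um",
            "centroid_y_um",
            "centroid_x_um",
            "direction_y",
            "direction_x",
        ],
    )
    avg = float(per_cluster["rmse_um"].mean()) if rows else None
    return ClusterSummary(
        n_clusters=assignment.n_clusters, per_cluster=per_cluster, average_rmse_um=avg
    )


def analyze_clusters(
    nuclei: NucleusSet, params: ClusterParams | None = None
) -> tuple[ClusterAssignment, ClusterSummary]:
    """Cluster the nuclei and fit a trendline per cluster, in one call."""
    params = params or ClusterParams()
    assignment = cluster_nuclei(nuclei, params)
    points = nuclei.centroids_um
    fits = [fit_trendline(points[assignment.members(k)]) for k in range(1, assignment.n_clusters + 1)]
    return assignment, summarize_clusters(assignment, fits)
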