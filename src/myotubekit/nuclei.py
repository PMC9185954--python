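"""Nucleus detection, classification and the fusion index.

Nucleus centers are proposed automatically from the blue (Hoechst) channel:
the image is smoothed with a disk-shaped averaging filter whose radius
matches an average nucleus (10 um diameter by default, converted to pixels
through the calibration), regional intensity maxima of the smoothed image
above a foreground threshold become watershed seeds, and the thresholded
foreground is watershed-segmented from those seeds.  One centroid per
segmented object is returned.  Maxima closer together than one nucleus
radius collapse into a single seed, so a nucleus never yields two centroids
merely because its smoothed profile has a flat or noisy top.

A nucleus is counted as "inside a myotube" when its centroid pixel falls on
a labeled myotube object — centroids are the only nucleus geometry retained,
so membership is a point-in-mask test.  The fusion index is the fraction of
all nuclei whose centroid lies inside a MyHC-positive myotube, the standard
readout of myoblast fusion.  An optional green marker channel (e.g. MYOD)
classifies nuclei as marker-positive by the same centroid test against a
fixed-threshold green mask.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, morphology, segmentation

from .errors import (
    CalibrationError,
    InvalidThresholdError,
    NoMatchError,
    ShapeMismatchError,
    UndefinedFusionIndexError,
)
from .mask import MyotubeMask
from .preprocessing import ChannelImage, PixelCalibration

__all__ = [
    "NucleusSet",
    "FusionIndex",
    "DEFAULT_NUCLEUS_DIAMETER_UM",
    "nucleus_radius_px",
    "detect_nuclei",
    "edit_nuclei",
    "classify_in_myotube",
    "classify_marker",
    "fusion_index",
]

DEFAULT_NUCLEUS_DIAMETER_UM = 10.0
DEFAULT_MARKER_THRESHOLD = 0.5


@dataclasses.dataclass
class NucleusSet:
    """Detected nucleus centroids with their classification flags.

    Attributes
    ----------
    centroids
        (n, 2) float array of (row, col) pixel coordinates.
    in_myotube
        (n,) bool; True where the centroid falls on a labeled myotube.
    myotube_label
        (n,) int; the label of that myotube, 0 outside.
    marker_positive
        (n,) bool; meaningful only when ``has_marker`` is True.
    has_marker
        Whether a marker (green) channel was classified.
    calibration
        Pixel calibration, used to report centroid coordinates in microns.
    """

    centroids: np.ndarray
    calibration: PixelCalibration
    in_myotube: np.ndarray = None  # type: ignore[assignment]
    myotube_label: np.ndarray = None  # type: ignore[assignment]
    marker_positive: np.ndarray = None  # type: ignore[assignment]
    has_marker: bool = False

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        n = len(self.centroids)
        if self.in_myotube is None:
            self.in_myotube = np.zeros(n, dtype=bool)
        if self.myotube_label is None:
            self.myotube_label = np.zeros(n, dtype=int)
        if self.marker_positive is None:
            self.marker_positive = np.zeros(n, dtype=bool)
        self.in_myotube = np.asarray(self.in_myotube, dtype=bool)
        self.myotube_label = np.asarray(self.myotube_label, dtype=int)
        self.marker_positive = np.asarray(self.marker_positive, dtype=bool)
        for arr, name in (
            (self.in_myotube, "in_myotube"),
            (self.myotube_label, "myotube_label"),
            (self.marker_positive, "marker_positive"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per nucleus")
        if bool(np.any((self.myotube_label > 0) != self.in_myotube)):
            raise ValueError("myotube_label must be positive exactly where in_myotube")

    def __len__(self) -> int:
        return len(self.centroids)

    @property
    def centroids_um(self) -> np.ndarray:
        """Centroids in microns, same (row, col) axis order."""
        return self.centroids * self.calibration.microns_per_pixel

    @property
    def counts(self) -> dict[str, int]:
        """The four nucleus counts reported per image set."""
        c = {
            "total": int(len(self)),
            "in_myotubes": int(self.in_myotube.sum()),
        }
        if self.has_marker:
            c["marker_total"] = int(self.marker_positive.sum())
            c["marker_in_myotubes"] = int((self.marker_positive & self.in_myotube).sum())
        return c

    def to_dataframe(self) -> pd.DataFrame:
        mpp = self.calibration.microns_per_pixel
        df = pd.DataFrame(
            {
                "row_px": self.centroids[:, 0],
                "col_px": self.centroids[:, 1],
                "y_um": self.centroids[:, 0] * mpp,
                "x_um": self.centroids[:, 1] * mpp,
                "in_myotube": self.in_myotube,
                "myotube_label": self.myotube_label,
            }
        )
        df["marker_positive"] = self.marker_positive if self.has_marker else pd.NA
        return df

    def replace(self, **kwargs) -> "NucleusSet":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class FusionIndex:
    """Nuclei inside MyHC-positive myotubes over all nuclei, in [0, 1]."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator


def nucleus_radius_px(calibration: PixelCalibration, diameter_um: float) -> int:
    """Nucleus radius in whole pixels at this calibration (>= 1)."""
    radius = calibration.to_pixels(diameter_um) / 2.0
    if calibration.to_pixels(diameter_um) <= 1.0:
        raise CalibrationError(
            f"nucleus diameter {diameter_um} um is <= 1 px at "
            f"{calibration.microns_per_pixel} um/px; calibration too coarse"
        )
    return max(1, int(round(radius)))


def detect_nuclei(
    image: ChannelImage,
    nucleus_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM,
    foreground_threshold: float | None = None,
) -> NucleusSet:
    """Detect nucleus centroids by disk-filter-seeded watershed.

    Parameters
    ----------
    image
        The (adjusted) nuclear channel.
    nucleus_diameter_um
        Average nucleus diameter; sets the smoothing-disk radius and the
        minimum seed separation.  Default 10 um.
    foreground_threshold
        Intensity separating nuclear foreground from background on the
        smoothed image.  Defaults to Otsu's threshold.

    Returns
    -------
    NucleusSet
        One centroid per watershed object, unclassified.
    """
    radius = nucleus_radius_px(image.calibration, nucleus_diameter_um)
    disk = morphology.disk(radius).astype(float)
    disk /= disk.sum()
    smoothed = ndimage.convolve(image.pixels, disk, mode="nearest")

    if foreground_threshold is None:
        if smoothed.max() == smoothed.min():
            return NucleusSet(np.empty((0, 2)), image.calibration)
        foreground_threshold = float(filters.threshold_otsu(smoothed))
    foreground = smoothed > foreground_threshold
    if not foreground.any():
        return NucleusSet(np.empty((0, 2)), image.calibration)

    # seeds: regional maxima of the smoothed image, at least one radius apart
    peaks = feature.peak_local_max(
        smoothed,
        min_distance=radius,
        threshold_abs=foreground_threshold,
        labels=foreground,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return NucleusSet(np.empty((0, 2)), image.calibration)
    markers = np.zeros(image.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-smoothed, markers=markers, mask=foreground)

    centroids = ndimage.center_of_mass(foreground, labels, index=np.arange(1, len(peaks) + 1))
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    centroids = centroids[~np.isnan(centroids).any(axis=1)]
    return NucleusSet(centroids, image.calibration)


def edit_nuclei(
    nuclei: NucleusSet,
    add: Sequence[tuple[float, float]] = (),
    remove: Sequence[tuple[float, float]] = (),
    capture_radius_px: float | None = None,
    nucleus_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM,
) -> NucleusSet:
    """Add and remove centroids, mirroring the manual correction step.

    Each removal point deletes the nearest existing centroid within the
    capture radius (default: one nucleus radius); a removal point with no
    centroid in range raises :class:`NoMatchError`.  Added nuclei start
    unclassified; re-run the classification steps afterwards.
    """
    if capture_radius_px is None:
        capture_radius_px = nucleus_radius_px(nuclei.calibration, nucleus_diameter_um)
    centroids = list(map(tuple, nuclei.centroids))
    for pt in add:
        centroids.append((float(pt[0]), float(pt[1])))
    for pt in remove:
        if not centroids:
            raise NoMatchError(f"no centroid within capture radius of {tuple(pt)}")
        arr = np.asarray(centroids, dtype=float)
        d = np.hypot(arr[:, 0] - pt[0], arr[:, 1] - pt[1])
        idx = int(np.argmin(d))
        if d[idx] > capture_radius_px:
            raise NoMatchError(f"no centroid within capture radius of {tuple(pt)}")
        centroids.pop(idx)
    arr = np.asarray(centroids, dtype=float).reshape(-1, 2)
    return NucleusSet(arr, nuclei.calibration, has_marker=nuclei.has_marker)


def _centroid_pixels(nuclei: NucleusSet, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.clip(np.round(nuclei.centroids[:, 0]).astype(int), 0, shape[0] - 1)
    cols = np.clip(np.round(nuclei.centroids[:, 1]).astype(int), 0, shape[1] - 1)
    return rows, cols


def classify_in_myotube(nuclei: NucleusSet, mask: MyotubeMask) -> NucleusSet:
    """Flag each nucleus whose centroid pixel lies on a labeled myotube."""
    shape = mask.binary.shape
    if len(nuclei) and (
        nuclei.centroids[:, 0].max() > shape[0] - 0.5 or nuclei.centroids[:, 1].max() > shape[1] - 0.5
    ):
        raise ShapeMismatchError("nucleus centroids fall outside the mask dimensions")
    rows, cols = _centroid_pixels(nuclei, shape)
    labels = mask.labels[rows, cols] if len(nuclei) else np.zeros(0, dtype=int)
    return nuclei.replace(in_myotube=labels > 0, myotube_label=labels)


def classify_marker(
    nuclei: NucleusSet,
    marker: ChannelImage,
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD,
) -> NucleusSet:
    """Flag marker-positive nuclei from the thresholded green channel."""
    if not (0.0 <= marker_threshold <= 1.0):
        raise InvalidThresholdError(f"marker threshold must lie in [0, 1], got {marker_threshold}")
    shape = marker.shape
    if len(nuclei) and (
        nuclei.centroids[:, 0].max() > shape[0] - 0.5 or nuclei.centroids[:, 1].max() > shape[1] - 0.5
    ):
        raise ShapeMismatchError("nucleus centroids fall outside the marker image dimensions")
    green_mask = marker.pixels > marker_threshold
    rows, cols = _centroid_pixels(nuclei, shape)
    positive = green_mask[rows, cols] if len(nuclei) else np.zeros(0, dtype=bool)
    return nuclei.replace(marker_positive=positive, has_marker=True)


def fusion_index(nuclei: NucleusSet) -> FusionIndex:
    """Fusion index = nuclei in myotubes / total nuclei.

    Raises :class:`UndefinedFusionIndexError` for an empty nucleus set
    rather than silently reporting 0.
    """
    total = len(nuclei)
    if total == 0:
        raise UndefinedFusionIndexError("fusion index undefined for zero nuclei")
    return FusionIndex(numerator=int(nuclei.in_myotube.sum()), denominator=total)
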