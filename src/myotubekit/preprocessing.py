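"""Channel loading and histogram intensity windowing.

A field of view arrives as up to three single-channel images: blue for the
nuclear stain (Hoechst), red for the myotube stain (anti-MyHC) and optionally
green for a nuclear marker such as MYOD.  Images are stored as floating-point
intensities normalized to [0, 1] regardless of on-disk bit depth, and every
image carries a pixel calibration (microns per pixel edge) so that downstream
geometry (nucleus diameters, clustering cutoffs) can be expressed in microns.

Coordinates throughout the package are (row, col), 0-based, pixel-center.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InvalidWindowError, UnsupportedFormatError

__all__ = [
    "PixelCalibration",
    "ChannelImage",
    "ROLES",
    "load_channel",
    "adjust_levels",
    "save_adjusted",
]

#: Valid channel roles and, for RGB input files, the plane each role reads.
ROLES = {"myotube": 0, "marker": 1, "nuclei": 2}


@dataclasses.dataclass(frozen=True)
class PixelCalibration:
    """Physical size of one pixel edge in microns.

    The same calibration is applied to every analysis step, which is what
    lets one parameter set cover images from different microscopes and
    magnifications.
    """

    microns_per_pixel: float

    def __post_init__(self) -> None:
        mpp = float(self.microns_per_pixel)
        if not math.isfinite(mpp) or mpp <= 0:
            raise ValueError(
                f"microns_per_pixel must be finite and > 0, got {self.microns_per_pixel!r}"
            )
        object.__setattr__(self, "microns_per_pixel", mpp)

    def to_pixels(self, microns: float) -> float:
        """Convert a length in microns to pixels."""
        return microns / self.microns_per_pixel

    def to_microns(self, pixels: float) -> float:
        """Convert a length in pixels to microns."""
        return pixels * self.microns_per_pixel


@dataclasses.dataclass
class ChannelImage:
    """A single-channel grayscale raster with a role and calibration.

    Attributes
    ----------
    pixels
        2-D float array with values in [0, 1].
    role
        One of ``"nuclei"``, ``"myotube"``, ``"marker"``.
    calibration
        The pixel-size calibration shared across the analysis.
    """

    pixels: np.ndarray
    role: str
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {self.pixels.shape}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {sorted(ROLES)}, got {self.role!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer raster to [0, 1] by its dtype's max representable value."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    # already float: assume the producer normalized it
    out = arr.astype(float)
    if out.size and out.max() > 1.0:
        out = out / out.max()
    return np.clip(out, 0.0, 1.0)


def load_channel(path: str | Path, role: str, calibration: PixelCalibration) -> ChannelImage:
    """Load one channel from a PNG or JPEG file.

    Grayscale files are used as-is; RGB(A) files contribute the plane
    matching ``role`` (blue -> nuclei, red -> myotube, green -> marker).
    Intensities are rescaled to [0, 1] by the source bit depth.

    Raises
    ------
    UnsupportedFormatError
        For TIFF input, which the pipeline deliberately does not accept,
        or any other non-PNG/JPEG format.
    OSError
        If the file is missing or unreadable.
    """
    path = Path(path)
    if role not in ROLES:
        raise ValueError(f"role must be one of {sorted(ROLES)}, got {role!r}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        raise UnsupportedFormatError(f"TIFF input is not supported: {path}")
    with Image.open(path) as im:
        if im.format not in {"PNG", "JPEG"}:
            raise UnsupportedFormatError(
                f"unsupported image format {im.format!r} (PNG or JPEG required): {path}"
            )
        if im.mode == "I;16":
            arr = np.asarray(im, dtype=np.uint16)
        else:
            arr = np.asarray(im)
    if arr.ndim == 3:
        plane = min(ROLES[role], arr.shape[2] - 1)
        arr = arr[:, :, plane]
    return ChannelImage(pixels=_normalize(arr), role=role, calibration=calibration)


def adjust_levels(image: ChannelImage, window_low: float, window_high: float) -> ChannelImage:
    """Spread the intensity window [low, high] over the full [0, 1] range.

    Pixels at or below ``window_low`` map to 0, pixels at or above
    ``window_high`` to 1, and the window interior is stretched linearly.
    This is the contrast adjustment applied to each channel before
    thresholding; it compensates for short exposure times used to avoid
    bleaching the stain.
    """
    low, high = float(window_low), float(window_high)
    if not (low < high):
        raise InvalidWindowError(f"window_low must be < window_high, got [{low}, {high}]")
    out = np.clip((image.pixels - low) / (high - low), 0.0, 1.0)
    return ChannelImage(pixels=out, role=image.role, calibration=image.calibration)


def save_adjusted(image: ChannelImage, input_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Persist an adjusted channel as 8-bit PNG next to (or near) its input.

    The output is named ``<input stem>_adjusted.png`` and overwrites any
    previous adjusted image, so repeated adjustment never accumulates files.
    """
    input_path = Path(input_path)
    directory = Path(out_dir) if out_dir is not None else input_path.parent
    directory.mkdir(parents=True, exist_ok=True)
    out_path = directory / f"{input_path.stem}_adjusted.png"
    raster = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(raster, mode="L").save(out_path, format="PNG")
    return out_path
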