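"""Binary myotube mask construction, editing and labeling.

The myotube (red, anti-MyHC) channel is segmented by a manual global
threshold: staining intensity varies with protein expression and imaging
settings, so no universal automatic threshold exists.  The rough mask is then
cleaned with the classic curation steps — removing junk objects smaller than
1000 px, filling holes that do not touch the image border — and optionally
corrected with an edit script that replays the manual corrections a GUI user
would draw: polygons to add or remove regions, polylines to separate touching
myotubes or join broken ones.  Finally the mask is labeled into separate
myotube objects; the label count is the "number of myotubes" parameter.

Connectivity convention: foreground is 8-connected, background 4-connected
(the standard dual pair).  Separation lines default to 2 px wide so that a
drawn line actually severs 8-connected foreground.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure, morphology

from .errors import (
    InvalidEditError,
    InvalidParameterError,
    InvalidThresholdError,
)
from .preprocessing import ChannelImage, PixelCalibration

__all__ = [
    "BinaryMask",
    "MyotubeMask",
    "Edit",
    "EditScript",
    "threshold_mask",
    "remove_junk",
    "fill_holes",
    "apply_edits",
    "label_myotubes",
    "DEFAULT_MIN_JUNK_AREA",
    "DEFAULT_SEPARATE_WIDTH",
]

DEFAULT_MIN_JUNK_AREA = 1000  # px; objects strictly smaller are junk
DEFAULT_SEPARATE_WIDTH = 2  # px; wide enough to sever 8-connected foreground
_FG_CONNECTIVITY = 2  # skimage connectivity=2 == 8-connected


@dataclasses.dataclass
class BinaryMask:
    """A foreground/background raster with pixel calibration."""

    pixels: np.ndarray
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"mask must be a non-empty 2-D array, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.pixels.copy(), self.calibration)


@dataclasses.dataclass
class MyotubeMask:
    """A binary mask plus its labeling into separate myotube objects.

    ``labels`` is 0 on background and k in 1..n_myotubes on the k-th object;
    labels are contiguous.
    """

    binary: BinaryMask
    labels: np.ndarray
    n_myotubes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.binary.shape:
            raise ValueError("labels and binary mask must share dimensions")
        if bool(np.any((self.labels > 0) != self.binary.pixels)):
            raise ValueError("labels must be positive exactly on foreground")
        present = np.unique(self.labels[self.labels > 0])
        if len(present) != self.n_myotubes or (
            len(present) and (present.min() != 1 or present.max() != self.n_myotubes)
        ):
            raise ValueError("label values must be contiguous 1..n_myotubes")


@dataclasses.dataclass(frozen=True)
class Edit:
    """One edit operation.

    ``op`` is one of add_region, remove_region, separate_line, join_line,
    remove_junk, fill_holes.  Region ops carry a polygon, line ops a
    polyline, both as (row, col) vertex lists.
    """

    op: str
    vertices: tuple[tuple[float, float], ...] = ()
    min_area: int = DEFAULT_MIN_JUNK_AREA
    width: int = DEFAULT_SEPARATE_WIDTH

    _OPS = ("add_region", "remove_region", "separate_line", "join_line", "remove_junk", "fill_holes")

    def __post_init__(self) -> None:
        if self.op not in self._OPS:
            raise InvalidEditError(f"unknown edit op {self.op!r}")
        if self.op.endswith(("_region", "_line")) and len(self.vertices) < 2:
            raise InvalidEditError(f"{self.op} requires >= 2 vertices, got {len(self.vertices)}")


@dataclasses.dataclass
class EditScript:
    """An ordered list of edits, replayable on any mask of matching size.

    Serialized as JSON so GUI-style manual corrections are reproducible and
    versionable::

        {"edits": [{"op": "add_region", "vertices": [[r, c], ...]},
                   {"op": "remove_junk", "min_area": 1000}]}
    """

    edits: list[Edit] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "edits": [
                {k: v for k, v in dataclasses.asdict(e).items() if k == "op" or v not in ((), None)}
                for e in self.edits
            ]
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EditScript":
        payload = json.loads(text)
        edits = []
        for entry in payload.get("edits", []):
            entry = dict(entry)
            verts = tuple(tuple(float(x) for x in v) for v in entry.pop("vertices", ()))
            edits.append(Edit(vertices=verts, **entry))
        return cls(edits=edits)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "EditScript":
        return cls.from_json(Path(path).read_text())


def threshold_mask(image: ChannelImage, threshold: float) -> BinaryMask:
    """Segment the myotube channel by a global threshold (strict ``>``).

    Pixels exactly at the threshold are background; the boundary convention
    is fixed so results are deterministic.
    """
    t = float(threshold)
    if not (0.0 <= t <= 1.0):
        raise InvalidThresholdError(f"threshold must lie in [0, 1], got {t}")
    return BinaryMask(image.pixels > t, image.calibration)


def remove_junk(mask: BinaryMask, min_area: int = DEFAULT_MIN_JUNK_AREA) -> BinaryMask:
    """Drop every foreground component with area < ``min_area`` pixels.

    The area unit is raw pixels (not microns squared).  Components with area
    exactly ``min_area`` survive.
    """
    if min_area <= 0:
        raise InvalidParameterError(f"min_area must be > 0, got {min_area}")
    labels = measure.label(mask.pixels, connectivity=_FG_CONNECTIVITY)
    areas = np.bincount(labels.ravel())
    keep = areas >= int(min_area)
    keep[0] = False
    return BinaryMask(keep[labels], mask.calibration)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background components that do not touch the image border.

    Background connectivity is 4-connected (dual of the 8-connected
    foreground), so diagonal background chains do not count as escapes.
    """
    filled = ndimage.binary_fill_holes(mask.pixels)  # default structure = 4-connectivity
    return BinaryMask(filled, mask.calibration)


def _check_bounds(vertices: Iterable[Sequence[float]], shape: tuple[int, int], index: int) -> None:
    for r, c in vertices:
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise InvalidEditError(
                f"edit {index}: vertex ({r}, {c}) outside image bounds {shape}"
            )


def _rasterize_polyline(
    vertices: Sequence[Sequence[float]], shape: tuple[int, int], width: int
) -> np.ndarray:
    """8-connected polyline raster, thickened to ``width`` px by dilation."""
    out = np.zeros(shape, dtype=bool)
    pts = [(int(round(r)), int(round(c))) for r, c in vertices]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        out[rr, cc] = True
    if width > 1:
        # a (width x width) footprint grows the 1-px line to the requested width
        out = morphology.dilation(out, footprint=np.ones((width, width), dtype=bool))
    return out


def _rasterize_polygon(vertices: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rows = np.array([v[0] for v in vertices], dtype=float)
    cols = np.array([v[1] for v in vertices], dtype=float)
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    out[rr, cc] = True
    # include the outline so thin polygons are not lost to interior-only fill
    prr, pcc = skdraw.polygon_perimeter(rows, cols, shape=shape)
    out[prr, pcc] = True
    return out


def apply_edits(mask: BinaryMask, script: EditScript) -> BinaryMask:
    """Replay an edit script on a mask, in order.

    add_region / remove_region set a polygon interior to foreground /
    background; separate_line / join_line rasterize a polyline (default
    2 px wide) to background / foreground; remove_junk and fill_holes apply
    the corresponding cleanup at that point in the sequence.
    """
    out = mask.copy()
    for i, edit in enumerate(script.edits):
        if edit.op in ("add_region", "remove_region", "separate_line", "join_line"):
            _check_bounds(edit.vertices, out.shape, i)
        if edit.op == "add_region":
            out.pixels |= _rasterize_polygon(edit.vertices, out.shape)
        elif edit.op == "remove_region":
            out.pixels &= ~_rasterize_polygon(edit.vertices, out.shape)
        elif edit.op == "separate_line":
            out.pixels &= ~_rasterize_polyline(edit.vertices, out.shape, edit.width)
        elif edit.op == "join_line":
            out.pixels |= _rasterize_polyline(edit.vertices, out.shape, edit.width)
        elif edit.op == "remove_junk":
            out = remove_junk(out, edit.min_area)
        elif edit.op == "fill_holes":
            out = fill_holes(out)
    return out


def label_myotubes(mask: BinaryMask) -> MyotubeMask:
    """Label 8-connected foreground components as separate myotubes."""
    labels, n = measure.label(mask.pixels, connectivity=_FG_CONNECTIVITY, return_num=True)
    return MyotubeMask(binary=mask.copy(), labels=labels, n_myotubes=int(n))
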