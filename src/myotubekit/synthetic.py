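"""Synthetic immunofluorescence scenes with full ground truth.

Real differentiated satellite-cell cultures are imaged as a blue nuclear
channel (Hoechst), a red myotube channel (anti-MyHC) and optionally a green
nuclear-marker channel (e.g. MYOD).  This module renders simplified but
structurally faithful versions of such fields of view so every pipeline
stage can be tested against known truth:

* myotubes are smooth bright ribbons of specified width following polyline
  paths in the red channel (round-capped, constant width), optionally
  branching;
* nuclei are anisotropic Gaussian blobs in the blue channel, truncated at
  2 sigma, some placed in chains along ribbon axes to emulate the nucleus
  clustering seen inside myotubes;
* marker-positive nuclei are re-rendered in the green channel;
* noise is Poisson shot noise plus Gaussian read noise behind a single
  ``noise_level`` knob (0 disables both).

The returned ground truth records the exact binary mask, per-ribbon labels,
the nucleus table (center, on-ribbon flag, marker flag, planted cluster
id), junction points of branched ribbons, ribbon widths and the exact
coverage, so detector output can be scored without circularity.  Identical
spec + seed reproduces the scene bit for bit.

What these scenes deliberately omit: optics (PSF blur, vignetting, chromatic
shift), uneven illumination, staining debris, and overlapping nuclei beyond
what the spacing parameters allow.  Passing on them shows algorithmic
correctness, not robustness to real acquisition artifacts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from PIL import Image

from .errors import SpecError
from .mask import BinaryMask, MyotubeMask
from .preprocessing import ChannelImage, PixelCalibration

__all__ = [
    "RibbonSpec",
    "NucleusSpec",
    "SceneSpec",
    "GroundTruth",
    "make_scene",
    "make_cluster_scene",
    "write_scene",
]


@dataclasses.dataclass(frozen=True)
class RibbonSpec:
    """One myotube ribbon: a polyline path with a constant width."""

    path: tuple[tuple[float, float], ...]  # (row, col) vertices
    width_px: float

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise SpecError("ribbon path needs >= 2 vertices")
        if self.width_px <= 0:
            raise SpecError(f"ribbon width must be > 0, got {self.width_px}")


@dataclasses.dataclass(frozen=True)
class NucleusSpec:
    """One nucleus: center, size, orientation and classification flags."""

    center: tuple[float, float]  # (row, col) px
    diameter_um: float = 10.0
    aspect: float = 1.4  # major/minor axis ratio of the blob
    angle: float = 0.0  # radians, major-axis orientation
    in_ribbon: bool = False
    marker: bool = False
    cluster_id: int = -1  # planted cluster membership, -1 = isolated


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic field of view."""

    shape: tuple[int, int] = (512, 512)
    microns_per_pixel: float = 1.0
    ribbons: tuple[RibbonSpec, ...] = ()
    nuclei: tuple[NucleusSpec, ...] = ()
    noise_level: float = 0.0
    background: float = 0.05
    ribbon_intensity: float = 0.85
    nucleus_peak: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 1 or w < 1:
            raise SpecError(f"invalid scene shape {self.shape}")
        for rib in self.ribbons:
            for r, c in rib.path:
                if not (0 <= r < h and 0 <= c < w):
                    raise SpecError(f"ribbon vertex ({r}, {c}) outside scene bounds {self.shape}")
        for nuc in self.nuclei:
            r, c = nuc.center
            if not (0 <= r < h and 0 <= c < w):
                raise SpecError(f"nucleus center ({r}, {c}) outside scene bounds {self.shape}")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows about the scene it rendered."""

    mask: MyotubeMask
    nuclei: pd.DataFrame  # row, col, in_ribbon, marker, cluster_id
    junctions: np.ndarray  # (m, 2) true branch-junction coordinates
    ribbon_widths_px: np.ndarray
    coverage_pct: float


def _ribbon_mask(shape: tuple[int, int], ribbon: RibbonSpec) -> np.ndarray:
    """Exact constant-width ribbon: pixels within width/2 of the polyline."""
    line = np.zeros(shape, dtype=bool)
    pts = [(int(round(r)), int(round(c))) for r, c in ribbon.path]
    from skimage.draw import line as skline

    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = skline(r0, c0, r1, c1)
        line[rr, cc] = True
    dist = ndimage.distance_transform_edt(~line)
    return dist <= ribbon.width_px / 2.0


def _render_nucleus(blue: np.ndarray, nuc: NucleusSpec, mpp: float, peak: float) -> None:
    """Add one truncated anisotropic Gaussian blob in place."""
    d_px = nuc.diameter_um / mpp
    sig_major = d_px / 4.0 * np.sqrt(nuc.aspect)
    sig_minor = d_px / 4.0 / np.sqrt(nuc.aspect)
    extent = int(np.ceil(2.0 * sig_major)) + 1
    r0, c0 = nuc.center
    rmin, rmax = int(np.floor(r0 - extent)), int(np.ceil(r0 + extent))
    cmin, cmax = int(np.floor(c0 - extent)), int(np.ceil(c0 + extent))
    rmin, cmin = max(rmin, 0), max(cmin, 0)
    rmax, cmax = min(rmax, blue.shape[0] - 1), min(cmax, blue.shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dr, dc = rr - r0, cc - c0
    u = dr * np.cos(nuc.angle) + dc * np.sin(nuc.angle)
    v = -dr * np.sin(nuc.angle) + dc * np.cos(nuc.angle)
    q = (u / sig_major) ** 2 + (v / sig_minor) ** 2
    blob = peak * np.exp(-0.5 * q)
    blob[q > 4.0] = 0.0  # truncate at 2 sigma
    patch = blue[rmin : rmax + 1, cmin : cmax + 1]
    np.maximum(patch, blob, out=patch)


def _add_noise(channel: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise plus Gaussian read noise, scaled by one knob."""
    if level <= 0:
        return channel
    photons = 200.0 / level
    shot = rng.poisson(channel * photons) / photons
    read = rng.normal(0.0, 0.02 * level, size=channel.shape)
    return np.clip(shot + read, 0.0, 1.0)


def make_scene(
    spec: SceneSpec,
) -> tuple[ChannelImage, ChannelImage, ChannelImage | None, GroundTruth]:
    """Render a scene spec into (blue, red, green-or-None, ground truth)."""
    calib = PixelCalibration(spec.microns_per_pixel)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape

    mask_px = np.zeros((h, w), dtype=bool)
    labels = np.zeros((h, w), dtype=int)
    junctions: list[tuple[float, float]] = []
    for k, ribbon in enumerate(spec.ribbons, start=1):
        rib = _ribbon_mask((h, w), ribbon)
        mask_px |= rib
        labels[rib] = k
    # merged ribbons become one object; relabel for contiguity
    from skimage.measure import label as cc_label

    labels, n_objects = cc_label(mask_px, connectivity=2, return_num=True)
    for ribbon in spec.ribbons:
        if len(ribbon.path) >= 3:
            # interior vertices of a branched path are junction candidates
            junctions.extend(ribbon.path[1:-1])

    red = np.full((h, w), spec.background)
    red[mask_px] = spec.ribbon_intensity
    blue = np.full((h, w), spec.background)
    green: np.ndarray | None = None
    rows = []
    for nuc in spec.nuclei:
        _render_nucleus(blue, nuc, spec.microns_per_pixel, spec.nucleus_peak)
        if nuc.marker:
            if green is None:
                green = np.full((h, w), spec.background)
            _render_nucleus(green, nuc, spec.microns_per_pixel, spec.nucleus_peak)
        rows.append(
            {
                "row": nuc.center[0],
                "col": nuc.center[1],
                "in_ribbon": nuc.in_ribbon,
                "marker": nuc.marker,
                "cluster_id": nuc.cluster_id,
            }
        )

    red = _add_noise(red, spec.noise_level, rng)
    blue = _add_noise(blue, spec.noise_level, rng)
    if green is not None:
        green = _add_noise(green, spec.noise_level, rng)

    truth = GroundTruth(
        mask=MyotubeMask(
            binary=BinaryMask(mask_px, calib), labels=labels, n_myotubes=int(n_objects)
        ),
        nuclei=pd.DataFrame(rows, columns=["row", "col", "in_ribbon", "marker", "cluster_id"]),
        junctions=np.asarray(junctions, dtype=float).reshape(-1, 2),
        ribbon_widths_px=np.asarray([r.width_px for r in spec.ribbons], dtype=float),
        coverage_pct=100.0 * float(mask_px.sum()) / mask_px.size,
    )
    blue_img = ChannelImage(blue, "nuclei", calib)
    red_img = ChannelImage(red, "myotube", calib)
    green_img = ChannelImage(green, "marker", calib) if green is not None else None
    return blue_img, red_img, green_img, truth


def make_cluster_scene(
    k_clusters: int,
    nuclei_per_cluster: int = 6,
    jitter_um: float = 0.5,
    n_isolated: int = 8,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    microns_per_pixel: float = 1.0,
    spacing_um: float = 12.0,
    nucleus_diameter_um: float = 10.0,
    ribbon_width_px: float | None = 21.0,
) -> SceneSpec:
    """Plant k line-aligned nucleus clusters plus isolated nuclei.

    Within-cluster spacing (default 12 um) is below the 14 um clustering
    cutoff; cluster-to-cluster and isolated-nucleus spacing is kept above
    twice the cutoff so planted structure is unambiguous.  ``jitter_um``
    displaces each nucleus perpendicular to its cluster line, controlling
    the true cluster RMSE.  Unless ``ribbon_width_px`` is None, a myotube
    ribbon is laid along each cluster line (clustered nuclei are inside
    it, isolated nuclei are kept off every ribbon), so the scene exercises
    the mask and fusion-index stages too.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    mpp = microns_per_pixel
    cutoff_um = 14.0
    margin_px = 20.0
    cluster_len_px = (nuclei_per_cluster - 1) * spacing_um / mpp

    anchors: list[np.ndarray] = []  # cluster line endpoints + isolated points, px
    segments: list[tuple[np.ndarray, np.ndarray]] = []  # cluster lines, px
    nuclei: list[NucleusSpec] = []

    def far_enough(candidate_pts: np.ndarray) -> bool:
        sep_px = 2.0 * cutoff_um / mpp
        for existing in anchors:
            d = np.sqrt(
                ((candidate_pts[:, None, :] - existing[None, :, :]) ** 2).sum(axis=2)
            )
            if d.min() < sep_px:
                return False
        return True

    def off_ribbons(pt: np.ndarray) -> bool:
        if ribbon_width_px is None:
            return True
        clearance = ribbon_width_px / 2.0 + 5.0
        for a, b in segments:
            ab = b - a
            t = float(np.clip(np.dot(pt - a, ab) / np.dot(ab, ab), 0.0, 1.0))
            if float(np.hypot(*(pt - (a + t * ab)))) < clearance:
                return False
        return True

    for cid in range(k_clusters):
        placed = False
        for _ in range(300):
            angle = rng.uniform(0, np.pi)
            direction = np.array([np.sin(angle), np.cos(angle)])
            max_start = np.array([h - 1 - margin_px, w - 1 - margin_px])
            start = rng.uniform([margin_px, margin_px], max_start)
            end = start + direction * cluster_len_px
            if not (margin_px <= end[0] <= h - 1 - margin_px and margin_px <= end[1] <= w - 1 - margin_px):
                continue
            t = np.arange(nuclei_per_cluster) * spacing_um / mpp
            centers = start[None, :] + t[:, None] * direction[None, :]
            perp = np.array([-direction[1], direction[0]])
            offsets = rng.normal(0.0, jitter_um / mpp, size=nuclei_per_cluster)
            centers = centers + offsets[:, None] * perp[None, :]
            if not far_enough(centers):
                continue
            anchors.append(centers)
            segments.append((start, end))
            for ctr in centers:
                nuclei.append(
                    NucleusSpec(
                        center=(float(ctr[0]), float(ctr[1])),
                        diameter_um=nucleus_diameter_um,
                        angle=float(angle),
                        cluster_id=cid,
                        in_ribbon=True,
                    )
                )
            placed = True
            break
        if not placed:
            raise SpecError(
                f"could not place cluster {cid}: scene too dense for {k_clusters} clusters"
            )

    for _ in range(n_isolated):
        for _ in range(300):
            pt = rng.uniform([margin_px, margin_px], [h - 1 - margin_px, w - 1 - margin_px])
            if far_enough(pt[None, :]) and off_ribbons(pt):
                anchors.append(pt[None, :])
                nuclei.append(
                    NucleusSpec(
                        center=(float(pt[0]), float(pt[1])),
                        diameter_um=nucleus_diameter_um,
                        angle=float(rng.uniform(0, np.pi)),
                    )
                )
                break
        else:
            raise SpecError("could not place isolated nuclei: scene too dense")

    ribbons: list[RibbonSpec] = []
    if ribbon_width_px is not None:
        extend = 1.5 * nucleus_diameter_um / mpp
        for a, b in segments:
            direction = (b - a) / np.hypot(*(b - a))
            p0 = np.clip(a - extend * direction, 2.0, [h - 3.0, w - 3.0])
            p1 = np.clip(b + extend * direction, 2.0, [h - 3.0, w - 3.0])
            ribbons.append(
                RibbonSpec(
                    path=((float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))),
                    width_px=ribbon_width_px,
                )
            )

    return SceneSpec(
        shape=shape,
        microns_per_pixel=mpp,
        ribbons=tuple(ribbons),
        nuclei=tuple(nuclei),
        seed=seed,
    )


def write_scene(
    spec: SceneSpec, out_dir: str | Path, name: str = "scene"
) -> dict[str, Path]:
    """Materialize a scene as the PNG-per-channel layout the pipeline reads.

    Writes ``<name>_blue.png``, ``<name>_red.png`` (and ``_green.png`` when
    marker nuclei exist) plus a ``<name>_truth.csv`` nucleus table; returns
    the path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blue, red, green, truth = make_scene(spec)
    paths: dict[str, Path] = {}

    def save(img: ChannelImage, channel: str) -> None:
        p = out_dir / f"{name}_{channel}.png"
        Image.fromarray(np.round(img.pixels * 255).astype(np.uint8), mode="L").save(p)
        paths[channel] = p

    save(blue, "blue")
    save(red, "red")
    if green is not None:
        save(green, "green")
    truth_path = out_dir / f"{name}_truth.csv"
    truth.nuclei.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
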