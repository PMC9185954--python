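"""End-to-end pipeline: config-driven per-image analysis with resumable steps.

The analysis is modular: each step reads its prerequisites from the output
directory and writes its own artifacts there, so any step can be re-run
(after, say, replacing an edit script) without redoing the earlier ones.
Step order::

    adjust -> mask -> nuclei -> clusters -> branch_points -> diameters -> summary

Per image set the pipeline writes suffix-named PNGs
(``<name>_<channel>_adjusted.png``, ``<name>_mask.png``, ``<name>_labels.png``,
``<name>_nuclei.png``, ``<name>_clusters.png``, ``<name>_skeleton.png``,
``<name>_disttrans.png``), one CSV per step, and a combined workbook
``<name>_results.xlsx`` with one sheet per step.  A ``run_log.json`` records
every parameter so any output is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import plots
from .clustering import ClusterParams, analyze_clusters
from .errors import DependencyError, MyotubeKitError
from .mask import (
    DEFAULT_MIN_JUNK_AREA,
    BinaryMask,
    EditScript,
    MyotubeMask,
    apply_edits,
    fill_holes,
    label_myotubes,
    remove_junk,
    threshold_mask,
)
from .myotube_features import (
    coverage,
    find_branch_points,
    measure_diameters,
    myotube_feature_summary,
    skeletonize_mask,
    summary_frame,
)
from .nuclei import (
    DEFAULT_MARKER_THRESHOLD,
    DEFAULT_NUCLEUS_DIAMETER_UM,
    NucleusSet,
    classify_in_myotube,
    classify_marker,
    detect_nuclei,
    fusion_index,
)
from .preprocessing import PixelCalibration, adjust_levels, load_channel, save_adjusted

__all__ = ["ImageSetConfig", "RunConfig", "run_pipeline", "resume_step", "STEPS"]

STEPS = ["adjust", "mask", "nuclei", "clusters", "branch_points", "diameters", "summary"]

SHEETS = ["nuclei", "clusters", "branch_points", "diameters", "summary"]


@dataclasses.dataclass
class ImageSetConfig:
    """Input file mapping for one field of view."""

    name: str
    blue: Path
    red: Path
    green: Path | None = None
    edit_script: Path | None = None
    diameter_points: Path | None = None  # CSV with row,col sample points

    def __post_init__(self) -> None:
        self.blue, self.red = Path(self.blue), Path(self.red)
        self.green = Path(self.green) if self.green else None
        self.edit_script = Path(self.edit_script) if self.edit_script else None
        self.diameter_points = Path(self.diameter_points) if self.diameter_points else None


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters plus the image-set inputs.

    Defaults follow the published analysis conditions: 10 um nucleus
    diameter, 14 um clustering cutoff (10 + 4 um edge gap), minimum
    cluster size 4, junk filter at 1000 px.
    """

    output_dir: Path
    microns_per_pixel: float
    image_sets: list[ImageSetConfig]
    window: tuple[float, float] = (0.0, 1.0)
    mask_threshold: float = 0.3
    nucleus_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM
    nucleus_threshold: float | None = None  # None -> Otsu
    marker_threshold: float = DEFAULT_MARKER_THRESHOLD
    max_edge_gap_um: float = 4.0
    min_cluster_size: int = 4
    junk_min_area: int = DEFAULT_MIN_JUNK_AREA
    min_branch_length: int = 0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.image_sets = [
            s if isinstance(s, ImageSetConfig) else ImageSetConfig(**s) for s in self.image_sets
        ]

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(self.microns_per_pixel)

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            nucleus_diameter_um=self.nucleus_diameter_um,
            max_edge_gap_um=self.max_edge_gap_um,
            min_size=self.min_cluster_size,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        window = payload.pop("window", (0.0, 1.0))
        cfg = cls(window=tuple(window), **payload)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        for s in d["image_sets"]:
            for key in ("blue", "red", "green", "edit_script", "diameter_points"):
                if s[key] is not None:
                    s[key] = str(s[key])
        return d


def _set_dir(config: RunConfig, name: str) -> Path:
    d = config.output_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, step: str) -> Path:
    if not path.exists():
        raise DependencyError(f"step {step!r} requires missing artifact {path}")
    return path


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------- steps


def _step_adjust(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    low, high = config.window
    for channel, path, role in (
        ("blue", iset.blue, "nuclei"),
        ("red", iset.red, "myotube"),
        ("green", iset.green, "marker"),
    ):
        if path is None:
            continue
        img = load_channel(path, role, config.calibration)
        adjusted = adjust_levels(img, low, high)
        target = out / f"{iset.name}_{channel}.png"  # stable stem for downstream steps
        save_adjusted(adjusted, target, out)


def _adjusted(config: RunConfig, iset: ImageSetConfig, channel: str, role: str, step: str):
    out = _set_dir(config, iset.name)
    path = _require(out / f"{iset.name}_{channel}_adjusted.png", step)
    return load_channel(path, role, config.calibration)


def _step_mask(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    red = _adjusted(config, iset, "red", "myotube", "mask")
    mask = threshold_mask(red, config.mask_threshold)
    mask = remove_junk(mask, config.junk_min_area)
    mask = fill_holes(mask)
    if iset.edit_script is not None:
        mask = apply_edits(mask, EditScript.load(iset.edit_script))
    labeled = label_myotubes(mask)
    from PIL import Image

    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(
        out / f"{iset.name}_mask.png"
    )
    np.save(out / f"{iset.name}_labels.npy", labeled.labels)
    plots.save_labels_png(labeled, out / f"{iset.name}_labels.png")


def _load_mask(config: RunConfig, iset: ImageSetConfig, step: str) -> MyotubeMask:
    out = _set_dir(config, iset.name)
    labels = np.load(_require(out / f"{iset.name}_labels.npy", step))
    binary = BinaryMask(labels > 0, config.calibration)
    return MyotubeMask(binary=binary, labels=labels, n_myotubes=int(labels.max()))


def _step_nuclei(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    blue = _adjusted(config, iset, "blue", "nuclei", "nuclei")
    mask = _load_mask(config, iset, "nuclei")
    nuclei = detect_nuclei(blue, config.nucleus_diameter_um, config.nucleus_threshold)
    nuclei = classify_in_myotube(nuclei, mask)
    if iset.green is not None:
        green = _adjusted(config, iset, "green", "marker", "nuclei")
        nuclei = classify_marker(nuclei, green, config.marker_threshold)
    _write_csv(nuclei.to_dataframe(), out / f"{iset.name}_nuclei.csv")
    red = _adjusted(config, iset, "red", "myotube", "nuclei")
    plots.save_nuclei_overlay(nuclei, blue, out / f"{iset.name}_nuclei.png", red=red)


def _load_nuclei(config: RunConfig, iset: ImageSetConfig, step: str) -> NucleusSet:
    out = _set_dir(config, iset.name)
    df = pd.read_csv(_require(out / f"{iset.name}_nuclei.csv", step))
    marker = df["marker_positive"]
    has_marker = len(df) > 0 and bool(marker.notna().any())
    return NucleusSet(
        centroids=df[["row_px", "col_px"]].to_numpy(float),
        calibration=config.calibration,
        in_myotube=df["in_myotube"].to_numpy(bool),
        myotube_label=df["myotube_label"].to_numpy(int),
        marker_positive=marker.fillna(False).astype(bool).to_numpy()
        if has_marker
        else np.zeros(len(df), dtype=bool),
        has_marker=bool(has_marker),
    )


def _step_clusters(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    nuclei = _load_nuclei(config, iset, "clusters")
    assignment, summary = analyze_clusters(nuclei, config.cluster_params)
    _write_csv(summary.per_cluster, out / f"{iset.name}_clusters.csv")
    assign_df = pd.DataFrame(
        {"nucleus": np.arange(len(nuclei)), "cluster": assignment.labels}
    )
    _write_csv(assign_df, out / f"{iset.name}_cluster_assignment.csv")
    plots.save_cluster_plot(nuclei, assignment, out / f"{iset.name}_clusters.png")


def _step_branch_points(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    mask = _load_mask(config, iset, "branch_points")
    skeleton = skeletonize_mask(mask)
    points = find_branch_points(skeleton, config.min_branch_length)
    df = pd.DataFrame(points.points, columns=["row_px", "col_px"])
    _write_csv(df, out / f"{iset.name}_branch_points.csv")
    plots.save_skeleton_overlay(mask, skeleton, points, out / f"{iset.name}_skeleton.png")
    plots.save_distance_transform(mask, out / f"{iset.name}_disttrans.png")


def _step_diameters(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    columns = ["sample_row", "sample_col", "skel_row", "skel_col", "diameter_px", "diameter_um"]
    if iset.diameter_points is None:
        _write_csv(pd.DataFrame(columns=columns), out / f"{iset.name}_diameters.csv")
        return
    mask = _load_mask(config, iset, "diameters")
    skeleton = skeletonize_mask(mask)
    pts = pd.read_csv(iset.diameter_points)[["row", "col"]].to_numpy(float)
    measurements = measure_diameters(mask, skeleton, [tuple(p) for p in pts])
    df = pd.DataFrame(
        [
            {
                "sample_row": m.sample_point[0],
                "sample_col": m.sample_point[1],
                "skel_row": m.skeleton_point[0],
                "skel_col": m.skeleton_point[1],
                "diameter_px": m.diameter_px,
                "diameter_um": m.diameter_um,
            }
            for m in measurements
        ],
        columns=columns,
    )
    _write_csv(df, out / f"{iset.name}_diameters.csv")


def _step_summary(config: RunConfig, iset: ImageSetConfig) -> None:
    out = _set_dir(config, iset.name)
    mask = _load_mask(config, iset, "summary")
    nuclei = _load_nuclei(config, iset, "summary")
    clusters = pd.read_csv(_require(out / f"{iset.name}_clusters.csv", "summary"))
    branch_df = pd.read_csv(_require(out / f"{iset.name}_branch_points.csv", "summary"))
    diameters = pd.read_csv(_require(out / f"{iset.name}_diameters.csv", "summary"))

    skeleton = skeletonize_mask(mask)
    from .myotube_features import BranchPointSet

    points = BranchPointSet(branch_df.to_numpy(float).reshape(-1, 2))
    cov = coverage(mask)
    features = myotube_feature_summary(mask, points, cov, nuclei)

    counts = nuclei.counts
    fi = fusion_index(nuclei).value if counts["total"] else float("nan")
    n_clusters = int(len(clusters))
    avg_rmse = float(clusters["rmse_um"].mean()) if n_clusters else float("nan")
    record = {
        "image_set": iset.name,
        "total_nuclei": counts["total"],
        "nuclei_in_myotubes": counts["in_myotubes"],
        "marker_nuclei": counts.get("marker_total", pd.NA),
        "marker_nuclei_in_myotubes": counts.get("marker_in_myotubes", pd.NA),
        "fusion_index": fi,
        "n_clusters": n_clusters,
        "average_rmse_um": avg_rmse,
        "n_myotubes": features["n_myotubes"],
        "n_branch_points": features["n_branch_points"],
        "coverage_pct": features["coverage_pct"],
        "mean_diameter_um": float(diameters["diameter_um"].mean())
        if len(diameters)
        else float("nan"),
    }
    _write_csv(pd.DataFrame([record]), out / f"{iset.name}_summary.csv")
    _write_csv(summary_frame(features), out / f"{iset.name}_per_myotube.csv")

    # combined workbook with one sheet per step
    with pd.ExcelWriter(out / f"{iset.name}_results.xlsx", engine="openpyxl") as writer:
        pd.read_csv(out / f"{iset.name}_nuclei.csv").to_excel(writer, sheet_name="nuclei", index=False)
        clusters.to_excel(writer, sheet_name="clusters", index=False)
        branch_df.to_excel(writer, sheet_name="branch_points", index=False)
        diameters.to_excel(writer, sheet_name="diameters", index=False)
        pd.DataFrame([record]).to_excel(writer, sheet_name="summary", index=False)


_STEP_FUNCS = {
    "adjust": _step_adjust,
    "mask": _step_mask,
    "nuclei": _step_nuclei,
    "clusters": _step_clusters,
    "branch_points": _step_branch_points,
    "diameters": _step_diameters,
    "summary": _step_summary,
}


def _write_run_log(config: RunConfig) -> None:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    log = {"package_version": __version__, "config": config.to_dict()}
    (config.output_dir / "run_log.json").write_text(json.dumps(log, indent=2))


def run_pipeline(config: RunConfig) -> dict[str, str | None]:
    """Run every step for every image set.

    A failing image set (e.g. missing channel file) is recorded in the
    returned error mapping and in the run log; remaining sets still run.
    Returns ``{image set name: None on success, error message on failure}``.
    """
    _write_run_log(config)
    errors: dict[str, str | None] = {}
    for iset in config.image_sets:
        try:
            for step in STEPS:
                _STEP_FUNCS[step](config, iset)
            errors[iset.name] = None
        except (MyotubeKitError, OSError) as exc:
            errors[iset.name] = f"{type(exc).__name__}: {exc}"
    log = json.loads((config.output_dir / "run_log.json").read_text())
    log["errors"] = errors
    (config.output_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return errors


def resume_step(config: RunConfig, step: str) -> None:
    """Re-run one step and everything downstream of it.

    Prerequisite artifacts must already exist in the output directory;
    a missing one raises :class:`DependencyError` naming the artifact.
    """
    if step not in STEPS:
        raise ValueError(f"unknown step {step!r}; choose from {STEPS}")
    start = STEPS.index(step)
    for iset in config.image_sets:
        for s in STEPS[start:]:
            _STEP_FUNCS[s](config, iset)
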