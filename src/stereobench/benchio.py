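"""Shared I/O, report rendering, configuration and the benchmark runner.

File conventions
----------------
* Image stacks: multi-page TIFF, planes in ascending Z; grayscale 8/16-bit or
  RGB 8-bit.  Physical spacing travels in a structured-text sidecar
  (``<stack>.meta.yaml``) rather than TIFF tags, avoiding tag-dialect
  ambiguity.
* Marker sets: CSV with header ``id,x_um,y_um,z_um,boundary[,n_voxels]``,
  comma-separated, decimal point; coordinates in um (0-based voxel index
  times spacing).
* Rates in rendered reports are rounded half away from zero to 2 decimals
  (3 on demand).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import chroma, matching, regionstats, segment, synth
from .core import GeometryError, ImageStack, MarkerSet, Spacing, quantize

MARKER_COLUMNS = ["id", "x_um", "y_um", "z_um", "boundary"]


# ---------------------------------------------------------------------------
# rounding / rendering

def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention the published tables use)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_rate(x: float, decimals: int = 2) -> str:
    return f"{round_half_away(x, decimals):.{decimals}f}"


@dataclass
class ReportRow:
    """One row of the benchmark report (the published table schema)."""

    dataset: str
    method: str
    mode: str
    n_gt: int
    n_gti: int
    n_s: int
    n_tp: int
    n_fn: int
    n_fp: int
    r_tp: float
    r_tpi: float
    r_tpb: float
    r_fp: float

    def __post_init__(self) -> None:
        if self.n_tp + self.n_fn != self.n_gt:
            raise ValueError("N_tp + N_fn must equal N_gt")
        if self.n_tp + self.n_fp != self.n_s:
            raise ValueError("N_tp + N_fp must equal N_s")

    @classmethod
    def from_result(
        cls, result: matching.MatchResult, dataset: str, method: str, mode: str
    ) -> "ReportRow":
        return cls(
            dataset=dataset,
            method=method,
            mode=mode,
            n_gt=result.n_gt,
            n_gti=result.n_gti,
            n_s=result.n_s,
            n_tp=result.n_tp,
            n_fn=result.n_fn,
            n_fp=result.n_fp,
            r_tp=result.r_tp,
            r_tpi=result.r_tpi,
            r_tpb=result.r_tpb,
            r_fp=result.r_fp,
        )


def rows_to_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def render_report(rows: Sequence[ReportRow], decimals: int = 2) -> pd.DataFrame:
    """Report table with rate columns rendered as fixed-decimal strings."""
    frame = rows_to_frame(rows)
    for col in ("r_tp", "r_tpi", "r_tpb", "r_fp"):
        frame[col] = [format_rate(v, decimals) for v in frame[col]]
    return frame


# ---------------------------------------------------------------------------
# stacks

def write_stack(path: Union[str, Path], stack: ImageStack, modality: str = "") -> None:
    """Write a stack as multi-page TIFF plus a spacing sidecar."""
    path = Path(path)
    data = stack.data
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError("only 8/16-bit integer stacks are written to TIFF")
    if data.ndim == 4 and (data.shape[-1] != 3 or data.dtype != np.uint8):
        raise ValueError("multi-channel TIFF output supports 8-bit RGB only")
    photometric = "rgb" if data.ndim == 4 else "minisblack"
    tifffile.imwrite(path, data, photometric=photometric)
    meta = {
        "spacing_um": {"x": stack.spacing[0], "y": stack.spacing[1], "z": stack.spacing[2]},
        "modality": modality,
        "axes": "ZYX" if data.ndim == 3 else "ZYXC",
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_stack(
    path: Union[str, Path], spacing: Optional[Spacing] = None
) -> ImageStack:
    """Read a multi-page TIFF; spacing from the sidecar unless given."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise GeometryError(f"inconsistent plane dimensions in {path}: {shapes}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth {data.dtype} in {path}")
    if spacing is None:
        sidecar = Path(str(path) + ".meta.yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            s = meta["spacing_um"]
            spacing = (s["x"], s["y"], s["z"])
        else:
            spacing = (1.0, 1.0, 1.0)
    return ImageStack(data, spacing)


def write_labels(path: Union[str, Path], vol: segment.LabeledVolume) -> None:
    """Write a labeled volume as 16-bit multi-page TIFF (plus sidecar)."""
    if vol.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    write_stack(path, ImageStack(vol.labels.astype(np.uint16), vol.spacing), "labels")


# ---------------------------------------------------------------------------
# markers

def write_markers(path: Union[str, Path], markers: MarkerSet) -> None:
    markers.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def read_markers(
    path: Union[str, Path], spacing: Optional[Spacing] = None
) -> MarkerSet:
    """Read a marker CSV, validating columns and values.

    Raises ValueError naming the first offending line (1-based, header is
    line 1) on non-numeric coordinates or boundary flags outside {0, 1}.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in MARKER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    numeric = {}
    for col in ["id", "x_um", "y_um", "z_um", "boundary"]:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-numeric or missing {col!r} at line {line}")
        numeric[col] = values
    bad_flag = ~numeric["boundary"].isin([0, 1])
    if bad_flag.any():
        line = int(np.flatnonzero(bad_flag.to_numpy())[0]) + 2
        raise ValueError(f"{path}: boundary flag not in {{0,1}} at line {line}")
    sizes = None
    if "n_voxels" in frame.columns:
        sizes = pd.to_numeric(frame["n_voxels"], errors="coerce").to_numpy()
    return MarkerSet(
        ids=numeric["id"].to_numpy(dtype=np.int64),
        xyz=np.column_stack(
            [numeric["x_um"].to_numpy(), numeric["y_um"].to_numpy(), numeric["z_um"].to_numpy()]
        ),
        boundary=numeric["boundary"].to_numpy(dtype=bool),
        sizes=None if sizes is None else sizes.astype(np.int64),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# configuration and runner

#: sentinel detector that returns the ground truth as the detections
ORACLE = "oracle"


@dataclass
class RunConfig:
    """Full specification of one benchmark run."""

    profile: Union[str, synth.AcquisitionProfile]
    population: synth.CellPopulationSpec = field(default_factory=synth.CellPopulationSpec)
    noise: synth.NoiseModel = field(default_factory=synth.NoiseModel)
    detector: Union[str, segment.DetectorParams] = ORACLE
    detector_b: Optional[segment.DetectorParams] = None
    tolerance: Optional[matching.ToleranceSpec] = None
    combine: str = "none"  # none | union | intersection
    seed: int = 0
    scale: Optional[Tuple[int, int, int]] = None  # (width, height, n_planes)
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.combine not in ("none", "union", "intersection"):
            raise ValueError("combine must be none, union or intersection")
        if self.combine != "none" and self.detector_b is None:
            raise ValueError("combination modes need detector_b")

    def resolved_profile(self) -> synth.AcquisitionProfile:
        prof = (
            synth.preset_profile(self.profile)
            if isinstance(self.profile, str)
            else self.profile
        )
        if self.scale is not None:
            prof = prof.scaled(*self.scale)
        return prof

    def resolved_tolerance(self) -> matching.ToleranceSpec:
        if self.tolerance is not None:
            return self.tolerance
        return matching.default_tolerance(self.resolved_profile().name)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = dict(raw)
    if "population" in kwargs:
        pop = dict(kwargs["population"])
        for key in ("radius_xy_range", "radius_z_range", "intensity_range"):
            if key in pop:
                pop[key] = tuple(pop[key])
        kwargs["population"] = synth.CellPopulationSpec(**pop)
    if "noise" in kwargs:
        kwargs["noise"] = synth.NoiseModel(**kwargs["noise"])
    for det_key in ("detector", "detector_b"):
        if isinstance(kwargs.get(det_key), dict):
            det = dict(kwargs[det_key])
            if isinstance(det.get("smoothing"), (list, tuple)):
                det["smoothing"] = chroma.SmoothingSpec(*det["smoothing"])
            kwargs[det_key] = segment.DetectorParams(**det)
    if isinstance(kwargs.get("tolerance"), (list, tuple)):
        kwargs["tolerance"] = matching.ToleranceSpec(*kwargs["tolerance"])
    if "scale" in kwargs and kwargs["scale"] is not None:
        kwargs["scale"] = tuple(kwargs["scale"])
    if "outdir" in kwargs and kwargs["outdir"] is not None:
        kwargs["outdir"] = Path(kwargs["outdir"])
    return RunConfig(**kwargs)


def preprocess_for_detection(stack: ImageStack) -> ImageStack:
    """Convert any supported stack to 8-bit bright-on-dark grayscale.

    RGB brightfield stacks go through the red chromaticity conversion (cells
    come out brighter than background) and are re-quantized to 8-bit;
    grayscale stacks pass through unchanged.
    """
    if stack.is_rgb:
        r = chroma.red_chromaticity(stack)
        return ImageStack(quantize(r.data, 8), stack.spacing)
    if stack.data.ndim != 3:
        raise GeometryError("expected grayscale or RGB stack")
    return stack


def _run_detector(
    stack: ImageStack,
    gt: MarkerSet,
    detector: Union[str, segment.DetectorParams],
) -> MarkerSet:
    if detector == ORACLE:
        det = MarkerSet(
            ids=gt.ids.copy(),
            xyz=gt.xyz.copy(),
            boundary=gt.boundary.copy(),
            sizes=None if gt.sizes is None else gt.sizes.copy(),
            spacing=gt.spacing,
        )
        return det
    work = preprocess_for_detection(stack)
    _, det = segment.detect(work, detector)
    return det


def run_benchmark(config: RunConfig) -> List[ReportRow]:
    """Generate, preprocess, detect, evaluate; optionally combine two detectors.

    Returns the report rows; when ``config.outdir`` is set also writes the
    stack, ground truth, detections, per-marker assignment files, the report
    CSV, and a manifest recording every parameter and seed.
    """
    profile = config.resolved_profile()
    tol = config.resolved_tolerance()
    stack, gt, vol = synth.generate_stack(
        profile, config.population, config.noise, config.seed
    )

    def label_for(det) -> str:
        if det == ORACLE:
            return ORACLE
        return "threshold-cc"

    det_a = _run_detector(stack, gt, config.detector)
    res_a = matching.match(gt, det_a, tol)
    mode_a = (
        "S"
        if isinstance(config.detector, segment.DetectorParams)
        and config.detector.smoothing is not None
        else "M"
    )
    rows = [ReportRow.from_result(res_a, profile.name, label_for(config.detector), mode_a)]
    results = {"a": (det_a, res_a)}

    if config.detector_b is not None:
        det_b = _run_detector(stack, gt, config.detector_b)
        res_b = matching.match(gt, det_b, tol)
        mode_b = "S" if config.detector_b.smoothing is not None else "M"
        rows.append(ReportRow.from_result(res_b, profile.name, "threshold-cc", mode_b))
        results["b"] = (det_b, res_b)
        if config.combine == "union":
            comb = matching.combine_union(res_a, res_b, gt, tol)
            rows.append(ReportRow.from_result(comb, profile.name, "combined", "U"))
        elif config.combine == "intersection":
            comb = matching.combine_intersection(res_a, res_b, gt, tol)
            rows.append(ReportRow.from_result(comb, profile.name, "combined", "I"))

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(out / "stack.tif", stack, profile.modality)
        write_labels(out / "true_labels.tif", vol)
        write_markers(out / "ground_truth.csv", gt)
        for tag, (det, res) in results.items():
            write_markers(out / f"detections_{tag}.csv", det)
            res.assignments.to_csv(out / f"assignments_{tag}.csv", index=False)
        rows_to_frame(rows).to_csv(out / "report.csv", index=False)
        render_report(rows).to_csv(out / "report_rendered.csv", index=False)
        _write_manifest(out / "manifest.yaml", config, profile, tol)
    return rows


def _write_manifest(path: Path, config: RunConfig, profile, tol) -> None:
    from . import __version__

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    payload = {
        "config": {
            "profile": plain(config.profile),
            "population": plain(config.population),
            "noise": plain(config.noise),
            "detector": plain(config.detector),
            "detector_b": plain(config.detector_b),
            "tolerance": plain(tol),
            "combine": config.combine,
            "seed": config.seed,
            "scale": plain(config.scale),
        },
        "resolved_profile": plain(profile),
        "version": __version__,
    }
    text = yaml.safe_dump(payload, sort_keys=True)
    payload["config_sha256"] = hashlib.sha256(text.encode()).hexdigest()
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
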