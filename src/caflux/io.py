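"""File formats: TIFF stacks, sidecar metadata, ROI JSON, tables, configs, run logs.

Movies travel as multi-frame grayscale 16-bit TIFF plus a JSON sidecar
carrying the acquisition calibration (frame_rate, pixel_size) and any EFS
protocol; ROIs are JSON polygon + centerline point lists (0-based (row,
col) pixel coordinates); all tables are CSV with a header row; configs are
TOML or YAML keyed exactly like GeneratorConfig/DetectionParams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import DetectionParams, EFSProtocol, GeneratorConfig
from .stmap import CellROI, Movie

logger = logging.getLogger(__name__)


def setup_run_log(path: Path | str) -> None:
    """Line-oriented run log with ISO timestamps, mirrored to stderr."""
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("caflux")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    root.addHandler(logging.StreamHandler(sys.stderr))


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

def sidecar_path(movie_path: Path | str) -> Path:
    p = Path(movie_path)
    return p.with_suffix(p.suffix + ".json")


def write_movie(path: Path | str, movie: Movie, efs: EFSProtocol | None = None) -> None:
    """ImageJ-compatible multi-frame TIFF + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        movie.intensity,
        imagej=True,
        metadata={"axes": "TYX", "fps": movie.frame_rate},
    )
    meta = {
        "frame_rate": movie.frame_rate,
        "pixel_size_um": movie.pixel_size,
        "n_frames": int(movie.n_frames),
    }
    if efs is not None:
        meta["efs"] = {"onset_s": efs.onset, "train_duration_s": efs.train_duration,
                       "pulse_freq_hz": efs.pulse_freq}
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_movie(
    path: Path | str,
    frame_rate: float | None = None,
    pixel_size: float | None = None,
) -> tuple[Movie, EFSProtocol | None]:
    """Read a TIFF stack; calibration comes from the sidecar unless given."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    efs = None
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        frame_rate = frame_rate or meta.get("frame_rate")
        pixel_size = pixel_size or meta.get("pixel_size_um")
        if "efs" in meta:
            efs = EFSProtocol(
                onset=meta["efs"]["onset_s"],
                train_duration=meta["efs"]["train_duration_s"],
                pulse_freq=meta["efs"].get("pulse_freq_hz", 10.0),
            )
    if frame_rate is None or pixel_size is None:
        raise ValueError(
            f"{path}: frame_rate and pixel_size must come from the sidecar or arguments"
        )
    return Movie(np.asarray(stack), float(frame_rate), float(pixel_size)), efs


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

def write_roi(path: Path | str, roi: CellROI) -> None:
    payload = {
        "polygon": np.asarray(roi.polygon, dtype=float).tolist(),
        "centerline": np.asarray(roi.centerline, dtype=float).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_roi(path: Path | str) -> CellROI:
    d = json.loads(Path(path).read_text())
    return CellROI(polygon=np.array(d["polygon"]), centerline=np.array(d["centerline"]))


# ---------------------------------------------------------------------------
# Ground truth / results tables
# ---------------------------------------------------------------------------

def ground_truth_frames(gt) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(events, sites) DataFrames from a GroundTruth ledger."""
    ev = pd.DataFrame(
        [
            {
                "site_id": e.site_id,
                "t_init_s": e.t_init,
                "amplitude_dff": e.amplitude,
                "fdhm_ms": e.fdhm,
                "spread_um": e.spread,
                "velocity_um_s": e.velocity,
                "direction": e.direction,
            }
            for e in gt.events
        ],
        columns=["site_id", "t_init_s", "amplitude_dff", "fdhm_ms", "spread_um",
                 "velocity_um_s", "direction"],
    )
    sites = pd.DataFrame({
        "site_id": np.arange(gt.site_positions_um.size),
        "position_um": gt.site_positions_um,
    })
    if gt.escape_latencies is not None:
        sites["escape_latency_s"] = gt.escape_latencies
    return ev, sites


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def load_generator_config(path: Path | str) -> GeneratorConfig:
    """GeneratorConfig from a TOML or YAML file (keys = field names)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        import yaml

        data = yaml.safe_load(path.read_text())
    efs = data.pop("efs", None)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = GeneratorConfig(**data)
    if efs is not None:
        cfg = cfg.replace(efs=EFSProtocol(**efs))
    if cfg.frame_shape is not None:
        cfg = cfg.replace(frame_shape=tuple(cfg.frame_shape))
    cfg.validate()
    return cfg


def load_detection_params(data: dict) -> DetectionParams:
    params = DetectionParams(**data)
    params.validate()
    return params
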