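"""File formats, configuration and provenance.

Plain text only: photon traces, degradation traces and correlation
curves are CSV files with '#'-prefixed ``key: value`` metadata lines
before the header row; analysis results are schema-versioned JSON with a
provenance block (tool version, config hash, input hashes, seed,
timestamp). The run configuration is a flat TOML file of calibration
constants and algorithm parameters; unknown keys are rejected so a typo
in a threshold cannot pass silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
import math
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .types import CorrelationCurve, DegradationTrace, PhotonCountTrace

__all__ = [
    "RunConfig",
    "ProvenanceRecord",
    "load_config",
    "read_trace_csv",
    "write_photon_csv",
    "write_degradation_csv",
    "read_curve_csv",
    "write_curve_csv",
    "write_results_json",
    "read_results_json",
]

SCHEMA_VERSION = 1
INF_SENTINEL = "inf"


# ---------------------------------------------------------------- config

_CONFIG_DEFAULTS = {
    # calibration / environment
    "w_xy_um": 0.2,
    "kappa": 5.0,
    "temperature_k": 310.0,
    "viscosity_pa_s": 1.0e-3,
    # correlator
    "points_per_octave": 8,
    "n_segments": 10,
    "max_lag_s": 0.1,
    # kinetics
    "reference_frame": -20,
    "smooth_window": 4,
    "slope_window": 5,
    "slope_threshold": -0.05,
    "bleach_mode": "linear",
    "bleach_fit_first": -30,
    "bleach_fit_last": -25,
    # simulation defaults
    "box_multiplier": 3.0,
    "sim_bin_width_s": 1e-4,
    "sim_timestep_s": 1e-4,
    "sim_duration_s": 20.0,
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (see module docstring)."""

    w_xy_um: float = 0.2
    kappa: float = 5.0
    temperature_k: float = 310.0
    viscosity_pa_s: float = 1.0e-3
    points_per_octave: int = 8
    n_segments: int = 10
    max_lag_s: float = 0.1
    reference_frame: int = -20
    smooth_window: int = 4
    slope_window: int = 5
    slope_threshold: float = -0.05
    bleach_mode: str = "linear"
    bleach_fit_first: int = -30
    bleach_fit_last: int = -25
    box_multiplier: float = 3.0
    sim_bin_width_s: float = 1e-4
    sim_timestep_s: float = 1e-4
    sim_duration_s: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.w_xy_um <= 0:
            raise ValueError("w_xy_um must be positive")
        if self.kappa <= 1:
            raise ValueError("kappa must be > 1")
        if self.temperature_k <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("temperature and viscosity must be positive")
        if self.points_per_octave < 1 or self.n_segments < 2:
            raise ValueError("invalid correlator settings")
        if self.smooth_window < 1 or self.slope_window < 2:
            raise ValueError("invalid kinetics windows")
        if self.bleach_mode not in ("control", "linear", "none"):
            raise ValueError("bleach_mode must be control, linear or none")
        if self.bleach_fit_last <= self.bleach_fit_first:
            raise ValueError("bleach fit window must be increasing")
        if self.box_multiplier < 3:
            raise ValueError("box_multiplier must be >= 3")
        if not self.sim_duration_s > self.sim_bin_width_s > 0:
            raise ValueError("require sim_duration_s > sim_bin_width_s > 0")
        if not 0 < self.sim_timestep_s <= self.sim_bin_width_s:
            raise ValueError("require 0 < sim_timestep_s <= sim_bin_width_s")

    @property
    def volume(self):
        from .types import ObservationVolume

        return ObservationVolume(w_xy=self.w_xy_um, kappa=self.kappa)

    @property
    def environment(self):
        from .types import Environment

        return Environment(temperature=self.temperature_k,
                           viscosity=self.viscosity_pa_s)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a flat TOML config; unknown keys raise."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **data}
    return RunConfig(**merged)


# ------------------------------------------------------------ provenance

@dataclass(frozen=True)
class ProvenanceRecord:
    tool_version: str = __version__
    config_hash: str = ""
    input_hashes: dict = field(default_factory=dict)
    seed: Optional[int] = None
    timestamp: str = ""

    @classmethod
    def create(cls, config_path=None, input_paths=(), seed=None):
        cfg_hash = _sha256_file(config_path) if config_path else ""
        hashes = {str(p): _sha256_file(p) for p in input_paths}
        return cls(
            tool_version=__version__,
            config_hash=cfg_hash,
            input_hashes=hashes,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------ CSV traces

def _split_metadata(text: str):
    """Split a CSV payload into ('#' metadata dict, body, body_start_line)."""
    meta = {}
    body_lines = []
    start = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            if start:
                raise ValueError(f"line {lineno}: metadata after data rows")
            kv = stripped.lstrip("#").strip()
            if ":" in kv:
                key, _, value = kv.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if not start:
            start = lineno
        body_lines.append(line)
    return meta, "\n".join(body_lines), start


def write_photon_csv(path, trace: PhotonCountTrace, seed: Optional[int] = None):
    lines = [
        "# kind: photon",
        f"# channel: {trace.channel}",
        f"# bin_width_s: {float(trace.bin_width)!r}",
        f"# duration_s: {float(trace.duration)!r}",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("count")
    lines.extend(str(int(c)) for c in trace.counts)
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def write_degradation_csv(path, trace: DegradationTrace,
                          seed: Optional[int] = None):
    lines = [
        "# kind: degradation",
        f"# frame_interval_s: {float(trace.frame_interval)!r}",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("frame,intensity,background,compartment,cell_id")
    bg = trace.background_array()
    for f, v, b in zip(trace.frames, trace.intensities, bg):
        lines.append(f"{int(f)},{float(v)!r},{float(b)!r},{trace.compartment},{trace.cell_id}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_trace_csv(path) -> Union[PhotonCountTrace, DegradationTrace]:
    """Read a photon-count or degradation trace; the '#' metadata header
    declares the kind. Parse errors name line numbers."""
    text = Path(path).read_text()
    meta, body, start = _split_metadata(text)
    kind = meta.get("kind")
    if kind is None:
        raise ValueError(f"{path}: missing '# kind:' metadata line")
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    if kind == "photon":
        for key in ("channel", "bin_width_s"):
            if key not in meta:
                raise ValueError(f"{path}: missing '# {key}:' metadata line")
        if "count" not in df.columns:
            raise ValueError(f"{path}: line {start}: expected a 'count' column")
        counts = df["count"].to_numpy()
        bad = np.nonzero((counts < 0) | (counts != np.floor(counts)))[0]
        if bad.size:
            raise ValueError(
                f"{path}: line {start + 1 + bad[0]}: counts must be "
                "non-negative integers"
            )
        return PhotonCountTrace(
            channel=meta["channel"],
            bin_width=float(meta["bin_width_s"]),
            counts=counts.astype(np.int64),
        )
    if kind == "degradation":
        if "frame_interval_s" not in meta:
            raise ValueError(f"{path}: missing '# frame_interval_s:' metadata")
        needed = {"frame", "intensity"}
        if not needed <= set(df.columns):
            raise ValueError(f"{path}: line {start}: expected columns {needed}")
        frames = df["frame"].to_numpy(dtype=np.int64)
        gaps = np.nonzero(np.diff(frames) != 1)[0]
        if gaps.size:
            raise ValueError(
                f"{path}: line {start + 2 + gaps[0]}: frame gap after "
                f"frame {frames[gaps[0]]}"
            )
        background = (df["background"].to_numpy(dtype=float)
                      if "background" in df.columns else 0.0)
        compartment = (str(df["compartment"].iloc[0])
                       if "compartment" in df.columns else "other")
        cell_id = str(df["cell_id"].iloc[0]) if "cell_id" in df.columns else ""
        return DegradationTrace(
            frames=frames,
            intensities=df["intensity"].to_numpy(dtype=float),
            background=background,
            compartment=compartment,
            frame_interval=float(meta["frame_interval_s"]),
            cell_id=cell_id,
        )
    raise ValueError(f"{path}: unknown trace kind {kind!r}")


def write_curve_csv(path, curve: CorrelationCurve, sources=()):
    lines = [f"# kind: {curve.kind}"]
    for key, value in curve.meta.items():
        lines.append(f"# {key}: {value}")
    if sources:
        lines.append(f"# sources: {';'.join(str(s) for s in sources)}")
    lines.append("lag_s,g,sd")
    sd = curve.sd if curve.sd is not None else np.full(len(curve.g), np.nan)
    for lag, g, s in zip(curve.lags, curve.g, sd):
        lines.append(f"{float(lag)!r},{float(g)!r},"
                     f"{'' if math.isnan(s) else repr(float(s))}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_curve_csv(path) -> CorrelationCurve:
    text = Path(path).read_text()
    meta, body, _ = _split_metadata(text)
    kind = meta.pop("kind", None)
    if kind is None:
        raise ValueError(f"{path}: missing '# kind:' metadata line")
    df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    sd = None
    if "sd" in df.columns and df["sd"].notna().all():
        sd = df["sd"].to_numpy(dtype=float)
    return CorrelationCurve(
        kind=kind,
        lags=df["lag_s"].to_numpy(dtype=float),
        g=df["g"].to_numpy(dtype=float),
        sd=sd,
        meta=meta,
    )


# ----------------------------------------------------------- result JSON

def _encode(obj):
    """Recursively convert results to JSON-safe structures.

    +/-inf floats become the documented sentinel strings ('inf'/'-inf');
    NaN becomes null; dataclasses and arrays become dicts and lists.
    """
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _encode(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_encode(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if math.isinf(f):
            return INF_SENTINEL if f > 0 else "-" + INF_SENTINEL
        if math.isnan(f):
            return None
        return f
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    if obj == INF_SENTINEL:
        return float("inf")
    if obj == "-" + INF_SENTINEL:
        return float("-inf")
    return obj


def write_results_json(result, provenance: Optional[ProvenanceRecord] = None,
                       path=None):
    """Write a schema-versioned result document; returns the path."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "result": _encode(result),
        "provenance": _encode(provenance) if provenance else None,
    }
    if path is None:
        raise ValueError("path required")
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")
    return Path(path)


def read_results_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version")
    doc["result"] = _decode(doc["result"])
    return doc
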