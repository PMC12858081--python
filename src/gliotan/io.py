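"""Configuration loading/validation, run manifests and artifact writers.

A scenario run is fully described by its manifest (resolved config + seed);
re-running a manifest reproduces every numeric output bit-for-bit for a
fixed package version.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import DomainGrid
from .params import ModelParameters
from .pde import FIELD_NAMES, SolverControls

FIELD_UNITS = {"N1": "cells/cm^3", "N2": "cells/cm^3", "n": "cells/cm^3",
               "A": "g/cm^3", "S": "g/cm^3", "G": "g/cm^3"}

_TOP_KEYS = {"scenario", "seed", "grid", "dt", "t_end", "params", "geometry",
             "sample_times", "options"}


@dataclass
class RunConfig:
    scenario: str = "baseline"
    seed: int = 0
    grid: DomainGrid = field(default_factory=DomainGrid)
    dt: float = 0.01
    t_end: float | None = None
    params: ModelParameters = field(default_factory=ModelParameters)
    sample_times: tuple | None = None
    options: dict = field(default_factory=dict)

    def controls(self) -> SolverControls:
        return SolverControls(dt=self.dt, sample_times=self.sample_times)

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario, "seed": self.seed,
            "grid": {"nx": self.grid.nx, "ny": self.grid.ny},
            "dt": self.dt, "t_end": self.t_end,
            "params": self.params.as_dict(),
            "sample_times": list(self.sample_times) if self.sample_times else None,
            "options": self.options,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON scenario config; omitted parameters
    fall back to the reference defaults.  Unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    grid_raw = raw.get("grid", {}) or {}
    if not isinstance(grid_raw, dict) or set(grid_raw) - {"nx", "ny"}:
        raise ValueError("config key 'grid' must be a mapping with nx/ny")
    grid = DomainGrid(int(grid_raw.get("nx", 101)), int(grid_raw.get("ny", 101)))
    valid_params = {f.name for f in dc_fields(ModelParameters)}
    praw = raw.get("params", {}) or {}
    bad = set(praw) - valid_params
    if bad:
        raise ValueError(f"unknown model parameters: {sorted(bad)}")
    try:
        params = ModelParameters(**{k: float(v) for k, v in praw.items()})
    except ValueError as exc:
        raise ValueError(f"invalid parameter value: {exc}") from exc
    st = raw.get("sample_times")
    return RunConfig(
        scenario=str(raw.get("scenario", "baseline")),
        seed=int(raw.get("seed", 0)),
        grid=grid,
        dt=float(raw.get("dt", 0.01)),
        t_end=raw.get("t_end"),
        params=params,
        sample_times=tuple(float(t) for t in st) if st else None,
        options=dict(raw.get("options", {}) or {}),
    )


def apply_overrides(config: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply ``dotted.key=value`` overrides (e.g. ``params.lambda_A=2.89``)."""
    raw = config.as_dict()
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not key=value")
        key, val = ov.split("=", 1)
        tgt = raw
        parts = key.split(".")
        for p in parts[:-1]:
            tgt = tgt.setdefault(p, {})
        tgt[parts[-1]] = yaml.safe_load(val)
    return parse_config(raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    event_log: list = field(default_factory=list)
    wall_time_s: float = 0.0
    outputs: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def write_fields_h5(trajectory, path) -> None:
    """Snapshot fields to HDF5, one group per sample time, units as attrs."""
    with h5py.File(path, "w") as h5:
        h5.attrs["nx"] = trajectory.grid.nx
        h5.attrs["ny"] = trajectory.grid.ny
        h5.create_dataset("times", data=np.asarray(trajectory.times))
        for k, (t, st) in enumerate(zip(trajectory.times, trajectory.states)):
            grp = h5.create_group(f"snapshot_{k:04d}")
            grp.attrs["t_hours"] = float(t)
            for f in FIELD_NAMES:
                ds = grp.create_dataset(f, data=getattr(st, f))
                ds.attrs["units"] = FIELD_UNITS[f]


def read_fields_h5(path):
    """Round-trip reader: returns (times, list of {field: array})."""
    with h5py.File(path, "r") as h5:
        times = np.asarray(h5["times"])
        snaps = []
        for k in range(len(times)):
            grp = h5[f"snapshot_{k:04d}"]
            snaps.append({f: np.asarray(grp[f]) for f in FIELD_NAMES})
    return times, snaps


def populations_frame(trajectory) -> pd.DataFrame:
    """Tidy per-time population integrals: columns time, metric, value."""
    rows = []
    for f in FIELD_NAMES:
        for t, v in zip(trajectory.times, trajectory.populations[f]):
            rows.append({"time": float(t), "metric": f"{f}_total", "value": float(v)})
    return pd.DataFrame(rows)


def write_outputs(result, out_dir, config: RunConfig | None = None) -> list[str]:
    """Write a scenario result: per-arm HDF5 snapshots + metrics CSV and a
    JSON manifest indexing every emitted file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    t0 = time.time()
    for arm, traj in result.arms.items():
        if hasattr(traj, "states"):        # continuum trajectory
            if traj.states:
                fp = out / f"fields_{arm}.h5"
                write_fields_h5(traj, fp)
                written.append(fp.name)
            mp = out / f"metrics_{arm}.csv"
            populations_frame(traj).to_csv(mp, index=False)
            written.append(mp.name)
        else:                              # CA trajectory
            mp = out / f"counts_{arm}.csv"
            traj.counts.to_csv(mp)
            written.append(mp.name)
    sp = out / "summary.json"
    sp.write_text(json.dumps(result.summary, indent=2, default=_jsonable))
    written.append(sp.name)
    manifest = RunManifest(
        config=config.as_dict() if config else {"scenario": result.name},
        seed=result.seed,
        wall_time_s=time.time() - t0,
        outputs=written,
        extra={"summary_file": "summary.json"},
    )
    mp = out / "manifest.json"
    manifest.write(mp)
    written.append(mp.name)
    return written
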