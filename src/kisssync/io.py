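"""Readers, writers, configuration, and the end-to-end pipeline runner.

File formats
------------
* photometry: CSV with columns ``time_s, f465, f405, mask``
* slice ROI traces: wide CSV with ``time_s, cell_001..cell_N, background``
* membrane voltage: CSV with ``time_s, vmem_mV``
* spike trains: CSV with a single ``spike_time_s`` column
* HDF5 containers mirror the CSVs, one group per recording, with the
  simulation/analysis config serialized to JSON in a group attribute
* ground truth and run manifests: JSON sidecars

All CSVs are comma-separated UTF-8 with '.' decimals and a mandatory header
naming units.  Time is stored as float seconds from recording start;
injection and drug times share that frame.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .photometry import DualChannelTrace, detect_synchronization_events, se_timeline
from .slice_network import ROITraceSet
from .patch import VmTrace, SpikeTrain

__all__ = [
    "SchemaError",
    "read_trace",
    "write_trace",
    "write_ground_truth",
    "read_ground_truth",
    "AnalysisConfig",
    "RunManifest",
    "run_pipeline",
]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


_KINDS = ("photometry", "slice", "vmem", "spikes")


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_monotone(t: np.ndarray, path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise SchemaError(f"{path}: time not strictly increasing at rows "
                          f"{(bad + 2).tolist()[:5]}")  # +2: header + 1-based


def _check_nan(df: pd.DataFrame, path, max_run_s: float = 1.0) -> None:
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    for col in df.columns:
        isnan = df[col].isna().to_numpy()
        if not isnan.any():
            continue
        run, worst_start = 0, None
        longest = 0
        for i, v in enumerate(isnan):
            run = run + 1 if v else 0
            if run > longest:
                longest, worst_start = run, i - run + 2
        if longest * dt > max_run_s:
            raise SchemaError(f"{path}: NaN run longer than {max_run_s} s in "
                              f"column {col!r} starting near row {worst_start}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_trace(path, kind: str):
    """Read a typed recording from CSV or HDF5.

    ``kind`` is one of photometry | slice | vmem | spikes.  Invariants are
    validated on load; schema violations raise :class:`SchemaError` with the
    offending row numbers.
    """
    path = Path(path)
    if kind not in _KINDS:
        raise ValueError(f"unknown trace kind {kind!r}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as h5:
            grp = h5["recording"]
            df = pd.DataFrame({name: np.asarray(grp[name]) for name in grp})
    else:
        df = pd.read_csv(path)
    return _parse_frame(df, kind, path)


def _parse_frame(df: pd.DataFrame, kind: str, path):
    if kind == "photometry":
        _check_columns(df, ["time_s", "f465", "f405"], path)
        _check_nan(df, path)
        t = df["time_s"].to_numpy(float)
        _check_monotone(t, path)
        mask = (df["mask"].to_numpy(bool) if "mask" in df.columns
                else np.ones(t.size, dtype=bool))
        return DualChannelTrace(time=t, f465=df["f465"].to_numpy(float),
                                f405=df["f405"].to_numpy(float), mask=mask)
    if kind == "slice":
        _check_columns(df, ["time_s", "background"], path)
        _check_nan(df, path)
        t = df["time_s"].to_numpy(float)
        _check_monotone(t, path)
        cell_cols = [c for c in df.columns if c.startswith("cell_")]
        if len(cell_cols) < 2:
            raise SchemaError(f"{path}: need >= 2 cell_* columns")
        cells = {c: df[c].to_numpy(float) for c in cell_cols}
        return ROITraceSet(time=t, cells=cells,
                           background=df["background"].to_numpy(float))
    if kind == "vmem":
        _check_columns(df, ["time_s", "vmem_mV"], path)
        _check_nan(df, path)
        t = df["time_s"].to_numpy(float)
        _check_monotone(t, path)
        return VmTrace(time=t, vmem=df["vmem_mV"].to_numpy(float), drug_windows=[])
    _check_columns(df, ["spike_time_s"], path)
    st = df["spike_time_s"].to_numpy(float)
    _check_monotone(st, path)
    return SpikeTrain(spike_times=st, application_windows=[],
                      duration=float(st[-1]) if st.size else 0.0)


def write_trace(obj, path, config: Optional[object] = None) -> None:
    """Write a recording to CSV or HDF5 (chosen by extension)."""
    path = Path(path)
    df = _to_frame(obj)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as h5:
            grp = h5.create_group("recording")
            for col in df.columns:
                grp.create_dataset(col, data=df[col].to_numpy())
            if config is not None:
                grp.attrs["config_json"] = json.dumps(_config_dict(config))
    else:
        df.to_csv(path, index=False)


def _to_frame(obj) -> pd.DataFrame:
    if isinstance(obj, DualChannelTrace):
        return pd.DataFrame({"time_s": obj.time, "f465": obj.f465,
                             "f405": obj.f405, "mask": obj.mask.astype(int)})
    if isinstance(obj, ROITraceSet):
        data = {"time_s": obj.time}
        data.update(obj.cells)
        data["background"] = obj.background
        return pd.DataFrame(data)
    if isinstance(obj, VmTrace):
        return pd.DataFrame({"time_s": obj.time, "vmem_mV": obj.vmem})
    if isinstance(obj, SpikeTrain):
        return pd.DataFrame({"spike_time_s": obj.spike_times})
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------

_CONFIG_BOUNDS = {
    "window": (60.0, 86400.0),
    "min_prominence": (0.0, 100.0),
    "bin": (600.0, 86400.0),
    "n_bins": (1, 12),
    "baseline_bin": (600.0, 86400.0),
    "family_size": (1, 1000),
    "seed": (0, 2**31 - 1),
}
_CONFIG_KEYS = set(_CONFIG_BOUNDS) | {
    "input", "kind", "injection_time", "fit_isosbestic", "out_dir", "stages",
    "simulate", "epoch_drug_start",
}


class AnalysisConfig:
    """Validated analysis configuration with a provenance hash.

    Unknown keys are rejected; numeric parameters are bounds-checked.
    """

    def __init__(self, params: dict):
        unknown = set(params) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, (lo, hi) in _CONFIG_BOUNDS.items():
            if key in params and not (lo <= params[key] <= hi):
                raise ValueError(f"config {key}={params[key]} outside [{lo}, {hi}]")
        self.params = dict(params)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def get(self, key, default=None):
        return self.params.get(key, default)


def _config_dict(config) -> dict:
    if dataclasses.is_dataclass(config):
        d = dataclasses.asdict(config)
        return {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in d.items()}
    if isinstance(config, AnalysisConfig):
        return config.params
    return dict(config)


@dataclasses.dataclass
class RunManifest:
    inputs: dict        # path -> sha256
    config_hash: str
    seed: Optional[int]
    outputs: list
    timestamp: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig, out_dir) -> RunManifest:
    """Execute the configured stages on one photometry recording.

    Reads the input trace (or simulates one when ``simulate`` parameters are
    given), detects SEs, summarizes the post-injection timeline when an
    injection time is configured, and writes the SE table, timeline summary,
    and a manifest to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {}
    if config.get("simulate") is not None:
        from .synthetic import PhotometrySimConfig, simulate_photometry
        sim_params = dict(config.get("simulate"))
        sim_params.setdefault("seed", config.get("seed", 0))
        trace, truth = simulate_photometry(PhotometrySimConfig(**sim_params))
        sim_path = out / "simulated_photometry.csv"
        write_trace(trace, sim_path)
        write_ground_truth(truth, out / "ground_truth.json")
        inputs[str(sim_path)] = _sha256(sim_path)
    else:
        in_path = config.get("input")
        if in_path is None:
            raise ValueError("config needs either 'input' or 'simulate'")
        trace = read_trace(in_path, config.get("kind", "photometry"))
        inputs[str(in_path)] = _sha256(in_path)

    processed, ses = detect_synchronization_events(
        trace,
        fit_isosbestic=bool(config.get("fit_isosbestic", False)),
        window=float(config.get("window", 900.0)),
        min_prominence=float(config.get("min_prominence", 1.0)),
    )
    se_df = pd.DataFrame({
        "peak_time_s": [e.peak_time for e in ses],
        "onset_time_s": [e.onset_time for e in ses],
        "amplitude_z": [e.amplitude for e in ses],
        "fwhm_s": [e.fwhm for e in ses],
    })
    se_path = out / "synchronization_events.csv"
    se_df.to_csv(se_path, index=False)
    outputs = [str(se_path)]

    injection = config.get("injection_time")
    if injection is None and config.get("simulate") is not None:
        injection = config.get("simulate").get("injection_time")
    if injection is not None:
        tl = se_timeline(ses, float(injection),
                         bin=float(config.get("bin", 14400.0)),
                         n_bins=int(config.get("n_bins", 2)),
                         baseline_bin=float(config.get("baseline_bin", 14400.0)))
        tl_df = pd.DataFrame({
            "metric": (["baseline_count"]
                       + [f"bin{k + 1}_count" for k in range(len(tl.bin_counts))]
                       + ["latency_to_first_s"]
                       + [f"interval_{k + 1}_s" for k in range(len(tl.inter_se_intervals))]),
            "value": ([tl.baseline_count] + tl.bin_counts
                      + [tl.latency_to_first if tl.latency_to_first is not None else np.nan]
                      + tl.inter_se_intervals),
        })
        tl_path = out / "se_timeline.csv"
        tl_df.to_csv(tl_path, index=False)
        outputs.append(str(tl_path))

    manifest = RunManifest(
        inputs=inputs, config_hash=config.hash,
        seed=config.get("seed"), outputs=outputs,
        timestamp=_time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest
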