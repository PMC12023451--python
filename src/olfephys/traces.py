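"""Trace containers and file I/O for patch-clamp sweeps and behavioral session logs.

Conventions
-----------
* Time is 0-based from sweep start and carried in **seconds** internally;
  kinetic quantities are reported in ms at API boundaries.
* Current-clamp voltages are mV, voltage-clamp currents are pA.
* Inward currents are negative; event amplitudes downstream are reported as
  positive magnitudes.
* Liquid-junction-potential (LJP) correction is applied offline, exactly once;
  the applied offset is recorded on the trace so double application is an error.

Native on-disk formats are HDF5 (one group per sweep, metadata as attributes)
and per-sweep CSV with a JSON metadata sidecar.  ABF/NWB adapters are optional
and require third-party readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "StepStimulus",
    "SweepSet",
    "TraceFormatError",
    "apply_ljp",
    "save_traces",
    "load_traces",
    "save_session_log",
    "load_session_log",
]

CC_VOLTAGE = "cc_voltage"
VC_CURRENT = "vc_current"
_SIGNAL_UNITS = {CC_VOLTAGE: "mV", VC_CURRENT: "pA"}


class TraceFormatError(ValueError):
    """Raised when a trace file lacks required metadata or is inconsistent."""


@dataclass(frozen=True)
class StepStimulus:
    """Rectangular step command riding on a holding level.

    Amplitude is in pA for current clamp and mV for voltage clamp; ``onset``
    and ``duration`` are seconds from sweep start.
    """

    amplitude: float
    onset: float
    duration: float
    holding: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("step onset must be >= 0 and duration > 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def waveform(self, n: int, dt: float) -> np.ndarray:
        t = np.arange(n) * dt
        w = np.full(n, float(self.holding))
        w[(t >= self.onset) & (t < self.offset)] += self.amplitude
        return w


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled patch-clamp sweep with stimulus and cell metadata."""

    samples: np.ndarray
    dt: float
    signal_kind: str
    stimulus: StepStimulus | np.ndarray | None = None
    units: str = ""
    ljp_applied: float = 0.0
    cell_id: str = ""
    group_label: str = ""
    temperature: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.signal_kind not in _SIGNAL_UNITS:
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        units = self.units or _SIGNAL_UNITS[self.signal_kind]
        if units != _SIGNAL_UNITS[self.signal_kind]:
            raise TraceFormatError(
                f"units {units!r} do not match signal kind {self.signal_kind!r} "
                f"(expected {_SIGNAL_UNITS[self.signal_kind]!r})"
            )
        object.__setattr__(self, "units", units)
        if isinstance(self.stimulus, np.ndarray) and len(self.stimulus) != len(samples):
            raise TraceFormatError("stimulus array and samples must have equal length")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt


def apply_ljp(trace: Trace, ljp_mv: float) -> Trace:
    """Correct a trace for the liquid junction potential (offline, once).

    Voltages shift by ``-ljp_mv``; for voltage-clamp sweeps the recorded
    command/holding levels shift instead, so that reported holding potentials
    are the corrected ones (e.g. -70 mV at the pipette with LJP 15 mV becomes
    -85 mV).  Re-application raises.
    """
    if ljp_mv == 0:
        return trace
    if trace.ljp_applied != 0:
        raise ValueError(
            f"LJP correction of {trace.ljp_applied} mV already applied; refusing a second one"
        )
    if trace.signal_kind == CC_VOLTAGE:
        new = replace(trace, samples=trace.samples - ljp_mv, ljp_applied=ljp_mv)
    else:
        stim = trace.stimulus
        if isinstance(stim, StepStimulus):
            stim = replace(stim, holding=stim.holding - ljp_mv)
        elif isinstance(stim, np.ndarray):
            stim = stim - ljp_mv
        else:
            raise ValueError(
                "voltage-clamp trace needs a holding/command stimulus to record LJP correction"
            )
        new = replace(trace, stimulus=stim, ljp_applied=ljp_mv)
    return new


class SweepSet:
    """An ordered collection of sweeps sharing dt, signal kind and a protocol."""

    def __init__(self, traces: Sequence[Trace], protocol: str = ""):
        traces = list(traces)
        if not traces:
            raise ValueError("SweepSet needs at least one trace")
        dt0, kind0 = traces[0].dt, traces[0].signal_kind
        for tr in traces[1:]:
            if tr.signal_kind != kind0:
                raise TraceFormatError("mixed signal kinds in one SweepSet")
            if not np.isclose(tr.dt, dt0, rtol=1e-9, atol=0):
                raise TraceFormatError("mixed sampling intervals in one SweepSet")
        self.traces = traces
        self.protocol = protocol

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, i) -> Trace:
        return self.traces[i]

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    @property
    def signal_kind(self) -> str:
        return self.traces[0].signal_kind

    def step_amplitudes(self) -> np.ndarray:
        amps = []
        for tr in self.traces:
            if not isinstance(tr.stimulus, StepStimulus):
                raise ValueError("sweep lacks a step stimulus descriptor")
            amps.append(tr.stimulus.amplitude)
        return np.asarray(amps, dtype=float)

    def map_ljp(self, ljp_mv: float) -> "SweepSet":
        return SweepSet([apply_ljp(tr, ljp_mv) for tr in self.traces], self.protocol)


# ---------------------------------------------------------------------------
# HDF5 native format
# ---------------------------------------------------------------------------

def _stim_to_attrs(stim) -> dict:
    if stim is None:
        return {"stim_kind": "none"}
    if isinstance(stim, StepStimulus):
        return {
            "stim_kind": "step",
            "stim_amplitude": stim.amplitude,
            "stim_onset": stim.onset,
            "stim_duration": stim.duration,
            "stim_holding": stim.holding,
        }
    return {"stim_kind": "array"}


def _stim_from_attrs(attrs, group) -> StepStimulus | np.ndarray | None:
    kind = attrs.get("stim_kind", "none")
    if kind == "none":
        return None
    if kind == "step":
        return StepStimulus(
            amplitude=float(attrs["stim_amplitude"]),
            onset=float(attrs["stim_onset"]),
            duration=float(attrs["stim_duration"]),
            holding=float(attrs.get("stim_holding", 0.0)),
        )
    return np.asarray(group["stimulus"][()], dtype=np.float64)


def save_traces(sweeps: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet to the native HDF5 layout (one group per sweep)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "olfephys-sweepset-v1"
        f.attrs["protocol"] = sweeps.protocol
        f.attrs["n_sweeps"] = len(sweeps)
        for i, tr in enumerate(sweeps):
            g = f.create_group(f"sweep{i:03d}")
            g.create_dataset("samples", data=tr.samples)
            g.attrs["dt"] = tr.dt
            g.attrs["units"] = tr.units
            g.attrs["signal_kind"] = tr.signal_kind
            g.attrs["ljp_applied"] = tr.ljp_applied
            g.attrs["cell_id"] = tr.cell_id
            g.attrs["group_label"] = tr.group_label
            if tr.temperature is not None:
                g.attrs["temperature"] = tr.temperature
            for k, v in _stim_to_attrs(tr.stimulus).items():
                g.attrs[k] = v
            if isinstance(tr.stimulus, np.ndarray):
                g.create_dataset("stimulus", data=tr.stimulus)
    return path


def _load_hdf5(path: Path) -> SweepSet:
    import h5py

    traces = []
    with h5py.File(path, "r") as f:
        protocol = str(f.attrs.get("protocol", ""))
        for name in sorted(k for k in f.keys() if k.startswith("sweep")):
            g = f[name]
            if "dt" not in g.attrs:
                raise TraceFormatError(f"{path}:{name} lacks a dt attribute")
            if "units" not in g.attrs:
                raise TraceFormatError(f"{path}:{name} lacks a units attribute")
            traces.append(
                Trace(
                    samples=np.asarray(g["samples"][()], dtype=np.float64),
                    dt=float(g.attrs["dt"]),
                    signal_kind=str(g.attrs["signal_kind"]),
                    units=str(g.attrs["units"]),
                    stimulus=_stim_from_attrs(g.attrs, g),
                    ljp_applied=float(g.attrs.get("ljp_applied", 0.0)),
                    cell_id=str(g.attrs.get("cell_id", "")),
                    group_label=str(g.attrs.get("group_label", "")),
                    temperature=float(g.attrs["temperature"]) if "temperature" in g.attrs else None,
                )
            )
    return SweepSet(traces, protocol=protocol)


# ---------------------------------------------------------------------------
# CSV (one sweep per file) + JSON sidecar
# ---------------------------------------------------------------------------

def save_trace_csv(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, trace.samples, fmt="%.17g", header="samples", comments="")
    meta = {
        "dt": trace.dt,
        "units": trace.units,
        "signal_kind": trace.signal_kind,
        "ljp_applied": trace.ljp_applied,
        "cell_id": trace.cell_id,
        "group_label": trace.group_label,
        "temperature": trace.temperature,
        **_stim_to_attrs(trace.stimulus),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise TraceFormatError(f"missing JSON metadata sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    for key in ("dt", "units", "signal_kind"):
        if key not in meta or meta[key] in (None, ""):
            raise TraceFormatError(f"{sidecar} lacks required key {key!r}")
    samples = np.loadtxt(path, skiprows=1, dtype=np.float64)
    stim = None
    if meta.get("stim_kind") == "step":
        stim = StepStimulus(
            amplitude=meta["stim_amplitude"],
            onset=meta["stim_onset"],
            duration=meta["stim_duration"],
            holding=meta.get("stim_holding", 0.0),
        )
    return Trace(
        samples=np.atleast_1d(samples),
        dt=float(meta["dt"]),
        signal_kind=meta["signal_kind"],
        units=meta["units"],
        stimulus=stim,
        ljp_applied=float(meta.get("ljp_applied", 0.0)),
        cell_id=meta.get("cell_id", ""),
        group_label=meta.get("group_label", ""),
        temperature=meta.get("temperature"),
    )


def load_traces(path: str | Path, format: str = "hdf5") -> SweepSet:
    """Load a SweepSet; ``format`` is one of hdf5, csv (directory of sweeps), abf, nwb."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
        if not files:
            raise TraceFormatError(f"no CSV sweeps found under {path}")
        return SweepSet([load_trace_csv(f) for f in files])
    if format in ("abf", "nwb"):
        dep = {"abf": "pyabf", "nwb": "pynwb"}[format]
        raise TraceFormatError(
            f"{format.upper()} reading requires the optional dependency {dep!r}, "
            "which is not installed; convert to the native HDF5/CSV layout instead"
        )
    raise TraceFormatError(f"unknown trace format {format!r}")


# ---------------------------------------------------------------------------
# Behavioral session logs
# ---------------------------------------------------------------------------

SESSION_COLUMNS = ["trial_index", "block", "cs_label", "interval_licks", "valid_flag"]


def save_session_log(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a go/no-go session log (one row per trial) to CSV.

    ``interval_licks`` holds semicolon-joined 0/1 flags, one per 0.5 s lick
    interval.
    """
    missing = [c for c in SESSION_COLUMNS if c not in trials.columns]
    if missing:
        raise TraceFormatError(f"session log missing columns: {missing}")
    path = Path(path)
    trials.loc[:, SESSION_COLUMNS].to_csv(path, index=False)
    return path


def load_session_log(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"cs_label": str, "interval_licks": str})
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"session log {path} missing columns: {missing}")
    return df
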