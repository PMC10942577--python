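"""Core data model and I/O for intracellular electrophysiology traces.

Conventions used throughout the package:

* sample indexing is 0-based; the time of sample ``i`` is ``t0 + i*dt``
* all times are in ms, voltages in mV, currents in pA, charge in pC
  (1 pA·s = 1 pC), resistances in MΩ, capacitances in pF, conductances in nS
* inward currents are negative (EPSCs at a hyperpolarized hold are downward),
  outward currents positive
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

SignalKind = Literal["voltage", "current"]
Genotype = Literal["WT", "KO", "NA"]


class FormatError(ValueError):
    """A table or config does not have the required columns/fields."""


class SamplingError(ValueError):
    """The time base of a trace table is not uniform."""


class DataError(ValueError):
    """Samples are missing or non-finite."""


class ProtocolError(ValueError):
    """A protocol does not match the analysis being requested."""


class ConfigError(ValueError):
    """A pipeline configuration is invalid."""


class AnalysisError(RuntimeError):
    """An analysis stage could not produce a result."""


@dataclass
class Trace:
    """A uniformly sampled voltage (mV) or current (pA) signal.

    Parameters
    ----------
    values : array of float
        Samples, mV for ``signal_kind='voltage'`` and pA for ``'current'``.
    dt : float
        Sampling interval in ms, strictly positive.
    t0 : float
        Time of the first sample in ms.
    signal_kind : {'voltage', 'current'}
    condition : str
        Free-form pharmacological/protocol label (e.g. ``'basal'``,
        ``'XE991'``, ``'gabazine'``).
    cell_id : str
    genotype : {'WT', 'KO', 'NA'}
    meta : dict
        Extra metadata (set potential, protocol parameters, QC flags...).
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    signal_kind: SignalKind = "voltage"
    condition: str = "basal"
    cell_id: str = ""
    genotype: Genotype = "NA"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise DataError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace contains non-finite samples")
        if not (self.dt > 0):
            raise SamplingError(f"dt must be > 0, got {self.dt}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_ms(self) -> float:
        """Span from first to last sample, ms."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (``t0 + i*dt``)."""
        return self.t0 + self.dt * np.arange(self.n)

    def time_to_index(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to range)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice_time(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Samples with t in [start_ms, stop_ms)."""
        i0 = max(0, int(np.ceil((start_ms - self.t0) / self.dt - 1e-9)))
        i1 = min(self.n, int(np.ceil((stop_ms - self.t0) / self.dt - 1e-9)))
        return self.values[i0:i1]

    def replace(self, **kwargs) -> "Trace":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ProtocolSpec:
    """Declarative description of the injected current or stimulus train.

    Exactly the fields of the declared ``kind`` are meaningful:

    * ``step``: step_amplitude (pA), step_onset, step_duration (ms)
    * ``ramp``: ramp_rate (pA/ms or mV/ms), ramp_onset (ms),
      ramp_pre_offset (pA; hyperpolarizing onset level), ramp_start/ramp_stop
      for voltage ramps (mV)
    * ``multistep``: steps (list of pA), step_onset, step_duration
    * ``stim_train``: stim_times (ms, strictly increasing)
    """

    kind: Literal["step", "ramp", "multistep", "stim_train"]
    step_amplitude: float | None = None
    step_onset: float | None = None
    step_duration: float | None = None
    ramp_rate: float | None = None
    ramp_onset: float | None = None
    ramp_pre_offset: float = 0.0
    ramp_start: float | None = None
    ramp_stop: float | None = None
    steps: list[float] | None = None
    stim_times: list[float] | None = None
    holding_potential: float | None = None

    def __post_init__(self) -> None:
        required = {
            "step": ("step_amplitude", "step_onset", "step_duration"),
            "ramp": ("ramp_rate", "ramp_onset"),
            "multistep": ("steps", "step_onset", "step_duration"),
            "stim_train": ("stim_times",),
        }
        if self.kind not in required:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")
        for name in required[self.kind]:
            if getattr(self, name) is None:
                raise ProtocolError(f"{self.kind} protocol requires {name}")
        if self.stim_times is not None:
            st = np.asarray(self.stim_times, float)
            if st.size > 1 and not np.all(np.diff(st) > 0):
                raise ProtocolError("stim_times must be strictly increasing")

    def injected_current(self, t_ms: np.ndarray) -> np.ndarray:
        """Injected current (pA) at times ``t_ms`` for step/ramp/multistep.

        For a ramp the current is ``ramp_pre_offset`` before ``ramp_onset``
        and rises at ``ramp_rate`` from that level afterwards.
        """
        t = np.asarray(t_ms, dtype=float)
        if self.kind == "step":
            on = (t >= self.step_onset) & (t < self.step_onset + self.step_duration)
            return np.where(on, self.step_amplitude, 0.0)
        if self.kind == "ramp":
            i = np.full_like(t, self.ramp_pre_offset, dtype=float)
            after = t >= self.ramp_onset
            i[after] = self.ramp_pre_offset + self.ramp_rate * (t[after] - self.ramp_onset)
            return i
        raise ProtocolError(f"injected_current undefined for kind {self.kind!r}")


@dataclass
class CellRecord:
    """One recorded cell: identity, passive metadata, and its traces."""

    cell_id: str
    genotype: Genotype = "NA"
    cell_type: Literal["MC", "GC", "IN", "unknown"] = "unknown"
    capacitance: float | None = None  # pF, from amplifier compensation
    rmp: float | None = None  # mV
    traces: list[tuple[Trace, ProtocolSpec | None]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacitance is not None and not (self.capacitance > 0):
            raise DataError("capacitance must be > 0 when present")
        for tr, _ in self.traces:
            if tr.cell_id and tr.cell_id != self.cell_id:
                raise DataError(
                    f"trace cell_id {tr.cell_id!r} does not match record {self.cell_id!r}"
                )

    def add(self, trace: Trace, protocol: ProtocolSpec | None = None) -> None:
        if trace.cell_id and trace.cell_id != self.cell_id:
            raise DataError("trace cell_id mismatch")
        self.traces.append((trace, protocol))


# ---------------------------------------------------------------------------
# File I/O: CSV trace tables with JSON metadata sidecars
# ---------------------------------------------------------------------------

_REL_JITTER = 1e-6


def read_trace_table(path: str | Path, schema: dict | None = None) -> Trace:
    """Read a Trace from a CSV/TSV table.

    The table must contain a value column (``value`` by default) and either a
    time column in ms (``time_ms`` by default) or a declared ``dt`` in the
    schema / JSON sidecar. ``schema`` keys: ``time_col``, ``value_col``,
    ``dt``, ``signal_kind``, ``condition``, ``cell_id``, ``genotype``.
    A sidecar ``<path>.json`` written by :func:`write_trace` is merged in
    (explicit schema entries win).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(str(path) + ".json")
    merged: dict = {}
    if sidecar.exists():
        merged.update(json.loads(sidecar.read_text()))
    if schema:
        merged.update(schema)

    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    value_col = merged.get("value_col", "value")
    if value_col not in df.columns:
        raise FormatError(f"missing value column {value_col!r} in {path}")
    values = df[value_col].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError(f"NaN samples in {path}")

    time_col = merged.get("time_col", "time_ms")
    t0 = float(merged.get("t0", 0.0))
    if time_col in df.columns:
        t = df[time_col].to_numpy(dtype=float)
        if t.size < 2:
            dt = float(merged.get("dt", 1.0))
        else:
            diffs = np.diff(t)
            dt = float(np.median(diffs))
            if dt <= 0 or np.any(np.abs(diffs - dt) > _REL_JITTER * max(abs(dt), 1.0)):
                raise SamplingError(f"non-uniform time base in {path}")
            # a declared dt wins over the (rounding-afflicted) column median
            # when both agree within the jitter tolerance
            if "dt" in merged and abs(float(merged["dt"]) - dt) <= _REL_JITTER:
                dt = float(merged["dt"])
        t0 = float(t[0])
    elif "dt" in merged:
        dt = float(merged["dt"])
    else:
        raise FormatError(f"no time column {time_col!r} and no dt declared for {path}")

    return Trace(
        values=values,
        dt=dt,
        t0=t0,
        signal_kind=merged.get("signal_kind", "voltage"),
        condition=merged.get("condition", "basal"),
        cell_id=merged.get("cell_id", ""),
        genotype=merged.get("genotype", "NA"),
        meta=merged.get("meta", {}),
    )


def write_trace(trace: Trace, path: str | Path, include_time: bool = True) -> Path:
    """Write a Trace as CSV plus a JSON metadata sidecar. Round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {}
    if include_time:
        cols["time_ms"] = trace.times
    cols["value"] = trace.values
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "dt": trace.dt,
        "t0": trace.t0,
        "signal_kind": trace.signal_kind,
        "condition": trace.condition,
        "cell_id": trace.cell_id,
        "genotype": trace.genotype,
        "meta": _jsonable(trace.meta),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclasses for JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results(results, path: str | Path) -> list[Path]:
    """Write a stage output: JSON for scalar summaries, CSV for tables.

    ``results`` may be a dict (scalars and/or arrays), a DataFrame, or a
    dataclass. A dict whose values are all scalars (or short strings) becomes
    JSON; array-valued entries are written to a companion ``<stem>.csv``.
    Scalars are stored with full double precision (``repr`` round-trip).
    Returns the list of files written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(results, pd.DataFrame):
        csv_path = path.with_suffix(".csv")
        results.to_csv(csv_path, index=False, float_format="%.17g")
        written.append(csv_path)
        return written

    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        results = dataclasses.asdict(results)
    if not isinstance(results, dict):
        raise TypeError(f"cannot serialize results of type {type(results)}")

    scalars: dict = {"schema_version": SCHEMA_VERSION}
    arrays: dict = {}
    for k, v in results.items():
        v2 = _jsonable(v)
        if isinstance(v2, list) and v2 and all(isinstance(x, (int, float, type(None))) for x in v2):
            arrays[k] = v2
        else:
            scalars[k] = v2
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(scalars, indent=1, default=str))
    written.append(json_path)
    if arrays:
        # ragged arrays are padded with NaN so one CSV holds all columns
        n = max(len(v) for v in arrays.values())
        padded = {k: v + [np.nan] * (n - len(v)) for k, v in arrays.items()}
        csv_path = path.with_suffix(".csv")
        pd.DataFrame(padded).to_csv(csv_path, index=False, float_format="%.17g")
        written.append(csv_path)
    return written


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).with_suffix(".json").read_text())
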