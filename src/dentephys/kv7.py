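"""Condition-subtraction analysis of the Kv7/M current.

The Kv7-sensitive current is isolated by subtracting the trace recorded
under XE991 from the basal trace (sample-wise, so leak cancels implicitly).
Quasi-steady-state I-V curves are read off a slow voltage ramp every 5 mV
(mean current over a 0.01 mV command window) and normalized to cell
capacitance.  Holding-current, membrane-potential and input-resistance
shifts between conditions are simple deltas of stationary segment means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AnalysisError, Trace

IV_STEP_MV = 5.0
IV_WINDOW_MV = 0.01
STATIONARY_MIN_MS = 10_000.0
DRIFT_FLAG_FRAC_PER_MIN = 0.10


@dataclass
class IVCurve:
    voltages: np.ndarray  # mV, strictly increasing
    density: np.ndarray  # pA/pF
    capacitance_pF: float
    n_trials: int = 1
    dropped: list = field(default_factory=list)  # targets outside ramp range


@dataclass
class ConditionDelta:
    quantity: str  # holding_current_pA | membrane_potential_mV | input_resistance_MOhm
    basal: float
    treated: float
    delta: float
    percent: float  # NaN when basal == 0
    flags: list = field(default_factory=list)


def subtract_conditions(basal: Trace, treated: Trace) -> Trace:
    """Sample-wise ``basal - treated`` (the drug-sensitive current, positive
    outward for a blocked outward conductance). Inputs may be trial
    averages; they must share dt and length."""
    if basal.n != treated.n or abs(basal.dt - treated.dt) > 1e-12:
        raise AnalysisError("condition traces must share dt and length")
    return basal.replace(values=basal.values - treated.values,
                         condition=f"{basal.condition}-{treated.condition}")


def build_iv_curve(
    current: Trace,
    voltage_command: Trace,
    capacitance: float,
    step_mv: float = IV_STEP_MV,
    window_mv: float = IV_WINDOW_MV,
    v_start: float | None = None,
    v_stop: float | None = None,
    n_trials: int = 1,
) -> IVCurve:
    """Quasi-steady-state I-V curve from a ramp-evoked current.

    At each target voltage (every ``step_mv`` from the ramp start, rounded
    to the step grid), the current is averaged over command samples within
    ``window_mv/2`` of the target and divided by the capacitance."""
    if capacitance <= 0:
        raise AnalysisError("capacitance must be > 0")
    v = voltage_command.values
    i = current.values
    if v.size != i.size:
        raise AnalysisError("command and current must be the same length")
    dv = np.diff(v)
    ramp = dv != 0
    if ramp.any() and not (np.all(dv[ramp] > 0) or np.all(dv[ramp] < 0)):
        raise AnalysisError("voltage command must be monotone over the ramp")
    lo, hi = float(v.min()), float(v.max())
    if v_start is None:
        v_start = step_mv * math.ceil(lo / step_mv)
    if v_stop is None:
        v_stop = step_mv * math.floor(hi / step_mv)
    targets = np.arange(v_start, v_stop + 0.5 * step_mv, step_mv)
    volts, dens, dropped = [], [], []
    for vt in targets:
        sel = np.abs(v - vt) <= window_mv / 2.0
        if not sel.any():
            dropped.append(float(vt))
            continue
        volts.append(float(vt))
        dens.append(float(np.mean(i[sel])) / capacitance)
    return IVCurve(np.asarray(volts), np.asarray(dens), capacitance,
                   n_trials=n_trials, dropped=dropped)


def _stationary_mean(trace: Trace, quantity: str) -> tuple[float, list]:
    flags: list = []
    if trace.duration_ms < STATIONARY_MIN_MS:
        flags.append(f"{quantity}_segment_shorter_than_10s")
    v = trace.values
    mean = float(np.mean(v))
    # linear drift check: fitted slope over the segment vs the mean
    t_min = trace.times / 60_000.0  # minutes
    slope = float(np.polyfit(t_min, v, 1)[0])
    if mean != 0 and abs(slope / mean) > DRIFT_FLAG_FRAC_PER_MIN:
        flags.append("drift")
    return mean, flags


def holding_shift(basal: Trace, treated: Trace) -> ConditionDelta:
    """Change in holding current between conditions (treated - basal).
    Blocking a standing outward current makes the delta negative."""
    b, f1 = _stationary_mean(basal, "holding")
    t, f2 = _stationary_mean(treated, "holding")
    return ConditionDelta("holding_current_pA", b, t, t - b,
                          100.0 * (t - b) / b if b != 0 else math.nan,
                          flags=f1 + f2)


def vm_shift(basal: Trace, treated: Trace) -> ConditionDelta:
    """Change in membrane potential between conditions (treated - basal);
    expected depolarizing (positive) when a K+ conductance is blocked."""
    b, f1 = _stationary_mean(basal, "vm")
    t, f2 = _stationary_mean(treated, "vm")
    return ConditionDelta("membrane_potential_mV", b, t, t - b,
                          100.0 * (t - b) / b if b != 0 else math.nan,
                          flags=f1 + f2)


def rin_change(basal_rin: float, treated_rin: float) -> ConditionDelta:
    """Percent change of input resistance between conditions."""
    if basal_rin <= 0:
        raise AnalysisError("basal input resistance must be > 0")
    delta = treated_rin - basal_rin
    return ConditionDelta("input_resistance_MOhm", basal_rin, treated_rin,
                          delta, 100.0 * delta / basal_rin)
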