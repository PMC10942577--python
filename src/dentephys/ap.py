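"""Action-potential and passive-membrane feature extraction.

AP threshold is taken at the first peak of the third-order derivative of
the voltage trace preceding the AP peak; rheobase is the injected ramp
current at the threshold time and rheobase charge transfer the integral of
the depolarizing ramp current up to that time.  Waveform kinetics (maximum
rise rate, 10-90% rise/fall times, duration at the -10 mV crossing,
threshold-to-peak amplitude) are measured on the first AP of a ramp-evoked
train.  Passive properties come from 500 ms current steps.  Interneuron
firing patterns in response to a 100 pA / 600 ms step are classified as
fast-spiking, regular-spiking or stuttering-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import ProtocolError, ProtocolSpec, Trace

# AP counting criterion: upward crossing of DETECT_CROSS with a peak of at
# least PEAK_MIN, merging peaks closer than MIN_SEPARATION ms.
DETECT_CROSS = -20.0  # mV
PEAK_MIN = -10.0  # mV
MIN_SEPARATION = 2.0  # ms
WINDOW_PRE = 5.0  # ms of threshold-search region before the peak
WINDOW_POST = 10.0  # ms after the peak

SG_WINDOW_MS = 0.5  # Savitzky-Golay smoothing window for derivatives
SG_ORDER = 3
D3_FLOOR_MULT = 5.0  # third-derivative peak must exceed this x noise floor
D3_REL_FLOOR = 0.05  # ... and this fraction of the window's d3 maximum


@dataclass
class APWindow:
    """Index span of one detected AP (half-open) and its peak index."""

    start: int
    stop: int
    peak_index: int


@dataclass
class APFeatures:
    """Features of a single AP. Undetectable features are NaN with a flag."""

    threshold_mV: float = math.nan
    threshold_time_ms: float = math.nan
    peak_mV: float = math.nan
    peak_time_ms: float = math.nan
    amplitude_mV: float = math.nan  # threshold -> peak
    max_rise_rate_mV_per_ms: float = math.nan
    rise_time_ms: float = math.nan  # 10-90% of amplitude, upstroke
    fall_time_ms: float = math.nan  # 10-90% of amplitude, downstroke
    duration_ms: float = math.nan  # at the -10 mV crossings
    flags: list = field(default_factory=list)


@dataclass
class APFeatureSet:
    """Per-trace summary: all AP features plus count/rheobase/charge."""

    per_ap: list[APFeatures]
    ap_count: int
    rheobase_pA: float = math.nan
    rheobase_charge_pC: float = math.nan


@dataclass
class PassiveProps:
    rmp_mV: float
    r_in_MOhm: float
    measurement_potential_mV: float
    step_amplitude_pA: float


@dataclass
class FiringPatternLabel:
    label: str  # fast_spiking | regular_spiking | stuttering_like | undetermined
    max_rate_Hz: float = math.nan
    adaptation_index: float = math.nan  # last ISI / first ISI
    isi_cv: float = math.nan


def detect_aps(trace: Trace) -> list[APWindow]:
    """Detect APs: upward crossings of -20 mV whose excursion peaks at or
    above -10 mV, with peaks closer than 2 ms merged to the larger one.
    Windows span 5 ms before to 10 ms after each peak."""
    if trace.signal_kind != "voltage":
        raise ProtocolError("detect_aps requires a voltage trace")
    v = trace.values
    dt = trace.dt
    up = np.flatnonzero((v[:-1] < DETECT_CROSS) & (v[1:] >= DETECT_CROSS)) + 1
    if up.size == 0:
        return []
    # end of each suprathreshold excursion
    peaks = []
    for i0 in up:
        j = i0
        while j < v.size and v[j] >= DETECT_CROSS:
            j += 1
        seg = v[i0:j]
        if seg.size == 0 or seg.max() < PEAK_MIN:
            continue
        peaks.append(i0 + int(np.argmax(seg)))
    if not peaks:
        return []
    # merge peaks closer than the refractory separation, keep the larger
    merged = [peaks[0]]
    for p in peaks[1:]:
        if (p - merged[-1]) * dt < MIN_SEPARATION:
            if v[p] > v[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    pre = int(round(WINDOW_PRE / dt))
    post = int(round(WINDOW_POST / dt))
    return [APWindow(start=max(0, p - pre), stop=min(v.size, p + post + 1),
                     peak_index=p) for p in merged]


def _smooth(v: np.ndarray, dt: float) -> np.ndarray:
    win = int(round(SG_WINDOW_MS / dt))
    win = max(win | 1, SG_ORDER + 2 - (SG_ORDER % 2))  # odd, > polyorder
    if win >= v.size:
        win = (v.size - 1) | 1
    if win <= SG_ORDER:
        return v.astype(float)
    return savgol_filter(v, win, SG_ORDER)


def _third_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Third derivative of the smoothed window, same length (edge-padded)."""
    s = _smooth(v, dt)
    d3 = np.diff(s, n=3) / dt**3
    return np.pad(d3, (2, 1), mode="edge")


def ap_threshold(trace: Trace, window: APWindow) -> tuple[float, float]:
    """AP threshold: voltage/time at the first local maximum of d3V/dt3
    preceding the AP peak and exceeding 5x the robust noise floor of the
    pre-AP baseline. Returns ``(nan, nan)`` (feature undetectable) when no
    qualifying peak exists."""
    v = trace.values[window.start:window.stop]
    dt = trace.dt
    rel_peak = window.peak_index - window.start
    d3 = _third_derivative(v, dt)
    # robust noise floor from the earliest quarter of the pre-peak region
    base_n = max(5, rel_peak // 4)
    base = d3[:base_n]
    mad = np.median(np.abs(base - np.median(base)))
    floor = D3_FLOOR_MULT * 1.4826 * mad
    search = d3[: rel_peak + 1]
    if search.size < 3:
        return math.nan, math.nan
    is_max = (search[1:-1] >= search[:-2]) & (search[1:-1] > search[2:])
    cand = np.flatnonzero(is_max) + 1
    # reject both noise bumps (absolute floor) and sub-percent shoulders on
    # the foot (relative floor): the threshold peak is a dominant feature
    floor = max(floor, D3_REL_FLOOR * float(search.max()), 0.0)
    cand = cand[search[cand] > floor]
    if cand.size == 0:
        return math.nan, math.nan
    i = int(cand[0])
    # sub-sample refinement: parabola through the d3 peak and neighbours
    di = 0.0
    if 1 <= i < d3.size - 1:
        y0, y1, y2 = d3[i - 1], d3[i], d3[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            di = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    t_th = trace.t0 + (window.start + i + di) * dt
    s = _smooth(v, dt)
    v_th = float(np.interp(i + di, np.arange(s.size), s))
    return v_th, float(t_th)


def rheobase_and_charge(
    trace: Trace, protocol: ProtocolSpec, t_th: float
) -> tuple[float, float]:
    """Rheobase (pA) and rheobase charge transfer (pC) from a ramp protocol.

    Rheobase is the injected ramp current at the threshold time of the
    first AP; charge is the integral of the injected current from the start
    of the depolarizing segment (the zero-crossing of a hyperpolarizing-
    onset ramp) to the threshold time, in pC (pA*ms/1000). Exact for the
    piecewise-linear ramp (the trapezoid rule is exact on a linear
    integrand)."""
    if protocol.kind != "ramp":
        raise ProtocolError("rheobase is defined for ramp protocols only")
    onset = protocol.ramp_onset
    rate = protocol.ramp_rate
    pre = protocol.ramp_pre_offset
    if t_th < onset:
        raise ProtocolError("threshold time precedes ramp onset")
    rheobase = pre + rate * (t_th - onset)
    # start of the depolarizing (positive-current) segment
    if pre >= 0:
        t_start = onset
        i_start = pre
    else:
        t_start = onset - pre / rate  # pre < 0, rate > 0
        i_start = 0.0
    if t_th <= t_start:
        return float(rheobase), 0.0
    charge_pa_ms = 0.5 * (i_start + rheobase) * (t_th - t_start)
    return float(rheobase), float(charge_pa_ms / 1000.0)


def _cross_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First linear-interpolated crossing of ``level`` in the stated
    direction; NaN when absent."""
    if rising:
        idx = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        idx = np.flatnonzero((y[:-1] >= level) & (y[1:] < level))
    if idx.size == 0:
        return math.nan
    i = int(idx[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ap_waveform_features(trace: Trace, window: APWindow,
                         v_th: float | None = None,
                         t_th: float | None = None) -> APFeatures:
    """All per-AP features. When ``v_th`` is not given it is computed via
    :func:`ap_threshold`."""
    f = APFeatures()
    if v_th is None or t_th is None:
        v_th, t_th = ap_threshold(trace, window)
    f.threshold_mV, f.threshold_time_ms = v_th, t_th
    v = trace.values[window.start:window.stop]
    dt = trace.dt
    t = trace.t0 + (window.start + np.arange(v.size)) * dt
    rel_peak = window.peak_index - window.start
    f.peak_mV = float(v[rel_peak])
    f.peak_time_ms = float(t[rel_peak])

    # maximum rise rate: peak of the first-order derivative on the upstroke.
    # Boxcar smoothing before central differences: a positive kernel can
    # never overshoot the true slope at waveform corners (polynomial-fit
    # derivatives do).
    from scipy.ndimage import uniform_filter1d

    box = max(3, int(round(SG_WINDOW_MS / dt)) | 1)
    d1 = np.gradient(uniform_filter1d(v, box, mode="nearest"), dt)
    f.max_rise_rate_mV_per_ms = float(d1[: rel_peak + 1].max())

    if math.isnan(v_th):
        f.flags.append("threshold_undetectable")
        return f
    f.amplitude_mV = f.peak_mV - v_th

    lo = v_th + 0.1 * f.amplitude_mV
    hi = v_th + 0.9 * f.amplitude_mV
    up_t, up_v = t[: rel_peak + 1], v[: rel_peak + 1]
    t10 = _cross_time(up_t, up_v, lo, rising=True)
    t90 = _cross_time(up_t, up_v, hi, rising=True)
    f.rise_time_ms = t90 - t10

    down_t, down_v = t[rel_peak:], v[rel_peak:]
    t90d = _cross_time(down_t, down_v, hi, rising=False)
    t10d = _cross_time(down_t, down_v, lo, rising=False)
    f.fall_time_ms = t10d - t90d
    if math.isnan(f.fall_time_ms):
        f.flags.append("downstroke_incomplete")

    if f.peak_mV > PEAK_MIN:
        tu = _cross_time(up_t, up_v, PEAK_MIN, rising=True)
        td = _cross_time(down_t, down_v, PEAK_MIN, rising=False)
        f.duration_ms = td - tu
        if math.isnan(f.duration_ms):
            f.flags.append("duration_right_censored")
    else:
        f.flags.append("duration_undefined")
    return f


def extract_features(trace: Trace, protocol: ProtocolSpec | None = None) -> APFeatureSet:
    """Detect APs and extract all features; with a ramp protocol, rheobase
    and charge are computed from the FIRST AP's threshold time."""
    windows = detect_aps(trace)
    per_ap = [ap_waveform_features(trace, w) for w in windows]
    fs = APFeatureSet(per_ap=per_ap, ap_count=len(windows))
    if protocol is not None and protocol.kind == "ramp" and per_ap:
        t_th = per_ap[0].threshold_time_ms
        if not math.isnan(t_th):
            fs.rheobase_pA, fs.rheobase_charge_pC = rheobase_and_charge(
                trace, protocol, t_th)
    return fs


def excitability_curve(traces: list[Trace]) -> dict[float, float]:
    """Mean AP count per set potential, ordered by potential.

    Each trace must carry ``meta['set_potential_mV']``; multiple traces at
    the same potential are trials and averaged."""
    by_pot: dict[float, list[int]] = {}
    for tr in traces:
        if "set_potential_mV" not in tr.meta:
            raise ProtocolError("trace lacks set_potential_mV metadata")
        pot = float(tr.meta["set_potential_mV"])
        by_pot.setdefault(pot, []).append(len(detect_aps(tr)))
    return {pot: float(np.mean(counts)) for pot, counts in sorted(by_pot.items())}


def passive_props(trace: Trace, protocol: ProtocolSpec) -> PassiveProps:
    """Input resistance from a 500 ms current step.

    R_in = |dV/dI| with dV = mean(last 100 ms of the step) - mean(100 ms of
    pre-step baseline); mV/pA converted to MOhm. The baseline mean is the
    RMP when no holding current is applied, otherwise the measurement
    potential."""
    if protocol.kind != "step":
        raise ProtocolError("passive_props requires a step protocol")
    if protocol.step_duration < 300.0:
        raise ProtocolError("step shorter than 300 ms: insufficient settling")
    on = protocol.step_onset
    off = on + protocol.step_duration
    if on < 100.0:
        raise ProtocolError("need >= 100 ms pre-step baseline")
    base = trace.slice_time(on - 100.0, on)
    steady = trace.slice_time(off - 100.0, off)
    dv = float(np.mean(steady) - np.mean(base))
    r_in = abs(dv / protocol.step_amplitude) * 1000.0  # mV/pA -> MOhm
    return PassiveProps(
        rmp_mV=float(np.mean(base)),
        r_in_MOhm=r_in,
        measurement_potential_mV=float(np.mean(base)),
        step_amplitude_pA=float(protocol.step_amplitude),
    )


# firing-pattern decision thresholds (config defaults; qualitative classes)
FP_CV_STUTTER = 0.5
FP_RATE_FAST = 50.0  # Hz
FP_ADAPT_FAST = 1.3


def classify_firing_pattern(trace: Trace) -> FiringPatternLabel:
    """Classify the response to a 100 pA / 600 ms step.

    Metrics from spike times: max instantaneous rate (1000/min ISI, Hz),
    adaptation index (last ISI / first ISI), ISI coefficient of variation.
    Rule: ISI CV > 0.5 -> stuttering_like; else rate >= 50 Hz and
    adaptation < 1.3 -> fast_spiking; else regular_spiking. Fewer than 3
    APs -> undetermined."""
    windows = detect_aps(trace)
    if len(windows) < 3:
        return FiringPatternLabel(label="undetermined")
    t_peaks = np.array([trace.t0 + w.peak_index * trace.dt for w in windows])
    isi = np.diff(t_peaks)
    max_rate = 1000.0 / isi.min()
    adapt = float(isi[-1] / isi[0])
    cv = float(np.std(isi) / np.mean(isi))
    if cv > FP_CV_STUTTER:
        label = "stuttering_like"
    elif max_rate >= FP_RATE_FAST and adapt < FP_ADAPT_FAST:
        label = "fast_spiking"
    else:
        label = "regular_spiking"
    return FiringPatternLabel(label=label, max_rate_Hz=float(max_rate),
                              adaptation_index=adapt, isi_cv=cv)
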