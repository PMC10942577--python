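"""Theta-gamma stimulation analysis: per-stimulus AP detection, AP
probability in 1-s bins, EPSP amplitudes, and gamma suppression.

The control protocol is 15 extracellular stimuli at 5 Hz; the test protocol
adds a burst of five stimuli at 50 Hz ending 200 ms before the theta train.
A theta stimulus 'evoked' an AP when a spike is detected within a response
window (default 50 ms) after it; AP probability is computed per 1-s bin of
the theta train (5 stimuli per bin) from at least 10 trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import ap as _ap
from .core import ProtocolError, ProtocolSpec, Trace
from .synth import StimRaster, theta_gamma_times

RESPONSE_WINDOW_MS = 50.0
BIN_MS = 1000.0
N_BINS = 3
MIN_TRIALS = 10


def build_stim_protocol(kind: str = "control", theta_hz: float = 5.0,
                        n_theta: int = 15, gamma_hz: float = 50.0,
                        n_gamma: int = 5, lead_ms: float = 200.0) -> ProtocolSpec:
    """Stimulus-train protocol. Control: theta stimuli at t=0,200,...;
    test: a gamma burst whose last stimulus is ``lead_ms`` before theta
    onset, then the theta train."""
    if kind not in ("control", "test"):
        raise ProtocolError("kind must be 'control' or 'test'")
    theta, gamma = theta_gamma_times(theta_hz, n_theta, gamma_hz, n_gamma,
                                     lead_ms, with_gamma=(kind == "test"))
    times = np.concatenate([gamma, theta]) if gamma.size else theta
    spec = ProtocolSpec(kind="stim_train", stim_times=list(times))
    return spec


@dataclass
class StimTrainResult:
    protocol: str  # 'control' or 'test'
    stim_times: np.ndarray  # theta stimuli, ms
    spike_matrix: np.ndarray  # bool (n_trials, n_theta)
    bin_probability: np.ndarray  # per 1-s bin
    bin_edges_s: np.ndarray
    n_trials: int
    flags: list = field(default_factory=list)


def _theta_times(protocol: ProtocolSpec, protocol_kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Split a stim_train protocol into (gamma burst, theta train): the
    theta train is the final run of equal long intervals starting at the
    first non-negative stimulus time (theta onset at t=0 by convention)."""
    times = np.asarray(protocol.stim_times, float)
    theta = times[times >= 0.0]
    gamma = times[times < 0.0]
    if protocol_kind == "control" and gamma.size:
        raise ProtocolError("control protocol must not contain a gamma burst")
    return gamma, theta


def ap_probability_binned(
    traces_or_raster: list[Trace] | StimRaster,
    protocol: ProtocolSpec | None = None,
    protocol_kind: str = "control",
    response_window_ms: float = RESPONSE_WINDOW_MS,
) -> StimTrainResult:
    """AP probability per 1-s bin of the theta train.

    Accepts either voltage traces (spikes found with the AP detector within
    ``response_window_ms`` after each theta stimulus) or a Bernoulli
    StimRaster. Gamma-burst stimuli are excluded from the probability.
    Fewer than 10 trials is flagged (still computed)."""
    flags: list = []
    if isinstance(traces_or_raster, StimRaster):
        raster = traces_or_raster
        theta = raster.stim_times
        spikes = raster.spikes.astype(bool)
        kind = raster.protocol
    else:
        traces = traces_or_raster
        if protocol is None:
            raise ProtocolError("protocol required with voltage traces")
        _, theta = _theta_times(protocol, protocol_kind)
        kind = protocol_kind
        spikes = np.zeros((len(traces), theta.size), dtype=bool)
        for i, tr in enumerate(traces):
            peaks = np.array([tr.t0 + w.peak_index * tr.dt
                              for w in _ap.detect_aps(tr)])
            for j, st in enumerate(theta):
                spikes[i, j] = bool(np.any((peaks >= st) &
                                           (peaks < st + response_window_ms)))
    n_trials = spikes.shape[0]
    if n_trials < MIN_TRIALS:
        flags.append("low_trial_count")
    onset = theta[0]
    edges = onset + BIN_MS * np.arange(N_BINS + 1)
    probs = np.empty(N_BINS)
    for b in range(N_BINS):
        sel = (theta >= edges[b]) & (theta < edges[b + 1]) if b < N_BINS - 1 \
            else (theta >= edges[b]) & (theta <= edges[b + 1])
        probs[b] = spikes[:, sel].mean() if sel.any() else math.nan
    return StimTrainResult(protocol=kind, stim_times=theta, spike_matrix=spikes,
                           bin_probability=probs,
                           bin_edges_s=(edges - onset) / 1000.0,
                           n_trials=n_trials, flags=flags)


@dataclass
class EPSPResult:
    amplitudes_mV: np.ndarray  # (n_trials, n_theta); NaN where AP-contaminated
    mean_per_stimulus: np.ndarray
    n_excluded: int


def epsp_amplitudes(
    traces: list[Trace],
    protocol: ProtocolSpec,
    protocol_kind: str = "test",
    baseline_mV: float = -70.0,
    response_window_ms: float = RESPONSE_WINDOW_MS,
) -> EPSPResult:
    """Per-stimulus EPSP amplitude: peak within the response window minus
    the pre-gamma baseline (nominally -70 mV; measured from the trace
    segment before the first stimulus). Stimuli that evoked APs are
    excluded per-stimulus (NaN, counted)."""
    _, theta = _theta_times(protocol, protocol_kind)
    all_times = np.asarray(protocol.stim_times, float)
    amps = np.full((len(traces), theta.size), np.nan)
    n_excluded = 0
    for i, tr in enumerate(traces):
        base_seg = tr.slice_time(tr.t0, all_times[0])
        base = float(np.mean(base_seg)) if base_seg.size else baseline_mV
        peaks = np.array([tr.t0 + w.peak_index * tr.dt
                          for w in _ap.detect_aps(tr)])
        for j, st in enumerate(theta):
            if np.any((peaks >= st) & (peaks < st + response_window_ms)):
                n_excluded += 1
                continue
            seg = tr.slice_time(st, st + response_window_ms)
            if seg.size:
                amps[i, j] = float(seg.max()) - base
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(amps, axis=0)
    return EPSPResult(amplitudes_mV=amps, mean_per_stimulus=mean,
                      n_excluded=n_excluded)


def normalize_epsp(test: EPSPResult, control: EPSPResult) -> np.ndarray:
    """Test-train EPSP amplitude / control-train amplitude at the matching
    stimulus position."""
    return test.mean_per_stimulus / control.mean_per_stimulus


@dataclass
class GammaSuppression:
    delta_p: np.ndarray  # per-bin p_test - p_control
    ratio: np.ndarray  # per-bin p_test / p_control (NaN where undefined)
    first_bin_delta: float
    first_bin_ratio: float


def gamma_suppression_index(control: StimTrainResult,
                            test: StimTrainResult) -> GammaSuppression:
    """Per-bin probability difference and ratio; the headline comparison is
    the first-second bin."""
    if control.bin_probability.size != test.bin_probability.size:
        raise ProtocolError("control and test must have matching bins")
    delta = test.bin_probability - control.bin_probability
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(control.bin_probability > 0,
                         test.bin_probability / control.bin_probability, np.nan)
    return GammaSuppression(delta_p=delta, ratio=ratio,
                            first_bin_delta=float(delta[0]),
                            first_bin_ratio=float(ratio[0]))
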