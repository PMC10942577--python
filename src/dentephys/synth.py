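"""Synthetic patch-clamp recordings with known ground truth.

Every protocol the analysis stages consume can be generated here with
explicit parameters, so each stage is verifiable by parameter recovery:

* current-clamp step/ramp/multistep responses of a spiking membrane with a
  tunable subthreshold Kv7-like (M-type) K+ conductance,
* voltage-clamp ramps with and without the Kv7 conductance (emulating
  block by XE991),
* Poisson trains of biexponential PSCs with lognormal amplitudes,
* stimulus-evoked compound PSCs built from known EPSC and IPSC components,
* Bernoulli spike responses to theta trains with and without a preceding
  gamma burst,
* whole cohorts of jittered "cells" in two genotype groups.

Membrane model
--------------
The spike generator is an exponential-threshold membrane: a leaky RC cell
plus an instantaneous saturating Na+ drive ``g_na * m_inf(V)**3 * (E_na - V)``
whose subthreshold foot is exponential in V with slope ``delta_T``
(``k_m = 3*delta_T``), i.e. exponential-integrate-and-fire dynamics near
threshold, and a single fast-K recovery gate that repolarizes the spike so
full AP waveforms (peak, downstroke, duration) exist in the trace.  One
additional first-order subthreshold K+ gate with Boltzmann steady state
``a_inf(V) = 1/(1 + exp((v_half - a)/k))`` models the Kv7/M conductance;
the knockout profile differs from wildtype only by a scale factor on
``g_kv7_max``.  Current noise is Ornstein-Uhlenbeck.  Integration is
fixed-step exponential Euler at ``DT_SIM`` (0.005 ms), subsampled to the
requested output interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .core import (
    CellRecord,
    ProtocolSpec,
    Trace,
    AnalysisError,
    ProtocolError,
)

DT_SIM = 0.005  # ms, internal integration step
DT_OUT = 0.02  # ms, default output sampling interval (50 kHz)


@dataclass
class MembraneParams:
    """Parameters of the synthetic spiking membrane.

    Units: pF, nS, mV, ms, pA. ``g_kv7_max`` is the maximal Kv7/M
    conductance; a knockout profile is the wildtype with ``g_kv7_max``
    scaled by a factor >= 1 (enhanced Kv7 function).
    """

    C: float = 150.0  # pF (mossy-cell-like)
    g_leak: float = 6.7  # nS -> ~150 MOhm input resistance
    E_leak: float = -65.0  # mV, resting potential
    V_T: float = -45.0  # mV, exponential spike-threshold parameter
    delta_T: float = 2.0  # mV, spike sharpness
    refractory: float = 2.0  # ms, minimum separation of truth spikes
    # Kv7 / M-type subthreshold K+ conductance
    g_kv7_max: float = 1.5  # nS (wildtype)
    kv7_v_half: float = -40.0  # mV
    kv7_k: float = 8.0  # mV
    tau_kv7: float = 50.0  # ms
    E_K: float = -90.0  # mV
    # spike-shaping currents: saturating Na drive (instantaneous activation,
    # first-order inactivation) + fast-K recovery gate
    g_na: float = 1200.0  # nS
    E_na: float = 55.0  # mV
    na_h_v_half: float = -25.0  # mV, fast-inactivation midpoint
    na_h_k: float = 4.0  # mV
    tau_h: float = 1.5  # ms
    # slow (cumulative) Na inactivation: couples threshold to approach speed
    na_hs_v_half: float = -44.0  # mV
    na_hs_k: float = 2.5  # mV
    tau_hs: float = 120.0  # ms
    na_hs_floor: float = 0.25  # residual Na availability
    g_kd: float = 500.0  # nS
    kd_v_half: float = -5.0  # mV, depolarized so the gate is spike-only
    kd_k: float = 4.0  # mV
    tau_kd: float = 0.8  # ms
    # noise
    noise_sigma: float = 0.0  # pA, stationary sd of OU current noise
    noise_tau: float = 2.0  # ms, OU correlation time
    genotype: str = "WT"

    def __post_init__(self) -> None:
        for name in ("C", "g_leak", "delta_T", "kv7_k", "tau_kv7"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")

    @property
    def k_m(self) -> float:
        """Na activation slope; m_inf**3 foot slope equals delta_T."""
        return 3.0 * self.delta_T

    @property
    def vm_half(self) -> float:
        """Na half-activation chosen so the Na foot matches the
        exponential-integrate-and-fire spike term
        ``g_leak*delta_T*exp((V-V_T)/delta_T)`` at ``V = V_T``."""
        ratio = self.g_na * (self.E_na - self.V_T) / (self.g_leak * self.delta_T)
        return self.V_T + self.delta_T * math.log(ratio)

    def ko(self, scale: float = 1.5) -> "MembraneParams":
        """Knockout profile: wildtype with ``g_kv7_max`` scaled up."""
        if scale < 1:
            raise ValueError("KO scale factor must be >= 1")
        return replace(self, g_kv7_max=self.g_kv7_max * scale, genotype="KO")

    def a_inf(self, v: np.ndarray | float) -> np.ndarray | float:
        """Kv7 steady-state activation."""
        return 1.0 / (1.0 + np.exp((self.kv7_v_half - np.asarray(v, float)) / self.kv7_k))

    def kv7_current(self, v: np.ndarray | float) -> np.ndarray | float:
        """Steady-state Kv7 current (pA, outward positive) at voltage v."""
        v = np.asarray(v, float)
        return self.g_kv7_max * self.a_inf(v) * (v - self.E_K)

    def h_inf(self, v: np.ndarray | float) -> np.ndarray | float:
        """Na steady-state fast inactivation (1 at rest, 0 depolarized)."""
        return 1.0 / (1.0 + np.exp((np.asarray(v, float) - self.na_h_v_half) / self.na_h_k))

    def hs_inf(self, v: np.ndarray | float) -> np.ndarray | float:
        """Na steady-state slow inactivation, floored at ``na_hs_floor``."""
        sig = 1.0 / (1.0 + np.exp((np.asarray(v, float) - self.na_hs_v_half) / self.na_hs_k))
        return self.na_hs_floor + (1.0 - self.na_hs_floor) * sig

    def na_current(self, v: np.ndarray | float) -> np.ndarray | float:
        """Quasi-static Na drive (pA, positive = inward contribution) with
        activation and both inactivation gates at steady state."""
        v = np.asarray(v, float)
        m = 1.0 / (1.0 + np.exp((self.vm_half - v) / self.k_m))
        return self.g_na * m**3 * self.h_inf(v) * self.hs_inf(v) * (self.E_na - v)

    def kd_current(self, v: np.ndarray | float) -> np.ndarray | float:
        """Steady-state fast-rectifier current (pA, outward positive);
        negligible below spike voltages but kept for exact fixed points."""
        v = np.asarray(v, float)
        n = 1.0 / (1.0 + np.exp((self.kd_v_half - v) / self.kd_k))
        return self.g_kd * n * (v - self.E_K)

    def steady_state_current(self, v: float) -> float:
        """Injected current (pA) for which v is a membrane fixed point."""
        return float(
            self.g_leak * (v - self.E_leak)
            + self.kv7_current(v)
            + self.kd_current(v)
            - self.na_current(v)
        )


@dataclass
class EventTrainParams:
    """Parameters of a Poisson PSC train with biexponential kernels."""

    rate: float = 10.0  # Hz
    duration: float = 30.0  # s
    amp_mu: float = math.log(30.0)  # lognormal mu of |amplitude| in pA
    amp_sigma: float = 0.4  # lognormal sigma
    amp_min: float = 0.0  # pA, lower clip of |amplitude| (0 = unclipped)
    tau_rise: float = 0.5  # ms
    tau_decay: float = 5.0  # ms
    polarity: str = "inward"  # inward (negative) or outward (positive)
    noise_sd: float = 2.0  # pA Gaussian
    dt: float = 0.05  # ms
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every generated recording."""

    spike_times: np.ndarray | None = None  # ms
    event_times: np.ndarray | None = None  # ms
    event_amps: np.ndarray | None = None  # pA, signed
    components: dict = field(default_factory=dict)  # named noise-free traces
    params: object = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# current-clamp integration
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate_cc(
    i_inj, dt, v0, C, gL, EL, gNa, ENa, vmh, km, hvh, hk, tau_h,
    hsvh, hsk, tau_hs, hs_floor,
    gKd, vkh, kk, tau_kd, gkv7, vah, ka, tau_kv7, EK,
):  # pragma: no cover - numba kernel
    n = i_inj.size
    v_out = np.empty(n)
    a_out = np.empty(n)
    v = v0
    a = 1.0 / (1.0 + np.exp((vah - v) / ka))
    nn = 1.0 / (1.0 + np.exp((vkh - v) / kk))
    h = 1.0 / (1.0 + np.exp((v - hvh) / hk))
    hs = hs_floor + (1.0 - hs_floor) / (1.0 + np.exp((v - hsvh) / hsk))
    e_kd = np.exp(-dt / tau_kd)
    e_h = np.exp(-dt / tau_h)
    e_hs = np.exp(-dt / tau_hs)
    e_a = np.exp(-dt / tau_kv7)
    for i in range(n):
        m = 1.0 / (1.0 + np.exp((vmh - v) / km))
        g_na = gNa * m * m * m * h * hs
        g_tot = gL + g_na + gKd * nn + gkv7 * a
        num = gL * EL + g_na * ENa + (gKd * nn + gkv7 * a) * EK + i_inj[i]
        v_inf = num / g_tot
        v = v_inf + (v - v_inf) * np.exp(-g_tot * dt / C)
        n_inf = 1.0 / (1.0 + np.exp((vkh - v) / kk))
        nn = n_inf + (nn - n_inf) * e_kd
        h_inf = 1.0 / (1.0 + np.exp((v - hvh) / hk))
        h = h_inf + (h - h_inf) * e_h
        hs_i = hs_floor + (1.0 - hs_floor) / (1.0 + np.exp((v - hsvh) / hsk))
        hs = hs_i + (hs - hs_i) * e_hs
        a_inf = 1.0 / (1.0 + np.exp((vah - v) / ka))
        a = a_inf + (a - a_inf) * e_a
        v_out[i] = v
        a_out[i] = a
    return v_out, a_out


def _ou_noise(n: int, dt: float, sigma: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (sd = sigma, correlation tau)."""
    if sigma == 0:
        return np.zeros(n)
    rho = math.exp(-dt / tau)
    xi = rng.standard_normal(n)
    x = lfilter([sigma * math.sqrt(1.0 - rho * rho)], [1.0, -rho], xi)
    # start from a stationary sample rather than zero
    x0 = sigma * rng.standard_normal()
    x += x0 * rho ** np.arange(1, n + 1)
    return x


def _true_spikes(v: np.ndarray, dt: float, t0: float, refractory: float) -> np.ndarray:
    """Times (ms) of upward 0 mV crossings, separated by >= refractory."""
    up = np.flatnonzero((v[:-1] < 0.0) & (v[1:] >= 0.0)) + 1
    times = []
    last = -math.inf
    for i in up:
        t = t0 + i * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times, float)


def _run_cc(
    params: MembraneParams,
    i_inj_sim: np.ndarray,
    seed: int | None,
    dt_out: float,
    v0: float | None = None,
    i_hold: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate at DT_SIM with optional OU noise; subsample to dt_out.

    Returns (v_out, a_out, v_sim). ``i_hold`` is a constant holding current
    added to the protocol current.
    """
    rng = np.random.default_rng(seed)
    n = i_inj_sim.size
    i_tot = i_inj_sim + i_hold
    if params.noise_sigma > 0:
        i_tot = i_tot + _ou_noise(n, DT_SIM, params.noise_sigma, params.noise_tau, rng)
    if v0 is None:
        v0 = _resting_potential(params, i_hold)
    v, a = _integrate_cc(
        np.ascontiguousarray(i_tot), DT_SIM, v0,
        params.C, params.g_leak, params.E_leak,
        params.g_na, params.E_na, params.vm_half, params.k_m,
        params.na_h_v_half, params.na_h_k, params.tau_h,
        params.na_hs_v_half, params.na_hs_k, params.tau_hs, params.na_hs_floor,
        params.g_kd, params.kd_v_half, params.kd_k, params.tau_kd,
        params.g_kv7_max, params.kv7_v_half, params.kv7_k, params.tau_kv7,
        params.E_K,
    )
    if not np.all(np.isfinite(v)) or v.max() > 80.0 or v.min() < -130.0:
        raise AnalysisError("membrane integration unstable (voltage out of range)")
    stride = max(1, int(round(dt_out / DT_SIM)))
    return v[::stride], a[::stride], v


def _resting_potential(params: MembraneParams, i_hold: float = 0.0) -> float:
    """Lowest stable membrane fixed point for a constant injected current.

    Scans upward from hyperpolarized voltages for the first zero crossing
    of the net current (covers both normal cells, whose rest sits below the
    spike threshold, and pharmacologically isolated cells whose fixed point
    may lie above it). Falls back to E_leak when the cell is tonically
    active at this current."""
    from scipy.optimize import brentq

    f = lambda v: -params.steady_state_current(v) + i_hold
    grid = np.arange(-110.0, -19.9, 0.5)
    vals = np.array([f(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        return params.E_leak
    i = int(sign_change[0])
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-10))


def holding_current_for_potential(params: MembraneParams, v_set: float) -> float:
    """Constant current (pA) that sets the subthreshold potential to v_set."""
    return params.steady_state_current(v_set)


def simulate_membrane(
    params: MembraneParams,
    protocol: ProtocolSpec,
    seed: int | None = None,
    dt_out: float = DT_OUT,
    duration_ms: float | None = None,
    i_hold: float = 0.0,
):
    """Simulate a current-clamp protocol.

    For ``step`` and ``ramp`` protocols returns ``(Trace, SimulationTruth)``;
    for ``multistep`` returns ``(list of Trace, SimulationTruth)`` whose
    ``extras['spike_times_per_step']`` holds per-sweep truth. Deterministic
    given ``seed``; with ``noise_sigma == 0`` the trace is seed-independent.
    """
    if dt_out > 0.05 + 1e-12:
        raise ProtocolError("dt_out must be <= 0.05 ms for AP-resolved traces")
    if protocol.kind == "multistep":
        traces, per_step = [], []
        for amp in protocol.steps:
            sub = ProtocolSpec(
                kind="step", step_amplitude=amp,
                step_onset=protocol.step_onset, step_duration=protocol.step_duration,
            )
            tr, truth = simulate_membrane(params, sub, seed=seed, dt_out=dt_out,
                                          duration_ms=duration_ms, i_hold=i_hold)
            tr.meta["step_amplitude"] = amp
            traces.append(tr)
            per_step.append(truth.spike_times)
        truth = SimulationTruth(params=params, seed=seed,
                                extras={"spike_times_per_step": per_step})
        return traces, truth

    if protocol.kind not in ("step", "ramp"):
        raise ProtocolError(f"simulate_membrane cannot run kind {protocol.kind!r}")

    if duration_ms is None:
        if protocol.kind == "step":
            duration_ms = protocol.step_onset + protocol.step_duration + 200.0
        else:
            duration_ms = (protocol.ramp_onset or 0.0) + 2000.0
    n_sim = int(round(duration_ms / DT_SIM))
    t_sim = DT_SIM * np.arange(n_sim)
    i_inj = protocol.injected_current(t_sim)
    v_out, _, v_sim = _run_cc(params, i_inj, seed, dt_out, i_hold=i_hold)
    trace = Trace(
        values=v_out, dt=dt_out, t0=0.0, signal_kind="voltage",
        genotype=params.genotype,
        meta={"protocol_kind": protocol.kind, "i_hold_pA": i_hold},
    )
    spikes = _true_spikes(v_sim, DT_SIM, 0.0, params.refractory)
    truth = SimulationTruth(spike_times=spikes, params=params, seed=seed)
    return trace, truth


def simulate_set_potential(
    params: MembraneParams,
    v_set: float,
    duration_ms: float = 20_000.0,
    seed: int | None = None,
    noise_sigma: float = 150.0,
    noise_tau: float = 5.0,
    dt_out: float = DT_OUT,
):
    """Spontaneous firing at a set membrane potential.

    Emulates holding a cell at a given subthreshold potential via constant
    current injection while synaptic-like current fluctuations (OU noise,
    sd ``noise_sigma``, correlation ``noise_tau``) occasionally drive
    spikes. The default noise magnitude mimics the barrage of large
    spontaneous PSCs these cells receive in the intact circuit (membrane
    filtering attenuates it to a few mV of voltage noise). Returns
    (Trace, truth); ``meta['set_potential_mV']`` records the level.
    """
    p = replace(params, noise_sigma=noise_sigma, noise_tau=noise_tau)
    i_hold = holding_current_for_potential(params, v_set)
    n_sim = int(round(duration_ms / DT_SIM))
    v_out, _, v_sim = _run_cc(p, np.zeros(n_sim), seed, dt_out, v0=v_set, i_hold=i_hold)
    trace = Trace(values=v_out, dt=dt_out, signal_kind="voltage",
                  genotype=params.genotype,
                  meta={"set_potential_mV": v_set, "i_hold_pA": i_hold})
    spikes = _true_spikes(v_sim, DT_SIM, 0.0, params.refractory)
    return trace, SimulationTruth(spike_times=spikes, params=p, seed=seed)


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------


def simulate_vc_ramp(
    params: MembraneParams,
    ramp: ProtocolSpec,
    kv7_blocked: bool = False,
    seed: int | None = None,
    noise_sd: float = 0.0,
    dt_out: float = DT_OUT,
):
    """Clamp current in response to a voltage ramp.

    The command ramps from ``ramp.ramp_start`` to ``ramp.ramp_stop`` (mV) at
    ``ramp.ramp_rate`` (mV/ms) after ``ramp.ramp_onset``; before onset the
    command sits at ``ramp_start``.  The recorded current is leak plus the
    Kv7 current with first-order activation lag; ``kv7_blocked`` sets
    ``g_kv7_max`` to 0 (emulating saturating XE991). Capacitive transient is
    not modeled (capacitance is compensated at the amplifier).

    Returns ``(Trace current, Trace voltage_command)``.
    """
    if ramp.kind != "ramp" or ramp.ramp_start is None or ramp.ramp_stop is None:
        raise ProtocolError("simulate_vc_ramp needs a voltage ramp protocol "
                            "(ramp_start/ramp_stop in mV)")
    rate = ramp.ramp_rate
    span = ramp.ramp_stop - ramp.ramp_start
    ramp_dur = abs(span / rate)
    total = (ramp.ramp_onset or 0.0) + ramp_dur
    n = int(round(total / dt_out)) + 1
    t = dt_out * np.arange(n)
    v_cmd = np.clip(
        ramp.ramp_start + np.sign(span) * abs(rate) * np.maximum(t - ramp.ramp_onset, 0.0),
        min(ramp.ramp_start, ramp.ramp_stop), max(ramp.ramp_start, ramp.ramp_stop),
    )
    i_leak = params.g_leak * (v_cmd - params.E_leak)
    g = 0.0 if kv7_blocked else params.g_kv7_max
    a_inf = params.a_inf(v_cmd)
    if params.tau_kv7 <= dt_out:  # instantaneous limit
        a = a_inf
    else:
        alpha = 1.0 - math.exp(-dt_out / params.tau_kv7)
        a = lfilter([alpha], [1.0, -(1.0 - alpha)], a_inf, zi=[(1 - alpha) * a_inf[0]])[0]
    i_kv7 = g * a * (v_cmd - params.E_K)
    current = i_leak + i_kv7
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + noise_sd * rng.standard_normal(n)
    tr_i = Trace(values=current, dt=dt_out, signal_kind="current",
                 condition="XE991" if kv7_blocked else "basal",
                 genotype=params.genotype,
                 meta={"ramp_rate_mV_per_ms": rate, "capacitance_pF": params.C})
    tr_v = Trace(values=v_cmd, dt=dt_out, signal_kind="voltage",
                 meta={"role": "command"})
    return tr_i, tr_v


# ---------------------------------------------------------------------------
# synaptic event trains and compound PSCs
# ---------------------------------------------------------------------------


def biexp_kernel(dt: float, tau_rise: float, tau_decay: float,
                 length_ms: float | None = None) -> np.ndarray:
    """Biexponential PSC kernel sampled at dt, normalized to unit peak
    *on the sample grid* (so an event of amplitude A has extremum exactly A).
    """
    if length_ms is None:
        length_ms = 8.0 * tau_decay
    t = dt * np.arange(int(round(length_ms / dt)) + 1)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def generate_event_train(params: EventTrainParams):
    """Homogeneous Poisson train of biexponential PSCs plus Gaussian noise.

    Event times are snapped to the sample grid; each event adds
    ``amplitude * kernel`` with the kernel normalized to unit peak, so the
    truth amplitudes are exact extremum values for isolated events.
    Amplitudes are lognormal(amp_mu, amp_sigma) in pA, signed by polarity.
    Returns (Trace current, SimulationTruth).
    """
    rng = np.random.default_rng(params.seed)
    dur_ms = params.duration * 1000.0
    n = int(round(dur_ms / params.dt))
    n_ev = rng.poisson(params.rate * params.duration)
    if params.rate * params.duration > 1e6:
        raise ValueError("event count budget exceeded (rate*duration > 1e6)")
    t_ev = np.sort(rng.uniform(0.0, dur_ms, size=n_ev))
    idx = np.round(t_ev / params.dt).astype(np.int64)
    keep = idx < n
    idx, t_ev = idx[keep], idx[keep] * params.dt  # grid-aligned truth times
    sign = -1.0 if params.polarity == "inward" else 1.0
    mags = rng.lognormal(params.amp_mu, params.amp_sigma, size=idx.size)
    if params.amp_min > 0:
        mags = np.maximum(mags, params.amp_min)
    amps = sign * mags

    impulses = np.zeros(n)
    np.add.at(impulses, idx, amps)
    kernel = biexp_kernel(params.dt, params.tau_rise, params.tau_decay)
    from scipy.signal import fftconvolve

    sig = fftconvolve(impulses, kernel)[:n]
    if params.noise_sd > 0:
        sig = sig + params.noise_sd * rng.standard_normal(n)
    trace = Trace(values=sig, dt=params.dt, signal_kind="current",
                  meta={"true_rate_Hz": params.rate, "polarity": params.polarity})
    truth = SimulationTruth(event_times=t_ev, event_amps=amps,
                            params=params, seed=params.seed)
    return trace, truth


def poisson_event_times(rate_hz: float, duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Poisson event times in ms over [0, duration_s*1000). Times only —
    used where the test or analysis needs ISIs without a rendered trace."""
    n_ev = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n_ev))


def compose_cpsc(
    epsc_peak: float = -120.0,
    epsc_latency: float = 2.0,
    ipsc_peak: float = 80.0,
    ipsc_latency: float = 4.0,
    epsc_taus: tuple[float, float] = (0.5, 5.0),
    ipsc_taus: tuple[float, float] = (1.0, 12.0),
    n_sweeps: int = 25,
    n_template_sweeps: int = 25,
    noise_sd: float = 0.0,
    amp_jitter_cv: float = 0.0,
    seed: int | None = None,
    dt: float = DT_OUT,
    pre_ms: float = 60.0,
    post_ms: float = 150.0,
):
    """Stimulus-evoked compound PSC sweeps built from known components.

    Each sweep (stimulus at t=0) is ``EPSC kernel + IPSC kernel + noise``;
    the amplitudes may be jittered sweep-to-sweep (lognormal, given CV).
    Also emits EPSC-only sweeps (the 'gabazine' condition) for template
    building. Truth stores the noise-free mean EPSC and IPSC components and
    the per-sweep amplitudes.

    Returns ``(cpsc_sweeps, template_sweeps, SimulationTruth)``.
    """
    if not (epsc_peak < 0 <= ipsc_peak):
        raise ValueError("require epsc_peak < 0 <= ipsc_peak")
    if ipsc_peak > 0 and not (ipsc_latency > epsc_latency):
        raise ValueError("require ipsc_latency > epsc_latency")
    rng = np.random.default_rng(seed)
    n = int(round((pre_ms + post_ms) / dt)) + 1
    t = -pre_ms + dt * np.arange(n)

    def component(peak: float, latency: float, taus: tuple[float, float]) -> np.ndarray:
        k = np.zeros(n)
        on = t >= latency
        u = t[on] - latency
        kern = np.exp(-u / taus[1]) - np.exp(-u / taus[0])
        k[on] = kern / kern.max()
        return peak * k

    epsc_unit = component(1.0, epsc_latency, epsc_taus)
    ipsc_unit = component(1.0, ipsc_latency, ipsc_taus) if ipsc_peak > 0 else np.zeros(n)

    def jittered(base: float, count: int) -> np.ndarray:
        if amp_jitter_cv <= 0:
            return np.full(count, base)
        sig = math.sqrt(math.log(1.0 + amp_jitter_cv**2))
        return base * rng.lognormal(-0.5 * sig**2, sig, size=count)

    e_amps = jittered(epsc_peak, n_sweeps)
    i_amps = jittered(ipsc_peak, n_sweeps) if ipsc_peak > 0 else np.zeros(n_sweeps)
    te_amps = jittered(epsc_peak, n_template_sweeps)

    def make(values: np.ndarray, condition: str) -> Trace:
        v = values.copy()
        if noise_sd > 0:
            v = v + noise_sd * rng.standard_normal(n)
        return Trace(values=v, dt=dt, t0=-pre_ms, signal_kind="current",
                     condition=condition, meta={"stim_ms": 0.0})

    sweeps = [make(e_amps[j] * epsc_unit + i_amps[j] * ipsc_unit, "basal")
              for j in range(n_sweeps)]
    template_sweeps = [make(te_amps[j] * epsc_unit, "gabazine")
                       for j in range(n_template_sweeps)]
    truth = SimulationTruth(
        components={
            "epsc_mean": float(np.mean(e_amps)) * epsc_unit,
            "ipsc_mean": float(np.mean(i_amps)) * ipsc_unit,
            "epsc_unit": epsc_unit,
            "ipsc_unit": ipsc_unit,
            "t": t,
        },
        params={"epsc_peak": epsc_peak, "ipsc_peak": ipsc_peak,
                "epsc_latency": epsc_latency, "ipsc_latency": ipsc_latency,
                "epsc_taus": epsc_taus, "ipsc_taus": ipsc_taus},
        seed=seed,
        extras={"epsc_amps": e_amps, "ipsc_amps": i_amps,
                "template_amps": te_amps},
    )
    return sweeps, template_sweeps, truth


# ---------------------------------------------------------------------------
# theta-gamma stimulation
# ---------------------------------------------------------------------------


@dataclass
class StimRaster:
    """Bernoulli spike outcomes of a theta train, per trial per stimulus."""

    stim_times: np.ndarray  # ms, theta stimuli only
    gamma_times: np.ndarray  # ms, empty for control protocol
    spikes: np.ndarray  # bool, (n_trials, n_stim)
    p_true: np.ndarray  # per-stimulus spike probability used
    epsp_scale_true: np.ndarray  # per-stimulus EPSP amplitude factor
    protocol: str  # 'control' or 'test'


def theta_gamma_times(theta_hz: float = 5.0, n_theta: int = 15,
                      gamma_hz: float = 50.0, n_gamma: int = 5,
                      lead_ms: float = 200.0, with_gamma: bool = True):
    """Stimulus times: theta train from t=0; gamma burst whose last stimulus
    ends ``lead_ms`` before theta onset."""
    theta = 1000.0 / theta_hz * np.arange(n_theta)
    if not with_gamma:
        return theta, np.array([])
    gamma_isi = 1000.0 / gamma_hz
    gamma = -lead_ms - gamma_isi * np.arange(n_gamma)[::-1]
    return theta, gamma


def simulate_theta_gamma(
    p_base: float = 0.5,
    suppression: float = 0.4,
    n_trials: int = 10,
    with_gamma: bool = True,
    seed: int | None = None,
    recovery_tau_ms: float = math.inf,
    theta_hz: float = 5.0,
    n_theta: int = 15,
    epsp_suppression: float | None = None,
) -> tuple[StimRaster, SimulationTruth]:
    """Bernoulli spike responses to a theta train.

    Per theta stimulus at time t (theta onset at 0, gamma burst ending at
    ``-lead_ms``), the spike probability is ``p_base`` for the control
    protocol and ``p_base * (s + (1-s) * (1 - exp(-(t+lead)/tau)))`` for the
    test protocol, i.e. suppression by factor ``s`` recovering toward
    ``p_base`` with time constant ``recovery_tau_ms`` (default infinite:
    sustained suppression across the train). ``epsp_suppression`` scales the
    subthreshold EPSP amplitude the same way (defaults to ``suppression``).
    """
    if not (0.0 <= p_base <= 1.0):
        raise ValueError("p_base must be in [0, 1]")
    if not (0.0 <= suppression <= 1.0):
        raise ValueError("suppression must be in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    theta, gamma = theta_gamma_times(theta_hz=theta_hz, n_theta=n_theta,
                                     with_gamma=with_gamma)
    if epsp_suppression is None:
        epsp_suppression = suppression

    def factor(s: float) -> np.ndarray:
        if not with_gamma:
            return np.ones_like(theta)
        elapsed = theta - (gamma[-1] if gamma.size else 0.0)
        if math.isinf(recovery_tau_ms):
            rec = np.zeros_like(theta)
        else:
            rec = 1.0 - np.exp(-elapsed / recovery_tau_ms)
        return s + (1.0 - s) * rec

    p_true = np.clip(p_base * factor(suppression), 0.0, 1.0)
    epsp_scale = factor(epsp_suppression)
    rng = np.random.default_rng(seed)
    spikes = rng.random((n_trials, theta.size)) < p_true[None, :]
    raster = StimRaster(stim_times=theta, gamma_times=gamma, spikes=spikes,
                        p_true=p_true, epsp_scale_true=epsp_scale,
                        protocol="test" if with_gamma else "control")
    truth = SimulationTruth(params={"p_base": p_base, "suppression": suppression,
                                    "recovery_tau_ms": recovery_tau_ms},
                            seed=seed, extras={"p_true": p_true,
                                               "epsp_scale": epsp_scale})
    return raster, truth


def render_theta_gamma_traces(
    raster: StimRaster,
    seed: int | None = None,
    dt: float = 0.1,
    baseline_mV: float = -70.0,
    epsp_amp: float = 8.0,
    noise_sd: float = 0.3,
    ap_peak: float = 25.0,
) -> list[Trace]:
    """Render a StimRaster as membrane-potential traces.

    Each theta stimulus adds a biexponential EPSP (amplitude
    ``epsp_amp * epsp_scale_true``); stimuli whose Bernoulli outcome is a
    spike additionally get a stereotyped AP waveform (logistic upstroke to
    ``ap_peak``, exponential repolarization) riding on the EPSP, 3-6 ms
    after the stimulus. Gamma stimuli add EPSPs only.
    """
    rng = np.random.default_rng(seed)
    t_start = (raster.gamma_times[0] - 50.0) if raster.gamma_times.size else -50.0
    t_stop = raster.stim_times[-1] + 150.0
    n = int(round((t_stop - t_start) / dt)) + 1
    t = t_start + dt * np.arange(n)

    # unit-peak EPSP kernel and stereotyped AP waveform
    ke = biexp_kernel(dt, tau_rise=2.0, tau_decay=20.0, length_ms=140.0)
    tw = dt * np.arange(int(round(8.0 / dt)))
    up = 1.0 / (1.0 + np.exp(-(tw - 1.0) / 0.12))
    down = np.exp(-np.maximum(tw - 1.0, 0.0) / 0.7)
    shape = up * down
    ap_wave = (ap_peak - baseline_mV) * shape / shape.max()

    traces = []
    for trial in range(raster.spikes.shape[0]):
        v = np.zeros(n)
        for st in raster.gamma_times:
            i0 = int(round((st - t_start) / dt))
            seg = min(ke.size, n - i0)
            v[i0:i0 + seg] += epsp_amp * ke[:seg]
        for j, st in enumerate(raster.stim_times):
            i0 = int(round((st - t_start) / dt))
            seg = min(ke.size, n - i0)
            v[i0:i0 + seg] += epsp_amp * raster.epsp_scale_true[j] * ke[:seg]
            if raster.spikes[trial, j]:
                lat = 3.0 + rng.uniform(0.0, 3.0)
                ia = int(round((st + lat - t_start) / dt))
                seg = min(ap_wave.size, n - ia)
                v[ia:ia + seg] = np.maximum(v[ia:ia + seg], ap_wave[:seg])
        v += baseline_mV
        if noise_sd > 0:
            v = v + noise_sd * rng.standard_normal(n)
        traces.append(Trace(values=v, dt=dt, t0=t_start, signal_kind="voltage",
                            condition=raster.protocol,
                            meta={"trial": trial}))
    return traces


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study conditions for a two-genotype synthetic cohort.

    Jitter: multiplicative lognormal with the given CV on capacitance, leak
    and Kv7 conductance; additive Gaussian (SD in mV) on the spike-threshold
    parameter. Event-train rates define per-genotype synaptic drive onto the
    recorded cell class; suppression defines the gamma-suppression factor of
    the theta-train protocol.
    """

    n_per_group: int = 15
    jitter_cv: float = 0.02
    v_t_jitter_sd: float = 0.05  # mV
    exc_rate: dict = field(default_factory=lambda: {"WT": 10.0, "KO": 6.0})  # Hz
    inh_rate: dict = field(default_factory=lambda: {"WT": 5.0, "KO": 5.0})  # Hz
    suppression: dict = field(default_factory=lambda: {"WT": 0.3, "KO": 0.7})
    event_duration_s: float = 30.0
    n_theta_trials: int = 20
    ko_kv7_scale: float = 1.5


def jitter_params(base: MembraneParams, rng: np.random.Generator,
                  cv: float, v_t_sd: float) -> MembraneParams:
    """Per-cell parameter jitter: lognormal CV on C/g_leak/g_kv7_max,
    additive Gaussian on V_T."""
    if cv > 0:
        sig = math.sqrt(math.log(1.0 + cv**2))
        mul = lambda: float(rng.lognormal(-0.5 * sig**2, sig))
    else:
        mul = lambda: 1.0
    return replace(
        base,
        C=base.C * mul(),
        g_leak=base.g_leak * mul(),
        g_kv7_max=base.g_kv7_max * mul(),
        V_T=base.V_T + (v_t_sd * float(rng.standard_normal()) if v_t_sd > 0 else 0.0),
    )


def make_cohort(
    spec: CohortSpec | None = None,
    wt_params: MembraneParams | None = None,
    ko_params: MembraneParams | None = None,
    seed: int = 0,
) -> tuple[list[CellRecord], dict]:
    """Generate per-cell parameter sets for a WT vs KO cohort.

    Returns ``(cells, truth)`` where each CellRecord's ``meta['membrane']``
    holds its jittered MembraneParams and ``meta`` carries the cell's true
    synaptic rates and suppression factor. Traces are simulated lazily by
    the pipeline stages (each protocol derives its own child seed from the
    cohort seed and cell index), keeping cohort construction cheap and
    fully reproducible.
    """
    spec = spec or CohortSpec()
    if spec.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    wt = wt_params or MembraneParams()
    ko = ko_params or wt.ko(spec.ko_kv7_scale)
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    for genotype, base in (("WT", wt), ("KO", ko)):
        for j in range(spec.n_per_group):
            p = jitter_params(base, rng, spec.jitter_cv, spec.v_t_jitter_sd)
            p = replace(p, genotype=genotype)
            cell_id = f"{genotype}{j:03d}"
            rec = CellRecord(
                cell_id=cell_id, genotype=genotype, cell_type="MC",
                capacitance=p.C, rmp=p.E_leak,
                meta={
                    "membrane": p,
                    "exc_rate_Hz": spec.exc_rate[genotype],
                    "inh_rate_Hz": spec.inh_rate[genotype],
                    "suppression": spec.suppression[genotype],
                    "cell_seed": int(rng.integers(0, 2**31 - 1)),
                },
            )
            cells.append(rec)
    truth = {"spec": spec, "wt_params": wt, "ko_params": ko, "seed": seed}
    return cells, truth
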