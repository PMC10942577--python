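"""Compound-PSC decomposition into underlying EPSC and IPSC.

At an intermediate holding potential the stimulus-evoked compound PSC
(cPSC) is an initial downward (excitatory) component overlapped by a later
upward (inhibitory) component.  A pure-EPSC template (average of >= 20
uncontaminated EPSC sweeps recorded under GABA-A block) is scaled to each
sample of the cPSC 'approximating segment' — the early rising limb between
25% and 65% of the excitatory peak depth, no later than 2.5 ms after the
stimulus, where the inhibitory component has not yet engaged.  The scaled
templates are averaged into the underlying EPSC; the underlying IPSC is the
sample-wise remainder ``cPSC - underlying EPSC`` (so the subtraction
identity holds to machine precision).  E/I ratios are computed from the
component peaks or from charge transfer within 100 ms of the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import events as _events
from .core import AnalysisError, Trace

MIN_TEMPLATE_SWEEPS = 20
BASELINE_MS = 5.0  # pre-stimulus baseline window per sweep
TEMPLATE_FLOOR_FRAC = 0.05  # drop segment samples with |template| below this x peak
SEGMENT_LO = 0.25  # approximating segment: 25-65% of excitatory peak depth
SEGMENT_HI = 0.65
SEGMENT_CAP_MS = 2.5  # but not beyond 2.5 ms after stimulation
CONTAM_PRE_MS = 50.0  # pre-stimulus window screened by the event detector
CONTAM_SECONDARY_FRAC = 0.25  # secondary inward peak on the decay
CHARGE_WINDOW_MS = 100.0
NOISE_FLOOR_MULT = 3.0  # x baseline sd for departure/return detection


@dataclass
class EPSCTemplate:
    waveform: np.ndarray  # pA, baseline-subtracted, stimulus at t=0
    t: np.ndarray  # ms relative to stimulus
    dt: float
    n_events: int
    peak_pA: float  # signed minimum (inward)
    peak_time_ms: float
    n_excluded: int = 0


@dataclass
class DecompositionResult:
    t: np.ndarray  # ms relative to stimulus
    cpsc: np.ndarray  # mean baseline-subtracted cPSC
    epsc: np.ndarray  # underlying EPSC
    ipsc: np.ndarray  # underlying IPSC = cpsc - epsc
    cpsc_norm: np.ndarray  # / |underlying EPSC peak|
    ipsc_norm: np.ndarray
    scale_factors: np.ndarray
    excitation_window_ms: float
    ei_peak: float
    ei_charge: float
    n_sweeps: int
    flags: list = field(default_factory=list)

    @property
    def epsc_peak(self) -> float:
        return float(self.epsc.min())

    @property
    def ipsc_peak(self) -> float:
        return float(self.ipsc.max())


def blank_stimulus_artifact(trace: Trace, stim_ms: float,
                            blank_ms: float = 0.5) -> Trace:
    """Replace samples in [stim, stim+blank_ms) by the pre-stimulus value
    (stimulation artifacts are assumed pre-blanked; this utility covers
    inputs where they are not)."""
    v = trace.values.copy()
    i0 = trace.time_to_index(stim_ms)
    i1 = trace.time_to_index(stim_ms + blank_ms)
    v[i0:i1 + 1] = v[max(0, i0 - 1)]
    return trace.replace(values=v)


def _baseline_subtract(trace: Trace, stim_ms: float) -> np.ndarray:
    base = trace.slice_time(stim_ms - BASELINE_MS, stim_ms)
    if base.size == 0:
        raise AnalysisError("no pre-stimulus baseline available")
    return trace.values - float(np.mean(base))


def _is_contaminated(values: np.ndarray, trace: Trace, stim_ms: float) -> str | None:
    """Screen one baseline-subtracted sweep; returns a reason or None."""
    pre = trace.replace(values=values, signal_kind="current")
    ev = _events.detect_events(pre, polarity="inward",
                               threshold=_events.DEFAULT_THRESHOLD_PA)
    pre_hits = ev.times[(ev.times >= stim_ms - CONTAM_PRE_MS) & (ev.times < stim_ms)]
    if pre_hits.size:
        return "pre_stimulus_event"
    # secondary inward peak on the decay beyond 25% of the main peak
    i_stim = trace.time_to_index(stim_ms)
    post = values[i_stim:]
    if post.size < 5:
        return None
    i_peak = int(np.argmin(post))
    main = post[i_peak]  # < 0 for an inward EPSC
    decay = post[i_peak + 1:]
    if decay.size > 4 and main < 0:
        # a secondary inward event on the decay shows as a local minimum
        # that re-descends by more than 25% of the main peak from the
        # running maximum reached since the main peak
        interior = decay[1:-1]
        minima = np.flatnonzero((interior <= decay[:-2]) & (interior < decay[2:])) + 1
        if minima.size:
            run_max = np.maximum.accumulate(decay)
            redesc = run_max[minima] - decay[minima]
            if np.any(redesc > CONTAM_SECONDARY_FRAC * abs(main)):
                return "secondary_event_on_decay"
    return None


def build_epsc_template(sweeps: list[Trace], stim_ms: float = 0.0) -> EPSCTemplate:
    """Average >= 20 uncontaminated, baseline-subtracted EPSC sweeps.

    A sweep is contaminated when the event detector fires in the 50 ms
    before the stimulus or a secondary inward event rides on the decay;
    contaminated sweeps are excluded (and counted)."""
    clean, excluded = [], 0
    for tr in sweeps:
        vals = _baseline_subtract(tr, stim_ms)
        if _is_contaminated(vals, tr, stim_ms) is None:
            clean.append(vals)
        else:
            excluded += 1
    if len(clean) < MIN_TEMPLATE_SWEEPS:
        raise AnalysisError(
            f"insufficient template sweeps: {len(clean)} clean of "
            f"{len(sweeps)} (need >= {MIN_TEMPLATE_SWEEPS})")
    ref = sweeps[0]
    wave = np.mean(clean, axis=0)
    t = ref.times - stim_ms
    i_peak = int(np.argmin(np.where(t >= 0, wave, np.inf)))
    return EPSCTemplate(waveform=wave, t=t, dt=ref.dt, n_events=len(clean),
                        peak_pA=float(wave[i_peak]), peak_time_ms=float(t[i_peak]),
                        n_excluded=excluded)


def find_approximating_segment(cpsc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sample indices of the approximating segment of a mean cPSC.

    Samples on the rising (downward-going) limb whose depth is between 25%
    and 65% of the excitatory-component peak depth, intersected with
    (0, 2.5 ms] after the stimulus (t=0)."""
    post = t >= 0
    if not post.any() or np.min(cpsc[post]) >= 0:
        raise AnalysisError("approximating segment not found: no downward "
                            "excitatory component")
    idx_post = np.flatnonzero(post)
    i_peak = idx_post[int(np.argmin(cpsc[post]))]
    depth = cpsc / cpsc[i_peak]  # 1 at peak, ~0 at baseline (both negative)
    limb = np.arange(idx_post[0], i_peak + 1)
    sel = limb[(depth[limb] >= SEGMENT_LO) & (depth[limb] <= SEGMENT_HI)
               & (t[limb] > 0) & (t[limb] <= SEGMENT_CAP_MS)]
    if sel.size < 2:
        raise AnalysisError("approximating segment not found: fewer than 2 "
                            "qualifying samples")
    return sel


def excitation_window(cpsc: np.ndarray, t: np.ndarray,
                      baseline_sd: float | None = None) -> tuple[float, list]:
    """Full duration (ms) of the excitatory (downward) component.

    From the first downward departure beyond the noise floor after the
    stimulus to the first return crossing of baseline after the excitatory
    peak, linearly interpolated. Right-censored (flagged) when the trace
    never returns to baseline."""
    flags: list = []
    pre = cpsc[t < 0]
    if baseline_sd is None:
        baseline_sd = float(np.std(pre)) if pre.size else 0.0
    floor = max(NOISE_FLOOR_MULT * baseline_sd, 1e-12)
    post_idx = np.flatnonzero(t >= 0)
    y = cpsc[post_idx]
    tt = t[post_idx]
    below = y < -floor
    if not below.any():
        return math.nan, ["window_undefined"]
    i_dep = int(np.argmax(below))
    if i_dep == 0:
        t_start = float(tt[0])
    else:
        y0, y1 = y[i_dep - 1], y[i_dep]
        frac = (-floor - y0) / (y1 - y0)
        t_start = float(tt[i_dep - 1] + frac * (tt[i_dep] - tt[i_dep - 1]))
    i_peak = i_dep + int(np.argmin(y[i_dep:]))
    after = y[i_peak:]
    ret = np.flatnonzero(after >= 0.0)
    if ret.size == 0:
        flags.append("right_censored")
        return float(tt[-1] - t_start), flags
    j = i_peak + int(ret[0])
    if j == i_peak:
        t_end = float(tt[j])
    else:
        y0, y1 = y[j - 1], y[j]
        frac = (0.0 - y0) / (y1 - y0)
        t_end = float(tt[j - 1] + frac * (tt[j] - tt[j - 1]))
    return t_end - t_start, flags


def decompose_cpsc(
    sweeps: list[Trace],
    template: EPSCTemplate,
    stim_ms: float = 0.0,
    per_sweep: bool = False,
    charge_window_ms: float = CHARGE_WINDOW_MS,
) -> DecompositionResult:
    """Isolate the underlying EPSC and IPSC of a compound PSC.

    Default mode scales the template to the sweep-averaged cPSC (a
    per-sweep mode averages per-sweep decompositions instead; both agree on
    synthetic data). The template is scaled to each approximating-segment
    sample i by ``s_i = cPSC(t_i)/template(t_i)``; samples where
    ``|template|`` is below 5% of the template peak are dropped. The
    underlying EPSC is the average of the scaled templates, i.e.
    ``mean(s_i) * template``."""
    flags: list = []
    if not (MIN_TEMPLATE_SWEEPS <= len(sweeps) <= 25):
        flags.append(f"n_sweeps={len(sweeps)} outside recommended 20-25")
    mats = np.stack([_baseline_subtract(tr, stim_ms) for tr in sweeps])
    ref = sweeps[0]
    t = ref.times - stim_ms
    if template.waveform.size != t.size or abs(template.dt - ref.dt) > 1e-12:
        raise AnalysisError("template and sweeps must share dt and alignment")

    def one(cpsc_wave: np.ndarray):
        seg = find_approximating_segment(cpsc_wave, t)
        tw = template.waveform
        ok = np.abs(tw[seg]) >= TEMPLATE_FLOOR_FRAC * abs(template.peak_pA)
        seg = seg[ok]
        if seg.size == 0:
            raise AnalysisError("all approximating-segment samples below "
                                "template floor")
        s = cpsc_wave[seg] / tw[seg]
        epsc = float(np.mean(s)) * tw
        return s, epsc

    if per_sweep:
        all_s, all_epsc = [], []
        for row in mats:
            s, epsc = one(row)
            all_s.append(np.mean(s))
            all_epsc.append(epsc)
        cpsc_mean = mats.mean(axis=0)
        epsc = np.mean(all_epsc, axis=0)
        scale = np.asarray(all_s)
    else:
        cpsc_mean = mats.mean(axis=0)
        scale, epsc = one(cpsc_mean)

    ipsc = cpsc_mean - epsc
    epsc_peak = float(epsc.min())
    if epsc_peak == 0:
        raise AnalysisError("degenerate underlying EPSC (zero peak)")
    win, wflags = excitation_window(cpsc_mean, t)
    flags += wflags

    sel = (t >= 0) & (t <= charge_window_ms)
    q_e = abs(np.trapezoid(epsc[sel], dx=ref.dt))
    q_i = abs(np.trapezoid(ipsc[sel], dx=ref.dt))
    ipsc_peak = float(ipsc.max())
    pre = cpsc_mean[t < 0]
    noise_sd = float(np.std(pre)) if pre.size else 0.0
    if ipsc_peak <= NOISE_FLOOR_MULT * noise_sd:
        flags.append("ei_unbounded")
    ei_peak = abs(epsc_peak) / ipsc_peak if ipsc_peak > 0 else math.inf
    ei_charge = q_e / q_i if q_i > 0 else math.inf

    return DecompositionResult(
        t=t, cpsc=cpsc_mean, epsc=epsc, ipsc=ipsc,
        cpsc_norm=cpsc_mean / abs(epsc_peak), ipsc_norm=ipsc / abs(epsc_peak),
        scale_factors=scale, excitation_window_ms=win,
        ei_peak=float(ei_peak), ei_charge=float(ei_charge),
        n_sweeps=len(sweeps), flags=flags,
    )


def ei_from_decomposition(result: DecompositionResult) -> dict[str, float]:
    """E/I by peak amplitudes and by 100 ms charge transfer."""
    return {"peak": result.ei_peak, "charge": result.ei_charge}
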