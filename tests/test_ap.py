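"""AP detection, threshold, rheobase, waveform features, passive props."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dentephys import ap, synth
from dentephys.core import ProtocolError, ProtocolSpec, Trace

from conftest import MC_RAMP, RAMP_MS


def triangle_ap(dt=0.02, v_th=-45.0, peak=35.0, rise_ms=1.0, fall_ms=2.0,
                base_ms=20.0):
    """Idealized triangular AP riding on a flat baseline at v_th."""
    n_base = int(base_ms / dt)
    up = np.linspace(v_th, peak, int(rise_ms / dt) + 1)
    down = np.linspace(peak, v_th, int(fall_ms / dt) + 1)[1:]
    v = np.concatenate([np.full(n_base, v_th), up, down, np.full(n_base, v_th)])
    return Trace(values=v, dt=dt)


class TestDetectAps:
    def test_flat_trace_has_no_aps(self):
        tr = Trace(values=np.full(10_000, -65.0), dt=0.02)
        assert ap.detect_aps(tr) == []

    def test_counts_match_simulation_truth(self, wt_ramp_trace):
        tr, truth = wt_ramp_trace
        assert len(ap.detect_aps(tr)) == len(truth.spike_times)

    def test_subthreshold_excursion_not_counted(self):
        """Crossing -20 mV with a peak below -10 mV is not an AP."""
        tr = triangle_ap(peak=-12.0)
        assert ap.detect_aps(tr) == []

    def test_two_peaks_within_refractory_merge(self):
        dt = 0.02
        base = np.full(1000, -65.0)
        spike = np.concatenate([np.linspace(-65, 10, 25),
                                np.linspace(10, -25, 20)[1:]])
        gap = np.full(int(1.0 / dt), -25.0)  # stays above -20: one excursion
        v = np.concatenate([base, spike, gap, spike + 5, base])
        tr = Trace(values=v, dt=dt)
        assert len(ap.detect_aps(tr)) == 1

    def test_current_trace_rejected(self):
        tr = Trace(values=np.zeros(100), dt=0.02, signal_kind="current")
        with pytest.raises(ProtocolError):
            ap.detect_aps(tr)


class TestThreshold:
    def test_concordant_with_dvdt_criterion_on_simulated_aps(self, wt_ramp_trace):
        """Third-derivative threshold within 3 mV of the independent
        dV/dt = 20 mV/ms oracle on every AP of a noise-free ramp train."""
        tr, _ = wt_ramp_trace
        for w in ap.detect_aps(tr):
            v = tr.values[w.start:w.stop]
            dv = np.gradient(v, tr.dt)
            rel = w.peak_index - w.start
            k = np.flatnonzero(dv[: rel + 1] >= 20.0)
            v_th, t_th = ap.ap_threshold(tr, w)
            assert not math.isnan(v_th)
            assert abs(v_th - v[k[0]]) <= 3.0
            assert t_th < tr.t0 + w.peak_index * tr.dt  # threshold precedes peak

    def test_constructed_slope_break_located(self):
        """A C1-smoothed junction between a 1 mV/ms and a 20 mV/ms segment
        is found within 0.5 ms of the true break point."""
        dt = 0.02
        t = np.arange(0, 100.0, dt)
        t_star = 50.0
        blend = 1.0 / (1.0 + np.exp(-(t - t_star) / 0.1))  # ~0.5 ms switch
        rolloff = 1.0 / (1.0 + np.exp((t - 90.0) / 2.0))  # smooth flat-topping
        slope = (1.0 + 19.0 * blend) * rolloff
        v = -70.0 + np.cumsum(slope) * dt
        tr = Trace(values=v, dt=dt)
        w = ap.APWindow(start=int(40.0 / dt), stop=v.size,
                        peak_index=int(np.argmax(v)))
        _, t_th = ap.ap_threshold(tr, w)
        assert abs(t_th - t_star) <= 0.5

    def test_sine_wave_has_no_qualifying_peak(self):
        dt = 0.02
        t = np.arange(0, 40.0, dt)
        v = -40.0 + 35.0 * np.sin(2 * np.pi * t / 40.0)  # smooth, no kink
        tr = Trace(values=v, dt=dt)
        w = ap.APWindow(start=0, stop=v.size, peak_index=int(np.argmax(v)))
        v_th, t_th = ap.ap_threshold(tr, w)
        assert math.isnan(v_th) and math.isnan(t_th)


class TestRheobase:
    def test_linear_ramp_closed_form(self):
        """0.15 pA/ms from 0 pA with threshold at 1000 ms: rheobase 150 pA,
        charge 0.5*150 pA*1 s = 75 pC, exactly."""
        proto = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=0.0)
        tr = Trace(values=np.zeros(10), dt=0.02)
        rb, q = ap.rheobase_and_charge(tr, proto, t_th=1000.0)
        assert rb == pytest.approx(150.0, rel=1e-9)
        assert q == pytest.approx(75.0, rel=1e-9)

    def test_threshold_at_onset_gives_zero(self):
        proto = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=100.0)
        tr = Trace(values=np.zeros(10), dt=0.02)
        rb, q = ap.rheobase_and_charge(tr, proto, t_th=100.0)
        assert rb == 0.0 and q == 0.0

    def test_hyperpolarizing_onset_excluded_from_charge(self):
        """With a -50 pA onset, integration starts at the depolarizing
        zero-crossing; checked against a dense trapezoid oracle."""
        proto = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=0.0,
                             ramp_pre_offset=-50.0)
        t_zero = 50.0 / 0.15
        t_th = t_zero + 800.0
        tr = Trace(values=np.zeros(10), dt=0.02)
        rb, q = ap.rheobase_and_charge(tr, proto, t_th=t_th)
        tt = np.linspace(t_zero, t_th, 2_000_001)
        oracle = np.trapezoid(proto.injected_current(tt), tt) / 1000.0
        assert rb == pytest.approx(-50.0 + 0.15 * t_th, rel=1e-12)
        assert q == pytest.approx(oracle, rel=1e-9)

    def test_threshold_before_onset_is_protocol_error(self):
        proto = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=100.0)
        tr = Trace(values=np.zeros(10), dt=0.02)
        with pytest.raises(ProtocolError):
            ap.rheobase_and_charge(tr, proto, t_th=50.0)

    def test_charge_monotone_in_threshold_time(self):
        proto = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=0.0)
        tr = Trace(values=np.zeros(10), dt=0.02)
        charges = [ap.rheobase_and_charge(tr, proto, t)[1]
                   for t in (100.0, 400.0, 900.0, 1500.0)]
        assert np.all(np.diff(charges) > 0)


class TestWaveformFeatures:
    def test_triangle_geometry(self):
        """Linear upstroke over 1 ms: rise time 0.8 ms (10-90%), max rise
        rate = amplitude/1 ms = 80 mV/ms; symmetric -10 mV crossings give
        the expected duration."""
        tr = triangle_ap(v_th=-45.0, peak=35.0, rise_ms=1.0, fall_ms=2.0)
        w = ap.detect_aps(tr)[0]
        f = ap.ap_waveform_features(tr, w, v_th=-45.0,
                                    t_th=20.0)
        assert f.amplitude_mV == pytest.approx(80.0, abs=0.1)
        assert f.rise_time_ms == pytest.approx(0.8, abs=0.05)
        assert f.max_rise_rate_mV_per_ms == pytest.approx(80.0, rel=0.05)
        # -10 mV is 35/80 of the way down from peak on each limb
        up_t = (35.0 - (-10.0)) / 80.0 * 1.0
        down_t = (35.0 - (-10.0)) / 80.0 * 2.0
        assert f.duration_ms == pytest.approx(up_t + down_t, abs=0.05)

    def test_features_converge_with_finer_sampling(self, wt_params):
        """Each waveform feature changes by <2% when the trace is emitted
        at 4x finer sampling."""
        coarse, _ = synth.simulate_membrane(wt_params, MC_RAMP,
                                            dt_out=0.02, duration_ms=RAMP_MS)
        fine, _ = synth.simulate_membrane(wt_params, MC_RAMP,
                                          dt_out=0.005, duration_ms=RAMP_MS)
        fc = ap.ap_waveform_features(coarse, ap.detect_aps(coarse)[0])
        ff = ap.ap_waveform_features(fine, ap.detect_aps(fine)[0])
        for name in ("peak_mV", "amplitude_mV", "max_rise_rate_mV_per_ms",
                     "rise_time_ms", "fall_time_ms", "duration_ms"):
            a, b = getattr(fc, name), getattr(ff, name)
            assert abs(a - b) / abs(b) < 0.02, name

    def test_low_peak_has_undefined_duration(self):
        tr = triangle_ap(peak=-10.5)
        # force a window despite no detection
        w = ap.APWindow(start=0, stop=tr.n, peak_index=int(np.argmax(tr.values)))
        f = ap.ap_waveform_features(tr, w, v_th=-45.0, t_th=10.0)
        assert math.isnan(f.duration_ms)
        assert "duration_undefined" in f.flags

    def test_time_axis_shift_invariance(self, wt_ramp_trace):
        tr, _ = wt_ramp_trace
        shifted = tr.replace(t0=tr.t0 + 123.0)
        f0 = ap.ap_waveform_features(tr, ap.detect_aps(tr)[0])
        f1 = ap.ap_waveform_features(shifted, ap.detect_aps(shifted)[0])
        assert f1.threshold_time_ms - f0.threshold_time_ms == pytest.approx(123.0)
        assert f1.amplitude_mV == pytest.approx(f0.amplitude_mV)
        assert f1.duration_ms == pytest.approx(f0.duration_ms)


class TestExcitabilityCurve:
    def test_silent_traces_give_zero_counts(self):
        traces = [Trace(values=np.full(5000, v), dt=0.02,
                        meta={"set_potential_mV": v}) for v in (-64.0, -60.0)]
        curve = ap.excitability_curve(traces)
        assert curve == {-64.0: 0.0, -60.0: 0.0}

    def test_trial_averaging(self):
        spike = np.concatenate([np.linspace(-65, 20, 30),
                                np.linspace(20, -65, 30)[1:]])

        def trace_with(n_spikes):
            parts = [np.full(2000, -65.0)]
            for _ in range(n_spikes):
                parts += [spike, np.full(1000, -65.0)]
            return Trace(values=np.concatenate(parts), dt=0.02,
                         meta={"set_potential_mV": -60.0})

        traces = [trace_with(n) for n in (3, 4, 5, 4)]
        assert ap.excitability_curve(traces) == {-60.0: 4.0}

    def test_counts_increase_with_set_potential(self, wt_params):
        """Spontaneous AP counts rise with the set potential on the noisy
        synthetic membrane (truth spike counts, 3 levels, short traces)."""
        counts = []
        for v_set in (-64.0, -58.0, -55.0):
            _, truth = synth.simulate_set_potential(wt_params, v_set,
                                                    duration_ms=4000.0, seed=3)
            counts.append(len(truth.spike_times))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]


class TestPassiveProps:
    STEP = ProtocolSpec(kind="step", step_amplitude=-60.0, step_onset=200.0,
                        step_duration=500.0)

    def _step_trace(self, dv, step=STEP, baseline=-65.0):
        dt = 0.1
        n = int(900.0 / dt)
        t = dt * np.arange(n)
        v = np.full(n, baseline)
        on = (t >= step.step_onset) & (t < step.step_onset + step.step_duration)
        v[on] += dv
        return Trace(values=v, dt=dt)

    def test_ohms_law_negative_step(self):
        tr = self._step_trace(-6.0)
        pp = ap.passive_props(tr, self.STEP)
        assert pp.r_in_MOhm == pytest.approx(100.0)
        assert pp.rmp_mV == pytest.approx(-65.0)

    def test_ohms_law_positive_step(self):
        step = ProtocolSpec(kind="step", step_amplitude=60.0, step_onset=200.0,
                            step_duration=500.0)
        tr = self._step_trace(3.0, step=step, baseline=-45.0)
        pp = ap.passive_props(tr, step)
        assert pp.r_in_MOhm == pytest.approx(50.0)
        assert pp.measurement_potential_mV == pytest.approx(-45.0)

    def test_short_step_rejected(self):
        step = ProtocolSpec(kind="step", step_amplitude=-60.0, step_onset=200.0,
                            step_duration=200.0)
        tr = self._step_trace(-6.0)
        with pytest.raises(ProtocolError):
            ap.passive_props(tr, step)

    def test_rc_cell_recovered_under_noise(self):
        """R = 150 MOhm, tau = 15 ms, 0.2 mV noise: recovered within 5%."""
        rng = np.random.default_rng(0)
        dt = 0.1
        t = dt * np.arange(int(900.0 / dt))
        on = self.STEP.step_onset
        dv_inf = -60.0 * 150.0 / 1000.0  # pA * MOhm -> mV
        v = np.full(t.size, -65.0)
        rise = t >= on
        u = t[rise] - on
        v[rise] += dv_inf * (1 - np.exp(-u / 15.0))
        off = t >= on + self.STEP.step_duration
        u2 = t[off] - (on + self.STEP.step_duration)
        v[off] = -65.0 + dv_inf * np.exp(-u2 / 15.0)
        v += 0.2 * rng.standard_normal(t.size)
        pp = ap.passive_props(Trace(values=v, dt=dt), self.STEP)
        assert pp.r_in_MOhm == pytest.approx(150.0, rel=0.05)


class TestFiringPattern:
    @staticmethod
    def _train(isis_ms, dt=0.05):
        spike = np.concatenate([np.linspace(-65, 20, int(0.5 / dt)),
                                np.linspace(20, -65, int(0.5 / dt))[1:]])
        parts = [np.full(int(20.0 / dt), -65.0), spike]
        for isi in isis_ms:
            gap = np.full(max(1, int(isi / dt) - spike.size), -65.0)
            parts += [gap, spike]
        parts.append(np.full(int(20.0 / dt), -65.0))
        return Trace(values=np.concatenate(parts), dt=dt)

    def test_fast_spiking_rule(self):
        label = ap.classify_firing_pattern(self._train([10.0] * 59))
        assert label.label == "fast_spiking"
        assert label.max_rate_Hz == pytest.approx(100.0, rel=0.02)
        assert label.isi_cv == pytest.approx(0.0, abs=0.02)

    def test_regular_spiking_rule(self):
        label = ap.classify_firing_pattern(self._train([20, 24, 29, 35, 42]))
        assert label.label == "regular_spiking"
        assert label.adaptation_index == pytest.approx(2.1, rel=0.05)
        assert label.isi_cv < 0.5

    def test_stuttering_from_bursts(self):
        """Bursts of 5 spikes at 100 Hz separated by 100 ms gaps: ISI CV
        computed by brute force exceeds 0.5 -> stuttering-like."""
        isis = ([10.0] * 4 + [100.0]) * 3 + [10.0] * 4
        cv_oracle = np.std(isis) / np.mean(isis)
        assert cv_oracle > 0.5
        label = ap.classify_firing_pattern(self._train(isis))
        assert label.label == "stuttering_like"

    def test_too_few_aps_undetermined(self):
        label = ap.classify_firing_pattern(self._train([10.0]))
        assert label.label == "undetermined"
        assert math.isnan(label.isi_cv)


class TestGenotypeContrast:
    def test_ko_direction_on_matched_cells(self, wt_ramp_trace, ko_ramp_trace):
        """KO (1.5x Kv7): fewer ramp APs, higher threshold, rheobase and
        charge; waveform kinetics within 5% of WT."""
        (tw, _), (tk, _) = wt_ramp_trace, ko_ramp_trace
        fw = ap.extract_features(tw, MC_RAMP)
        fk = ap.extract_features(tk, MC_RAMP)
        assert fk.ap_count < fw.ap_count
        assert fk.rheobase_pA > fw.rheobase_pA
        assert fk.rheobase_charge_pC > fw.rheobase_charge_pC
        assert fk.per_ap[0].threshold_mV > fw.per_ap[0].threshold_mV
        rise_ratio = (fk.per_ap[0].max_rise_rate_mV_per_ms
                      / fw.per_ap[0].max_rise_rate_mV_per_ms)
        dur_ratio = fk.per_ap[0].duration_ms / fw.per_ap[0].duration_ms
        assert abs(rise_ratio - 1.0) < 0.05
        assert abs(dur_ratio - 1.0) < 0.05
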