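"""Synthetic-recording generators: closed forms, determinism, truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dentephys import synth
from dentephys.core import ProtocolSpec

from conftest import MC_RAMP, RAMP_MS


class TestMembrane:
    def test_rc_steady_state_without_kv7(self):
        """Below rheobase with the Kv7 conductance off, the step response
        settles at the RC closed form E_leak + I/g_leak."""
        p = replace(synth.MembraneParams(), g_kv7_max=1e-12)
        step = ProtocolSpec(kind="step", step_amplitude=60.0,
                            step_onset=200.0, step_duration=500.0)
        tr, _ = synth.simulate_membrane(p, step)
        vss = tr.slice_time(600.0, 700.0).mean()
        expect = p.E_leak + 60.0 / p.g_leak
        assert abs(vss - expect) / abs(expect) < 1e-3

    def test_noise_free_traces_are_seed_independent(self, wt_params, ramp_protocol):
        tr1, _ = synth.simulate_membrane(wt_params, ramp_protocol, seed=1,
                                         duration_ms=500.0)
        tr2, _ = synth.simulate_membrane(wt_params, ramp_protocol, seed=2,
                                         duration_ms=500.0)
        np.testing.assert_array_equal(tr1.values, tr2.values)

    def test_noisy_traces_reproducible_by_seed(self, wt_params, ramp_protocol):
        p = replace(wt_params, noise_sigma=20.0)
        tr1, _ = synth.simulate_membrane(p, ramp_protocol, seed=5, duration_ms=300.0)
        tr2, _ = synth.simulate_membrane(p, ramp_protocol, seed=5, duration_ms=300.0)
        tr3, _ = synth.simulate_membrane(p, ramp_protocol, seed=6, duration_ms=300.0)
        np.testing.assert_array_equal(tr1.values, tr2.values)
        assert not np.array_equal(tr1.values, tr3.values)

    def test_enhanced_kv7_reduces_ramp_spike_count(self, wt_params):
        """Raising the Kv7 conductance never increases the spike count:
        checked pairwise over a batch of noisy seeds (majority direction)
        and strictly on the noise-free trace."""
        ko = wt_params.ko()
        _, t_wt = synth.simulate_membrane(wt_params, MC_RAMP, duration_ms=RAMP_MS)
        _, t_ko = synth.simulate_membrane(ko, MC_RAMP, duration_ms=RAMP_MS)
        assert len(t_ko.spike_times) < len(t_wt.spike_times)
        wins = 0
        for seed in range(20):
            pw = replace(wt_params, noise_sigma=15.0)
            pk = replace(ko, noise_sigma=15.0)
            _, tw = synth.simulate_membrane(pw, MC_RAMP, seed=seed, duration_ms=RAMP_MS)
            _, tk = synth.simulate_membrane(pk, MC_RAMP, seed=seed, duration_ms=RAMP_MS)
            wins += len(tk.spike_times) <= len(tw.spike_times)
        assert wins >= 15  # majority over the 20-seed batch

    def test_ko_profile_differs_only_by_kv7_scale(self, wt_params):
        ko = wt_params.ko(1.5)
        assert ko.g_kv7_max == pytest.approx(1.5 * wt_params.g_kv7_max)
        for f in ("C", "g_leak", "E_leak", "V_T", "delta_T"):
            assert getattr(ko, f) == getattr(wt_params, f)
        with pytest.raises(ValueError):
            wt_params.ko(0.5)

    def test_integration_instability_detected(self):
        step = ProtocolSpec(kind="step", step_amplitude=5e5,
                            step_onset=10.0, step_duration=100.0)
        from dentephys.core import AnalysisError

        with pytest.raises(AnalysisError):
            synth.simulate_membrane(synth.MembraneParams(), step)


class TestVoltageClampRamp:
    RAMP = ProtocolSpec(kind="ramp", ramp_rate=0.02, ramp_onset=0.0,
                        ramp_start=-95.0, ramp_stop=5.0)

    def test_blocked_current_is_pure_leak(self, wt_params):
        tr, vcmd = synth.simulate_vc_ramp(wt_params, self.RAMP, kv7_blocked=True)
        expect = wt_params.g_leak * (vcmd.values - wt_params.E_leak)
        np.testing.assert_allclose(tr.values, expect, rtol=0, atol=1e-9)

    def test_kv7_component_tracks_boltzmann_steady_state(self):
        """On the slow ramp the gated current stays within 5% (of curve
        amplitude) of g*a_inf(V)*(V-E_K)."""
        p = synth.MembraneParams(g_kv7_max=2.0)
        on, _ = synth.simulate_vc_ramp(p, self.RAMP, kv7_blocked=False)
        off, vcmd = synth.simulate_vc_ramp(p, self.RAMP, kv7_blocked=True)
        kv7 = on.values - off.values
        closed = p.kv7_current(vcmd.values)
        assert np.max(np.abs(kv7 - closed)) <= 0.05 * closed.max()

    def test_instantaneous_gate_has_no_hysteresis(self):
        p = replace(synth.MembraneParams(), tau_kv7=1e-9)
        fwd, vf = synth.simulate_vc_ramp(p, self.RAMP)
        rev_proto = ProtocolSpec(kind="ramp", ramp_rate=-0.02, ramp_onset=0.0,
                                 ramp_start=5.0, ramp_stop=-95.0)
        rev, vr = synth.simulate_vc_ramp(p, rev_proto)
        # same I-V relation sample-by-sample after sorting by command voltage
        iv_f = np.interp(vr.values, vf.values, fwd.values)
        np.testing.assert_allclose(np.sort(rev.values), np.sort(iv_f), atol=1e-6)


class TestEventTrain:
    def test_zero_rate_gives_pure_noise_and_empty_truth(self):
        p = synth.EventTrainParams(rate=0.0, duration=5.0, noise_sd=2.0, seed=0)
        tr, truth = synth.generate_event_train(p)
        assert truth.event_times.size == 0
        assert abs(np.std(tr.values) - 2.0) < 0.1

    def test_poisson_mean_count(self):
        """Mean event count over 200 seeds within 3 SE of rate*duration."""
        counts = [synth.generate_event_train(
            synth.EventTrainParams(rate=10.0, duration=30.0, noise_sd=0.0,
                                   seed=s))[1].event_times.size
                  for s in range(200)]
        se = math.sqrt(300.0 / 200)
        assert abs(np.mean(counts) - 300.0) <= 3 * se

    def test_unit_peak_kernel_amplitude_exact(self):
        """A single noise-free event of -50 pA produces a trace minimum of
        exactly -50 pA (kernel normalized to unit peak on the grid)."""
        for seed in range(40):
            p = synth.EventTrainParams(rate=0.3, duration=2.0, noise_sd=0.0,
                                       amp_mu=math.log(50.0), amp_sigma=0.0,
                                       seed=seed)
            tr, truth = synth.generate_event_train(p)
            if truth.event_times.size == 1:
                assert tr.values.min() == pytest.approx(-50.0, rel=1e-3)
                break
        else:
            pytest.fail("no single-event realization found")

    def test_amp_min_clips_magnitudes(self):
        p = synth.EventTrainParams(rate=20.0, duration=10.0, amp_min=10.0,
                                   noise_sd=0.0, seed=2)
        _, truth = synth.generate_event_train(p)
        assert np.all(np.abs(truth.event_amps) >= 10.0)


class TestComposeCpsc:
    def test_zero_ipsc_gives_pure_scaled_epsc(self):
        sweeps, _, truth = synth.compose_cpsc(ipsc_peak=0.0, noise_sd=0.0,
                                              n_sweeps=5)
        unit = truth.components["epsc_unit"]
        for tr, amp in zip(sweeps, truth.extras["epsc_amps"]):
            np.testing.assert_allclose(tr.values, amp * unit, atol=1e-12)

    def test_truth_components_sum_to_noise_free_sweep(self):
        sweeps, _, truth = synth.compose_cpsc(noise_sd=0.0, n_sweeps=3)
        recon = (truth.extras["epsc_amps"][0] * truth.components["epsc_unit"]
                 + truth.extras["ipsc_amps"][0] * truth.components["ipsc_unit"])
        np.testing.assert_allclose(sweeps[0].values, recon, atol=1e-12)

    def test_sweep_mean_tracks_truth_mean_under_jitter(self):
        sweeps, _, truth = synth.compose_cpsc(amp_jitter_cv=0.10, noise_sd=0.0,
                                              n_sweeps=25, seed=4)
        mean_sweep = np.mean([tr.values for tr in sweeps], axis=0)
        mean_truth = (truth.components["epsc_mean"] + truth.components["ipsc_mean"])
        scale = np.abs(mean_truth).max()
        assert np.max(np.abs(mean_sweep - mean_truth)) <= 0.03 * scale

    def test_invalid_latency_order_rejected(self):
        with pytest.raises(ValueError):
            synth.compose_cpsc(epsc_latency=4.0, ipsc_latency=2.0)


class TestThetaGamma:
    def test_no_suppression_means_control_probabilities(self):
        r, _ = synth.simulate_theta_gamma(p_base=0.5, suppression=1.0,
                                          n_trials=5, seed=0)
        np.testing.assert_allclose(r.p_true, 0.5)

    def test_full_suppression_without_recovery_silences_train(self):
        r, _ = synth.simulate_theta_gamma(p_base=0.5, suppression=0.0,
                                          n_trials=50, seed=0,
                                          recovery_tau_ms=math.inf)
        assert not r.spikes.any()

    def test_first_second_probability_matches_bernoulli_product(self):
        """p_base=0.5, s=0.4: empirical first-second probability within 3
        binomial SE of 0.2 over 200 trials."""
        r, _ = synth.simulate_theta_gamma(p_base=0.5, suppression=0.4,
                                          n_trials=200, seed=7)
        first_bin = r.spikes[:, :5]
        phat = first_bin.mean()
        se = math.sqrt(0.2 * 0.8 / first_bin.size)
        assert abs(phat - 0.2) <= 3 * se

    def test_raster_shapes_and_protocols(self):
        r, _ = synth.simulate_theta_gamma(n_trials=3, with_gamma=True, seed=1)
        assert r.spikes.shape == (3, 15)
        assert r.gamma_times.size == 5
        assert r.protocol == "test"
        rc, _ = synth.simulate_theta_gamma(n_trials=3, with_gamma=False, seed=1)
        assert rc.gamma_times.size == 0


class TestCohort:
    def test_zero_jitter_reproduces_group_parameters(self, wt_params):
        spec = synth.CohortSpec(n_per_group=1, jitter_cv=0.0, v_t_jitter_sd=0.0)
        cells, truth = synth.make_cohort(spec, seed=0)
        assert len(cells) == 2
        wt_cell = [c for c in cells if c.genotype == "WT"][0]
        p = wt_cell.meta["membrane"]
        assert p.C == wt_params.C and p.g_kv7_max == wt_params.g_kv7_max

    def test_same_seed_same_cohort(self):
        spec = synth.CohortSpec(n_per_group=4)
        a, _ = synth.make_cohort(spec, seed=3)
        b, _ = synth.make_cohort(spec, seed=3)
        for ca, cb in zip(a, b):
            assert ca.meta["membrane"] == cb.meta["membrane"]
            assert ca.meta["cell_seed"] == cb.meta["cell_seed"]

    def test_capacitance_jitter_cv_recovered(self):
        """Requested 10% CV on capacitance lands in [5%, 15%] at n=50."""
        spec = synth.CohortSpec(n_per_group=50, jitter_cv=0.10)
        cells, _ = synth.make_cohort(spec, seed=1)
        caps = np.array([c.capacitance for c in cells if c.genotype == "WT"])
        cv = caps.std() / caps.mean()
        assert 0.05 <= cv <= 0.15
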