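# Methods

This note documents the models, estimators and numerical choices behind
`dentephys`, and what the synthetic-data verification does and does not
establish about real recordings.

## The synthetic membrane

Current-clamp traces come from a single-compartment conductance model
chosen as the smallest one that yields (i) exponential-integrate-and-fire
(EIF) threshold dynamics, (ii) complete AP waveforms with a peak and a
downstroke — without which duration, fall time and peak potential would be
undefined — and (iii) repetitive firing under slow ramps:

```
C dV/dt = −g_L (V−E_L) − g_Na m∞(V)³ h h_s (V−E_Na) − g_Kd n (V−E_K)
          − g_kv7 a (V−E_K) + I_inj + I_noise
```

* **Na⁺ drive.** Activation is instantaneous, `m∞ = 1/(1+exp((V_m½−V)/k_m))`
  with `k_m = 3·ΔT`, so the foot of `m∞³` is exponential in V with slope
  ΔT (default 2 mV) — i.e. EIF behaviour near threshold. `V_m½` is chosen
  so the foot current equals the EIF spike term `g_L·ΔT·exp((V−V_T)/ΔT)`
  at `V = V_T` (default −45 mV). Fast inactivation `h` (midpoint −25 mV,
  τ = 1.5 ms) terminates the spike drive; a **slow inactivation** gate
  `h_s` (midpoint −44 mV, k = 2.5 mV, τ = 120 ms, floored at 0.25)
  implements cumulative Na-channel inactivation: cells that approach
  threshold more slowly arrive with less available Na⁺ and therefore fire
  from a higher voltage. This accommodation is the physiological route by
  which a subthreshold K⁺ shunt raises the *measured* AP threshold — in a
  pure EIF the third-derivative threshold is insensitive to added shunt
  because all escape trajectories collapse onto the same fast manifold
  (we verified this numerically: the shift is < 0.01 mV without `h_s`).
* **Repolarization.** A single fast-rectifier gate `n` (midpoint −5 mV,
  k = 4 mV, τ = 0.8 ms) is active only during the spike.
* **Kv7/M conductance.** First-order gate `a` with Boltzmann steady state
  (V½ = −40 mV, k = 8 mV), τ = 50 ms, E_K = −90 mV; maximal conductance
  1.5 nS for the wildtype profile. The knockout profile differs from the
  wildtype **only** by scaling `g_kv7_max` (default ×1.5) — enhanced Kv7
  function is the generator's entire mechanistic ground truth for the
  genotype contrast.
* **Passive defaults.** C = 150 pF, g_L = 6.7 nS (≈150 MΩ), E_L = −65 mV:
  mossy-cell-like values. The spike-shaping constants (g_Na = 1200 nS,
  g_Kd = 500 nS) were set for realistic AP metrics — threshold ≈ −30 mV,
  peak ≈ +26 mV, maximum rise rate ≈ 210 mV/ms, duration at −10 mV
  ≈ 1.1 ms — and are knobs, not claims.
* **Noise and integration.** Ornstein–Uhlenbeck current noise (stationary
  sd `noise_sigma`, τ = 2 ms), pre-generated and seeded. Exponential-Euler
  integration at a fixed 0.005 ms internal step (stable for all gate time
  constants), subsampled to the 0.02 ms output interval (50 kHz).
  Voltage-clamp ramps integrate only the Kv7 gate (first-order exact
  recursion) since the command voltage removes membrane dynamics.

Protocols mirror the experimental ones: 2 s depolarizing ramps at
0.15 pA/ms with a −50 pA hyperpolarizing onset; −60/+60 pA 500 ms steps for
input resistance; set-potential recordings with synaptic-like noise
(σ = 150 pA, τ = 5 ms — membrane filtering leaves a few mV of voltage
noise, enough for occasional spikes between −64 and −55 mV); −95→+5 mV
voltage ramps at 0.02 mV/ms.

## Other generators

* **PSC trains.** Homogeneous Poisson times snapped to the sample grid;
  biexponential kernels (τ_rise 0.5 ms, τ_decay 5 ms) normalized to unit
  peak *on the grid* so truth amplitudes are exact extrema; lognormal
  amplitude magnitudes (median 30 pA, σ_log 0.4, optional lower clip);
  additive Gaussian noise (2 pA default).
* **Compound PSCs.** Each sweep is EPSC kernel + IPSC kernel + noise with
  stimulus at t = 0 (defaults: EPSC −120 pA at 2 ms latency, τ 0.5/5 ms;
  IPSC +80 pA at 4 ms, τ 1/12 ms — disynaptic inhibition arrives later),
  with optional lognormal sweep-to-sweep amplitude jitter, plus EPSC-only
  sweeps for template building.
* **Theta–gamma rasters.** Per theta stimulus, a spike is Bernoulli(p);
  the control train uses `p_base`, the test train
  `p_base·(s + (1−s)(1−e^{−t/τ_rec}))` with suppression factor `s`. The
  default recovery time constant is infinite — suppression is sustained
  across the 3 s train — which makes the first-bin truth exactly
  `p_base·s` and the recovery-free parameter recovery clean; finite
  recovery is a knob. Real recordings show partial recovery across the
  train, so analyses of recovery kinetics need the knob, not the default.
  Rasters can be rendered as membrane-potential traces (EPSP kernels plus
  stereotyped AP waveforms) to exercise the AP-detection route.
* **Cohorts.** Per-cell lognormal jitter with CV 2 % on capacitance, leak
  and Kv7 conductance and 0.05 mV additive spread on `V_T`; per-genotype
  synaptic rates (excitatory 10 vs 6 Hz over a common 5 Hz inhibitory
  rate) and gamma-suppression factors (0.3 vs 0.7). These defaults are
  deliberately *tighter* than biological variability (real between-cell
  threshold SD is 1–2 mV, capacitance CV ≈ 20–30 %): the cohort is a
  verification instrument, sized so that the sub-millivolt threshold
  effect a ×1.5 Kv7 scaling produces is statistically resolvable at
  n = 15 cells/group. Passing the cohort tests therefore demonstrates
  that the *analysis chain* recovers the generator's ground truth with
  correct directions and calibrated tests — not that effects of this size
  would be detectable at n = 15 in real tissue.

## Estimator details

* **AP threshold.** The window (5 ms before to 10 ms after the peak) is
  Savitzky–Golay smoothed (0.5 ms window, order 3); the third difference
  ÷ dt³ is scanned forward for the first local maximum that precedes the
  peak and exceeds both 5× the robust (MAD-based) noise floor of the
  early window and 5 % of the window's pre-peak d³ maximum. The second
  floor matters: without it, sub-percent numerical shoulders at the AP
  foot masquerade as the "first peak". The located maximum is refined to
  sub-sample precision with a parabolic fit, which removes the ~0.5 mV
  quantization a 0.02 ms grid otherwise imposes on the steep upstroke.
  On noise-free simulated APs the estimate sits within ~1.5 mV of the
  dV/dt = 20 mV/ms criterion.
* **Rheobase charge.** Integration starts at the depolarizing
  zero-crossing of the ramp (the hyperpolarizing onset is excluded) and is
  analytic for the piecewise-linear ramp (the trapezoid rule is exact).
* **Maximum rise rate** uses boxcar smoothing before central differences —
  a positive kernel cannot overshoot the true slope at waveform corners,
  where polynomial-fit derivatives ring.
* **Event detection.** Baseline = 200 ms rolling median (evaluated every
  20 ms and interpolated — an O(n) approximation); a 0.2 ms Gaussian
  low-pass precedes thresholding because at 50 kHz single-sample noise
  excursions re-trigger on event tails (the PSC peak is attenuated
  < 1 %). Events are peaks above the threshold with prominence ≥
  threshold/4 and ≥ 0.5 ms separation; pairs closer than the 5 ms
  refractory window are QC-flagged as overlapping rather than merged —
  the prominence floor already suppresses noise chatter, and merging
  genuine overlaps costs recall. Two events closer than ≈1.5 ms superpose
  into a single peak and are reported as one; at 10 Hz this bounds recall
  near 0.97 (template-matching or deconvolution detectors are explicitly
  out of scope).
* **cPSC decomposition.** Per-sweep baseline = mean of the 5 ms before the
  stimulus. "Uncontaminated" is operationalized as: no detector hit in the
  50 ms pre-stimulus window, and no secondary inward trough on the decay
  that re-descends by more than 25 % of the main peak. Approximating-
  segment samples where |template| < 5 % of the template peak are dropped
  (division blow-up near onset). The default scales the template against
  the sweep-averaged cPSC; a per-sweep mode exists and agrees on synthetic
  data. Excitation-window edges use a 3× baseline-sd noise floor with
  linear interpolation; stimulus artifacts are assumed pre-blanked (a
  blanking utility is provided).
* **Kv7 I–V.** The 0.01 mV "interval" is a window centred on each 5 mV
  target; at 0.02 mV/ms and 50 kHz every window holds ~25 samples. No
  leak subtraction beyond the condition subtraction itself. The curve is
  *quasi*-steady-state: a first-order gate with τ = 50 ms lags a
  0.02 mV/ms ramp by τ·(dV/dt) = 1 mV of command voltage, which is an
  ~8 % point-wise deviation from the true steady state at −45 mV and more
  at the activation foot — a property of the protocol, not of the
  analysis. Against the Boltzmann closed form the recovered curve is
  within ~2 % of the curve's full scale everywhere.
* **Theta–gamma.** A stimulus "evoked" an AP when one is detected within
  50 ms (the theta ISI is 200 ms, so windows never overlap). Bins are
  [0,1), [1,2), [2,3] s from theta onset, five stimuli each; gamma-burst
  stimuli are excluded. EPSP amplitudes are peak minus the pre-gamma
  baseline, per stimulus, with AP-contaminated stimuli excluded.
* **Statistics.** Welch's t is the default (classic Student's t by flag);
  Pearson chi-square without Yates correction (the correction applies to
  2×2 tables only); no multiple-testing correction by default, with an
  opt-in Benjamini–Hochberg column. Under the null all four tests reject
  at 5 % within binomial error (1000-simulation calibration).
* **Firing patterns.** ISI CV > 0.5 → stuttering-like; else max rate
  ≥ 50 Hz and adaptation (last/first ISI) < 1.3 → fast-spiking; else
  regular-spiking. The thresholds are config defaults for qualitative
  classes.

## Degenerate inputs and tie-breaks

Traces must be finite, non-empty and uniformly sampled (relative jitter
≤ 1e-6). Empty event lists, all-silent excitability traces, flat cPSC
waveforms, zero-variance statistical groups and sub-10-trial probability
estimates all return flagged results rather than raising, except where a
result would be meaningless (no downward cPSC component, < 20 clean
template sweeps, threshold time before ramp onset). Instantaneous-
frequency histograms cap at 5000 bins with overflow clipped into the top
bin so count conservation holds even for pathological near-coincident
event times.

## Known limitations

* The membrane is a point model: no dendrites, no Ca²⁺ or AHP currents,
  no synaptic conductance dynamics in current clamp beyond OU noise. AP
  shape statistics are realistic but not cell-type-calibrated.
* Generated PSC trains are homogeneous Poisson with independent
  amplitudes; real spontaneous activity has burstiness and
  amplitude–frequency correlations the detector is never challenged with.
* The detector's overlap resolution stops at single-peak superpositions;
  recall figures quoted here assume the generator's kernel widths.
* The theta–gamma generator models suppression phenomenologically
  (Bernoulli with a scaled p), not via synaptic depression mechanisms.
* Cohort jitter defaults favour statistical power over biological realism
  (see above); effect sizes measured on these cohorts should not be read
  as power analyses for experiments.
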