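"""Config-driven pipeline: generate a synthetic cohort and run every
analysis stage, writing per-stage tables and a combined summary.

The pipeline is a pure function of (config, seed): identical configs and
seeds produce byte-identical outputs.  Stage names: ``synth``, ``ap``,
``events``, ``cpsc``, ``kv7``, ``osc``, ``stats``; ``all`` expands to all
of them in that order.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ap as _ap
from . import cpsc as _cpsc
from . import events as _events
from . import kv7 as _kv7
from . import osc as _osc
from . import stats as _stats
from . import synth as _synth
from .core import ConfigError, ProtocolSpec, write_results

STAGES = ("synth", "ap", "events", "cpsc", "kv7", "osc", "stats")

RAMP_PROTOCOL = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=100.0,
                             ramp_pre_offset=-50.0)
RAMP_DURATION_MS = 2400.0  # 100 ms onset + 2 s ramp + margin
RIN_STEP_PA = 60.0  # +60 pA / 500 ms at -45 mV
RIN_STEP_MS = 500.0
RIN_HOLD_MV = -45.0


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def analyze_cell_ramp(params: _synth.MembraneParams) -> dict:
    """First-AP features, count, rheobase and charge from the 2 s ramp."""
    trace, _ = _synth.simulate_membrane(params, RAMP_PROTOCOL,
                                        duration_ms=RAMP_DURATION_MS)
    fs = _ap.extract_features(trace, RAMP_PROTOCOL)
    out = {"ap_count_ramp": fs.ap_count,
           "rheobase_pA": fs.rheobase_pA,
           "rheobase_charge_pC": fs.rheobase_charge_pC}
    if fs.per_ap:
        f = fs.per_ap[0]
        out.update(threshold_mV=f.threshold_mV,
                   max_rise_rate_mV_per_ms=f.max_rise_rate_mV_per_ms,
                   ap_duration_ms=f.duration_ms,
                   ap_amplitude_mV=f.amplitude_mV)
    return out


def analyze_cell_rin(params: _synth.MembraneParams) -> dict:
    """Input resistance at -45 mV before/after Kv7 block, and its change.

    The near-threshold measurement is made on the pharmacologically
    isolated cell (Na+ spiking blocked, emulating TTX in the bath), as the
    paper's protocol requires, so the +60 pA step probes the passive
    response only."""
    step = ProtocolSpec(kind="step", step_amplitude=RIN_STEP_PA,
                        step_onset=200.0, step_duration=RIN_STEP_MS)
    isolated = replace(params, g_na=0.001)  # TTX: no regenerative Na drive

    def rin(p: _synth.MembraneParams) -> float:
        hold = _synth.holding_current_for_potential(p, RIN_HOLD_MV)
        tr, _ = _synth.simulate_membrane(p, step, i_hold=hold,
                                         duration_ms=900.0)
        return _ap.passive_props(tr, step).r_in_MOhm

    basal = rin(isolated)
    treated = rin(replace(isolated, g_kv7_max=0.0))
    delta = _kv7.rin_change(basal, treated)
    return {"rin_basal_MOhm": basal, "rin_xe991_MOhm": treated,
            "rin_increase_pct": delta.percent}


def analyze_cell_events(exc_rate: float, inh_rate: float, seed: int,
                        duration_s: float = 30.0) -> dict:
    """Detected excitatory/inhibitory rates and frequency-based E/I ratio."""
    out = {}
    rates = {}
    for name, rate, pol in (("exc", exc_rate, "inward"),
                            ("inh", inh_rate, "outward")):
        p = _synth.EventTrainParams(rate=rate, duration=duration_s,
                                    polarity=pol, seed=seed + (0 if name == "exc" else 1))
        tr, _ = _synth.generate_event_train(p)
        ev = _events.detect_events(tr, polarity=pol)
        rates[name] = _events.event_rate(ev)["per_min"]
    out["sepsc_per_min"] = rates["exc"]
    out["sipsc_per_min"] = rates["inh"]
    out["ei_ratio"] = _events.ei_ratio(rates["exc"], rates["inh"]).ratio
    return out


def analyze_cell_gamma(suppression: float, n_trials: int, seed: int) -> dict:
    """First-bin AP probability of control and gamma-test theta trains."""
    ctrl, _ = _synth.simulate_theta_gamma(p_base=0.5, suppression=suppression,
                                          n_trials=n_trials, with_gamma=False,
                                          seed=seed)
    test, _ = _synth.simulate_theta_gamma(p_base=0.5, suppression=suppression,
                                          n_trials=n_trials, with_gamma=True,
                                          seed=seed + 1)
    rc = _osc.ap_probability_binned(ctrl)
    rt = _osc.ap_probability_binned(test)
    gs = _osc.gamma_suppression_index(rc, rt)
    return {"p_first_bin_control": float(rc.bin_probability[0]),
            "p_first_bin_test": float(rt.bin_probability[0]),
            "gamma_suppression_ratio": gs.first_bin_ratio}


def cohort_metrics(spec: _synth.CohortSpec, seed: int = 0,
                   stages: tuple = ("ap", "events", "kv7", "osc")) -> pd.DataFrame:
    """Per-cell metric table for a WT vs KO synthetic cohort."""
    cells, _ = _synth.make_cohort(spec, seed=seed)
    rows = []
    for cell in cells:
        p: _synth.MembraneParams = cell.meta["membrane"]
        cs = cell.meta["cell_seed"]
        row = {"cell_id": cell.cell_id, "genotype": cell.genotype,
               "capacitance_pF": p.C}
        if "ap" in stages:
            row.update(analyze_cell_ramp(p))
        if "kv7" in stages:
            row.update(analyze_cell_rin(p))
        if "events" in stages:
            row.update(analyze_cell_events(cell.meta["exc_rate_Hz"],
                                           cell.meta["inh_rate_Hz"], cs,
                                           spec.event_duration_s))
        if "osc" in stages:
            row.update(analyze_cell_gamma(cell.meta["suppression"],
                                          spec.n_theta_trials, cs + 7))
        rows.append(row)
    return pd.DataFrame(rows)


def demo_cpsc_metrics(seed: int) -> dict:
    """One compound-PSC decomposition on generated sweeps (known truth)."""
    sweeps, templ, truth = _synth.compose_cpsc(noise_sd=3.0,
                                               amp_jitter_cv=0.10, seed=seed)
    template = _cpsc.build_epsc_template(templ)
    res = _cpsc.decompose_cpsc(sweeps, template)
    return {"epsc_peak_pA": res.epsc_peak, "ipsc_peak_pA": res.ipsc_peak,
            "true_ipsc_peak_pA": float(truth.components["ipsc_mean"].max()),
            "ei_peak": res.ei_peak, "ei_charge": res.ei_charge,
            "excitation_window_ms": res.excitation_window_ms,
            "n_sweeps": res.n_sweeps}


def demo_kv7_iv(seed: int, capacitance: float = 150.0) -> pd.DataFrame:
    """XE991-subtraction I-V on a generated voltage ramp (5-trial average)."""
    p = _synth.MembraneParams(C=capacitance, g_kv7_max=2.0)
    ramp = ProtocolSpec(kind="ramp", ramp_rate=0.02, ramp_onset=0.0,
                        ramp_start=-95.0, ramp_stop=5.0)
    rng = np.random.default_rng(seed)

    def avg(blocked: bool):
        trials = [_synth.simulate_vc_ramp(p, ramp, kv7_blocked=blocked,
                                          seed=_child_seed(rng), noise_sd=5.0)
                  for _ in range(5)]
        tr0, vcmd = trials[0]
        mean = np.mean([t.values for t, _ in trials], axis=0)
        return tr0.replace(values=mean), vcmd

    basal, vcmd = avg(False)
    treated, _ = avg(True)
    diff = _kv7.subtract_conditions(basal, treated)
    iv = _kv7.build_iv_curve(diff, vcmd, capacitance=capacitance, n_trials=5)
    return pd.DataFrame({"voltage_mV": iv.voltages,
                         "density_pA_per_pF": iv.density})


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the stages named in ``config`` and write a report directory.

    ``config`` is a dict (or path to a YAML/JSON file) with keys ``stages``
    (list), ``seed`` (int, default 0 and recorded in the report), ``out``
    (report directory), and optional ``cohort`` overrides for
    :class:`~dentephys.synth.CohortSpec`. Analysis stages require the synth
    stage (they consume its cohort); requesting one without it is a config
    error. Returns the report directory path."""
    if not isinstance(config, dict):
        path = Path(config)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    stages = list(config.get("stages", ["all"]))
    if "all" in stages:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    analysis = [s for s in stages if s != "synth"]
    if analysis and "synth" not in stages and "input" not in config:
        raise ConfigError(
            f"stage(s) {analysis} need either an 'input' or the synth stage")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out", "report"))
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = dict(config.get("cohort", {}))
    spec = _synth.CohortSpec(**cohort_cfg)
    report = {"seed": seed, "stages": stages,
              "n_per_group": spec.n_per_group, "schema": "pipeline-report"}

    metric_stages = tuple(s for s in ("ap", "events", "kv7", "osc")
                          if s in stages)
    metrics = None
    if metric_stages:
        metrics = cohort_metrics(spec, seed=seed, stages=metric_stages)
        write_results(metrics, out / "metrics")
    if "cpsc" in stages:
        write_results(demo_cpsc_metrics(seed + 101), out / "cpsc")
    if "kv7" in stages:
        write_results(demo_kv7_iv(seed + 202), out / "kv7_iv")
    if "stats" in stages and metrics is not None:
        table = _stats.summary_table(metrics.drop(columns=["cell_id"]),
                                     group_col="genotype")
        write_results(table, out / "summary")
        report["n_significant"] = int(table["significant"].sum())
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return out
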