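"""Shared fixtures: cached synthetic recordings used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from dentephys import synth
from dentephys.core import ProtocolSpec

MC_RAMP = ProtocolSpec(kind="ramp", ramp_rate=0.15, ramp_onset=100.0,
                       ramp_pre_offset=-50.0)
RAMP_MS = 2400.0


@pytest.fixture(scope="session")
def ramp_protocol() -> ProtocolSpec:
    return MC_RAMP


@pytest.fixture(scope="session")
def wt_params() -> synth.MembraneParams:
    return synth.MembraneParams()


@pytest.fixture(scope="session")
def ko_params(wt_params) -> synth.MembraneParams:
    return wt_params.ko()


@pytest.fixture(scope="session")
def wt_ramp_trace(wt_params, ramp_protocol):
    """Noise-free WT ramp response (2 s at 0.15 pA/ms) plus truth."""
    return synth.simulate_membrane(wt_params, ramp_protocol, duration_ms=RAMP_MS)


@pytest.fixture(scope="session")
def ko_ramp_trace(ko_params, ramp_protocol):
    return synth.simulate_membrane(ko_params, ramp_protocol, duration_ms=RAMP_MS)


@pytest.fixture(scope="session")
def event_train_30s():
    """10 Hz / 30 s Poisson PSC train with 2 pA noise, fixed seed."""
    p = synth.EventTrainParams(rate=10.0, duration=30.0, noise_sd=2.0, seed=3)
    return synth.generate_event_train(p)


def match_events(truth_times: np.ndarray, detected_times: np.ndarray,
                 tol_ms: float = 2.0) -> tuple[float, float]:
    """Greedy one-to-one matching; returns (recall, precision)."""
    used = np.zeros(detected_times.size, bool)
    hits = 0
    for t in truth_times:
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        d[used] = np.inf
        if d.min() <= tol_ms:
            used[np.argmin(d)] = True
            hits += 1
    recall = hits / truth_times.size if truth_times.size else float("nan")
    precision = used.sum() / detected_times.size if detected_times.size else float("nan")
    return recall, precision
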