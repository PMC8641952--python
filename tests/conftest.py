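"""Shared fixtures: cached preset simulations and synthetic trace builders.

Simulation-heavy fixtures are session-scoped so each protocol battery or
ramp is integrated once per test run.
"""

import numpy as np
import pytest

from mnephys import ProtocolSpec
from mnephys.config import AnalysisConfig
from mnephys.sim import make_preset, simulate_protocol
from mnephys.sweep import Sweep, CURRENT_CLAMP


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def preset_ramps(config):
    """100 pA/s ramp sweep for every subtype × week preset."""
    out = {}
    for subtype in ("delayed", "immediate"):
        for week in (1, 2, 3):
            p = make_preset(subtype, week)
            prot = ProtocolSpec(mode="current", kind="ramp", holding=-60.0,
                                rate=100.0, durations=(500.0, 12000.0, 200.0))
            out[(subtype, week)] = simulate_protocol(p, prot)[0]
    return out


@pytest.fixture(scope="session")
def preset_vc_ramps(config):
    """Voltage-clamp PIC ramp (10 mV/s, −90 → −10 mV) for each preset."""
    out = {}
    prot = ProtocolSpec(mode="voltage", kind="ramp", holding=-90.0,
                        rate=10.0, durations=(1500.0, 8000.0, 200.0))
    for subtype in ("delayed", "immediate"):
        for week in (1, 2, 3):
            p = make_preset(subtype, week)
            out[(subtype, week)] = (p, simulate_protocol(p, prot)[0])
    return out


def make_rc_step_sweep(R_mohm=100.0, tau_ms=10.0, delta_i_pa=-100.0,
                       v0=-60.0, pre_ms=200.0, step_ms=500.0,
                       post_ms=200.0, fs=20000.0):
    """Ideal RC response to a current step (exact analytic trace)."""
    dt = 1000.0 / fs
    n_pre, n_stim, n_post = (int(round(d / dt))
                             for d in (pre_ms, step_ms, post_ms))
    n = n_pre + n_stim + n_post
    t = np.arange(n) * dt
    cmd = np.zeros(n)
    cmd[n_pre:n_pre + n_stim] = delta_i_pa
    dv = delta_i_pa * R_mohm / 1000.0  # pA * GΩ -> mV
    v = np.full(n, v0)
    ts = t[n_pre:n_pre + n_stim] - t[n_pre]
    v[n_pre:n_pre + n_stim] = v0 + dv * (1.0 - np.exp(-ts / tau_ms))
    tp = t[n_pre + n_stim:] - t[n_pre + n_stim]
    v_end = v[n_pre + n_stim - 1]
    v[n_pre + n_stim:] = v0 + (v_end - v0) * np.exp(-tp / tau_ms)
    return Sweep(time=t, recorded=v, command=cmd, mode=CURRENT_CLAMP)


def add_stylized_spike(v, t, t_spike, thr=-45.0, peak=35.0, rise_ms=1.0,
                       fall_ms=1.0):
    """Superimpose a triangular spike starting at ``t_spike``; the segment
    ramps linearly from the trace value to ``peak`` and back."""
    dt = t[1] - t[0]
    i0 = int(round(t_spike / dt))
    n_rise = max(2, int(round(rise_ms / dt)))
    n_fall = max(2, int(round(fall_ms / dt)))
    base = v[i0]
    up = np.linspace(base, peak, n_rise + 1)
    down = np.linspace(peak, base, n_fall + 1)[1:]
    seg = np.concatenate([up, down])
    v[i0:i0 + seg.size] = seg[:max(0, v.size - i0)]
    return v
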