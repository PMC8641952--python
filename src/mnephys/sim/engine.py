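"""Protocol engine: fixed-step semi-implicit integration of the motoneuron
model in current or voltage clamp.

The integrator uses exponential (exact-relaxation) updates for both the
membrane potential and every first-order gate, at a 10 µs internal step,
resampled to the protocol sample rate (20 kHz default). This scheme is
unconditionally stable for the stiff spike currents and reproduces the
passive RC response exactly in the gated-conductance-free limit.

Voltage clamp is ideal by default: the recorded current is the total ionic
current plus the capacitive current required to impose the command. An
optional series-resistance mode models a non-ideal clamp through a pipette
resistor.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..errors import InvalidArgumentError, SimulationError
from ..sweep import CURRENT_CLAMP, ProtocolSpec, Sweep
from .params import ModelParams

#: Internal integration step (ms); protocol samples are integer multiples.
DT_INTERNAL = 0.01

#: Spike-indicator gate for the mAHP: charges while V is above ~0 mV.
_Z_GATE_V_HALF = 0.0
_Z_GATE_K = 4.0
_Z_TAU_RISE = 1.0  # ms

_DIVERGENCE_MV = 200.0


# ---------------------------------------------------------------------------
# steady-state activation curves (shared by the kernel and the analytic IV)
# ---------------------------------------------------------------------------

def _boltz(V, V_half, k):
    """Increasing Boltzmann activation, 1/(1+exp(-(V-V_half)/k))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - V_half) / k))


def _boltz_inv(V, V_half, k):
    """Decreasing Boltzmann (inactivation / hyperpolarization-activation)."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) - V_half) / k))


def _z_ss(V, tau_mAHP):
    s = _boltz(V, _Z_GATE_V_HALF, _Z_GATE_K)
    rate = s / _Z_TAU_RISE + 1.0 / tau_mAHP
    return (s / _Z_TAU_RISE) / rate


def steady_state_currents(params: ModelParams, v_grid) -> dict:
    """Closed-form steady-state ionic currents (pA) on a voltage grid.

    Returns a dict of per-current components plus ``"total"``; the total is
    exactly the sum of the components. This is the analytic oracle for PIC
    and Ih recovery tests and for solving holding bias currents.
    """
    V = np.atleast_1d(np.asarray(v_grid, dtype=float))
    if not np.all(np.isfinite(V)):
        raise InvalidArgumentError("v_grid must be finite")
    sb, mb = params.spike_block, params.mAHP_block

    out = {}
    out["leak"] = params.g_L * (V - params.E_L)
    m = _boltz(V, sb.m_V_half, sb.m_k)
    h = _boltz_inv(V, sb.h_V_half, sb.h_k)
    out["NaT"] = sb.g_Na * m ** 3 * h * (V - sb.E_Na)
    n = _boltz(V, sb.n_V_half, sb.n_k)
    out["KDR"] = sb.g_K * n ** 4 * (V - sb.E_K)
    out["mAHP"] = mb.g_mAHP * _z_ss(V, mb.tau_mAHP) * (V - sb.E_K)
    out["NaP"] = params.g_NaP * _boltz(V, params.V_half_NaP, params.k_NaP) * (V - sb.E_Na)
    out["CaL"] = params.g_CaL * _boltz(V, params.V_half_CaL, params.k_CaL) * (V - params.E_Ca)
    out["H"] = params.g_H * _boltz_inv(V, params.V_half_H, params.k_H) * (V - params.E_H)
    b_inf = _boltz_inv(V, params.b_V_half, params.b_k)
    s_spk = _boltz(V, _Z_GATE_V_HALF, _Z_GATE_K)
    b_ss = ((b_inf / params.tau_b)
            / (1.0 / params.tau_b + s_spk / params.tau_b_spike))
    out["Kslow"] = (params.g_Kslow * _boltz(V, params.a_V_half, params.a_k)
                    * b_ss * (V - sb.E_K))
    out["total"] = sum(out.values())
    return out


def steady_state_iv(params: ModelParams, v_grid) -> dict:
    """Alias of :func:`steady_state_currents` (the model's steady-state I–V)."""
    return steady_state_currents(params, v_grid)


def holding_bias_current(params: ModelParams, holding_mV: float) -> float:
    """Bias current (pA) that holds the membrane at ``holding_mV`` at rest.

    At equilibrium the injected current equals the total steady-state ionic
    current, so the solve is closed-form."""
    return float(steady_state_currents(params, holding_mV)["total"][0])


def resting_potential(params: ModelParams, v_lo=-120.0, v_hi=-20.0) -> float:
    """Zero-bias resting potential: the most hyperpolarized stable zero of
    the steady-state I–V on [v_lo, v_hi]."""
    grid = np.linspace(v_lo, v_hi, 2001)
    total = steady_state_currents(params, grid)["total"]
    sign = np.sign(total)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    for i in crossings:
        # stable equilibrium: current goes from inward (negative => depolarizing
        # force... note I_ion < 0 depolarizes) to outward as V increases
        if total[i] < 0 <= total[i + 1]:
            v0, v1 = grid[i], grid[i + 1]
            f0, f1 = total[i], total[i + 1]
            return float(v0 - f0 * (v1 - v0) / (f1 - f0))
    raise SimulationError("no stable resting potential found on the grid")


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel(p, command, substeps, dt, mode, i_bias, noise, r_series, v_init):
    """Integrate one sweep.

    mode 0: current clamp (command = stimulus pA above bias; records mV)
    mode 1: ideal voltage clamp (command = mV; records pA, incl. capacitive)
    mode 2: series-resistance voltage clamp (records pipette current pA)
    """
    (C, gL, EL,
     gNa, mVh, mk, hVh, hk, tauh,
     gK, nVh, nk, taun,
     ENa, EK,
     gmAHP, tauz,
     gNaP, VhNaP, kNaP,
     gCaL, VhCaL, kCaL, ECa,
     gH, VhH, kH, tauH, EH,
     gKs, aVh, ak, bVh, bk, taub, taubs) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19], p[20],
        p[21], p[22], p[23], p[24], p[25], p[26], p[27], p[28], p[29], p[30],
        p[31], p[32], p[33], p[34], p[35])

    n_out = command.shape[0]
    recorded = np.empty(n_out)

    V = v_init
    # gates at steady state for v_init
    h = 1.0 / (1.0 + math.exp((V - hVh) / hk))
    n = 1.0 / (1.0 + math.exp(-(V - nVh) / nk))
    r = 1.0 / (1.0 + math.exp((V - VhH) / kH))
    b = 1.0 / (1.0 + math.exp((V - bVh) / bk))
    s0 = 1.0 / (1.0 + math.exp(-(V - _Z_GATE_V_HALF) / _Z_GATE_K))
    zrate = s0 / _Z_TAU_RISE + 1.0 / tauz
    z = (s0 / _Z_TAU_RISE) / zrate

    for i in range(n_out):
        if i == 0:
            cmd_lo = command[0]
            cmd_hi = command[0]
            nsub = 1
        else:
            cmd_lo = command[i - 1]
            cmd_hi = command[i]
            nsub = substeps
        for j in range(nsub):
            frac = (j + 1.0) / nsub
            cmd = cmd_lo + (cmd_hi - cmd_lo) * frac
            if mode == 1:
                V = cmd  # ideal clamp: V follows the command exactly

            # gate updates (exponential relaxation)
            h_inf = 1.0 / (1.0 + math.exp((V - hVh) / hk))
            h += (h_inf - h) * (1.0 - math.exp(-dt / tauh))
            n_inf = 1.0 / (1.0 + math.exp(-(V - nVh) / nk))
            n += (n_inf - n) * (1.0 - math.exp(-dt / taun))
            r_inf = 1.0 / (1.0 + math.exp((V - VhH) / kH))
            r += (r_inf - r) * (1.0 - math.exp(-dt / tauH))
            s = 1.0 / (1.0 + math.exp(-(V - _Z_GATE_V_HALF) / _Z_GATE_K))
            b_inf = 1.0 / (1.0 + math.exp((V - bVh) / bk))
            brate = 1.0 / taub + s / taubs
            b_tgt = (b_inf / taub) / brate
            b += (b_tgt - b) * (1.0 - math.exp(-dt * brate))
            zr = s / _Z_TAU_RISE + 1.0 / tauz
            z_inf = (s / _Z_TAU_RISE) / zr
            z += (z_inf - z) * (1.0 - math.exp(-dt * zr))

            # instantaneous activations
            m = 1.0 / (1.0 + math.exp(-(V - mVh) / mk))
            pna = 1.0 / (1.0 + math.exp(-(V - VhNaP) / kNaP))
            c = 1.0 / (1.0 + math.exp(-(V - VhCaL) / kCaL))
            a = 1.0 / (1.0 + math.exp(-(V - aVh) / ak))

            gNaT = gNa * m * m * m * h
            gKdr = gK * n * n * n * n
            gZ = gmAHP * z
            gP = gNaP * pna
            gC = gCaL * c
            gR = gH * r
            gS = gKs * a * b

            if mode == 1:
                continue  # V imposed; nothing further to integrate

            g_tot = gL + gNaT + gKdr + gZ + gP + gC + gR + gS
            drive = (gL * EL + gNaT * ENa + gKdr * EK + gZ * EK + gP * ENa
                     + gC * ECa + gR * EH + gS * EK)
            if mode == 0:
                i_inj = i_bias + cmd + noise[i]
            else:  # mode 2: pipette resistor to the command potential
                g_s = 1000.0 / r_series  # MΩ -> nS
                g_tot += g_s
                drive += g_s * cmd
                i_inj = noise[i]
            v_inf = (drive + i_inj) / g_tot
            V += (v_inf - V) * (1.0 - math.exp(-dt * g_tot / C))
            if V > _DIVERGENCE_MV or V < -_DIVERGENCE_MV:
                return recorded, 1

        if mode == 0:
            recorded[i] = V
        else:
            # ionic current at the sample point
            m = 1.0 / (1.0 + math.exp(-(V - mVh) / mk))
            pna = 1.0 / (1.0 + math.exp(-(V - VhNaP) / kNaP))
            c = 1.0 / (1.0 + math.exp(-(V - VhCaL) / kCaL))
            a = 1.0 / (1.0 + math.exp(-(V - aVh) / ak))
            i_ion = (gL * (V - EL)
                     + gNa * m * m * m * h * (V - ENa)
                     + gK * n * n * n * n * (V - EK)
                     + gmAHP * z * (V - EK)
                     + gNaP * pna * (V - ENa)
                     + gCaL * c * (V - ECa)
                     + gH * r * (V - EH)
                     + gKs * a * b * (V - EK))
            if mode == 1:
                recorded[i] = i_ion + noise[i]
            else:
                g_s = 1000.0 / r_series
                recorded[i] = g_s * (command[i] - V) + noise[i]
    return recorded, 0


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------

def simulate_protocol(params: ModelParams, protocol: ProtocolSpec,
                      seed: int | None = None,
                      series_resistance: float = 0.0) -> list[Sweep]:
    """Simulate every sweep of ``protocol`` and return Sweep objects.

    In current clamp a bias current is first solved (closed form) so the
    pre-stimulus membrane potential equals ``protocol.holding``. Integration
    is deterministic given ``seed`` (defaults to ``params.seed``); with
    ``noise_sd == 0`` repeated calls are bit-identical regardless of seed.

    ``series_resistance`` (MΩ) > 0 switches voltage clamp from the ideal
    mode to a pipette-resistor model.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    p = params.to_vector()

    t, commands = protocol.command_waveforms()
    dt_out = protocol.dt
    substeps = max(1, int(round(dt_out / DT_INTERNAL)))
    dt_sub = dt_out / substeps

    if protocol.mode == CURRENT_CLAMP:
        mode = 0
        i_bias = holding_bias_current(params, protocol.holding)
        v_init = protocol.holding
    else:
        mode = 2 if series_resistance > 0 else 1
        i_bias = 0.0
        v_init = float(commands[0][0])

    sweeps = []
    for k, cmd in enumerate(commands):
        if params.noise_sd > 0:
            noise = rng.normal(0.0, params.noise_sd, size=cmd.shape[0])
        else:
            noise = np.zeros(cmd.shape[0])
        rec, err = _kernel(p, cmd, substeps, dt_sub, mode, i_bias, noise,
                           series_resistance, v_init)
        if err:
            raise SimulationError(
                f"membrane potential diverged (> {_DIVERGENCE_MV} mV) for "
                f"params {params.to_dict()!r}")
        if mode == 1:
            # capacitive current required to impose the command
            rec = rec + params.C_m * np.gradient(cmd, dt_out)
        meta = {
            "protocol": protocol.kind,
            "clamp_mode": protocol.mode,
            "holding": protocol.holding,
            "sweep_index": k,
            "bias_pA": i_bias if mode == 0 else 0.0,
            "sample_rate_hz": protocol.sample_rate,
            "ground_truth": params,
        }
        sweeps.append(Sweep(time=t.copy(), recorded=rec, command=cmd,
                            mode=protocol.mode, meta=meta))
    return sweeps
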