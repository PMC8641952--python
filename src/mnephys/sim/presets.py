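"""Subtype × developmental-week presets.

Six presets span the delayed/immediate firing dichotomy across three
postnatal weeks. The numbers encode the qualitative developmental programme
seen in lumbar motoneurons:

* delayed presets carry a large slowly inactivating low-threshold K
  conductance (Kv1-like) that postpones firing onset by seconds at rheobase
  and yields an accelerating rate as it inactivates; immediate presets lack
  it and fire within tens of ms with a steady-to-adapting rate (spike-
  triggered mAHP adaptation).
* the persistent-Na half-activation is more depolarized in delayed than
  immediate cells from week 2 onward.
* delayed cells grow (capacitance up, input resistance down) between weeks
  1 and 2 but not 2 and 3; immediate cells stay roughly constant.
* the HCN conductance of delayed cells increases sharply into week 3,
  producing a resting h-current near −100 pA at the resting potential
  (≈ −67 mV) and a prominent depolarizing sag; immediate cells keep a
  minimal HCN conductance at all ages.

The leak reversal of each preset is solved in closed form so that the
zero-bias resting potential lands exactly on the preset's target. Preset
values are calibration targets for the phenotype, not literature constants;
each preset is its own ground-truth manifest for recovery tests.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError
from .engine import steady_state_currents
from .params import MAHPBlock, ModelParams, SpikeBlock

SUBTYPES = ("delayed", "immediate")
WEEKS = (1, 2, 3)

# per-(subtype, week) targets: passive size, gated conductances, RMP.
# k_NaP is steeper in immediate cells so their persistent Na current stays
# small at rest (a stable resting potential requires the leak slope to beat
# the NaP negative slope there).
_PRESETS = {
    ("delayed", 1): dict(C_m=150.0, g_L=8.0, g_NaP=4.0, V_half_NaP=-34.0,
                         k_NaP=3.0, g_CaL=2.0, g_H=2.5, g_Kslow=14.0,
                         rmp=-62.0),
    ("delayed", 2): dict(C_m=370.0, g_L=16.0, g_NaP=22.0, V_half_NaP=-33.0,
                         k_NaP=3.0, g_CaL=6.0, g_H=4.0, g_Kslow=26.0,
                         rmp=-64.0),
    ("delayed", 3): dict(C_m=380.0, g_L=18.0, g_NaP=22.0, V_half_NaP=-33.0,
                         k_NaP=3.0, g_CaL=6.0, g_H=21.5, g_Kslow=28.0,
                         rmp=-66.8),
    ("immediate", 1): dict(C_m=140.0, g_L=7.0, g_NaP=3.0, V_half_NaP=-40.0,
                           k_NaP=3.0, g_CaL=1.0, g_H=0.8, g_Kslow=0.0,
                           rmp=-60.0),
    ("immediate", 2): dict(C_m=145.0, g_L=7.5, g_NaP=2.5, V_half_NaP=-40.0,
                           k_NaP=3.0, g_CaL=1.0, g_H=0.8, g_Kslow=0.0,
                           rmp=-60.0),
    ("immediate", 3): dict(C_m=150.0, g_L=8.0, g_NaP=2.5, V_half_NaP=-40.0,
                           k_NaP=3.0, g_CaL=1.0, g_H=0.8, g_Kslow=0.0,
                           rmp=-61.5),
}

# spike machinery differs by subtype: delayed cells have a more depolarized
# spike threshold and faster repolarization (narrower APs, shorter mAHPs)
_SPIKE = {
    "delayed": dict(m_V_half=-31.0, m_k=5.0, h_V_half=-52.0, h_k=5.0,
                    tau_h=2.0, n_V_half=-26.0, n_k=4.0, tau_n=1.2,
                    g_Na_per_pF=50.0, g_K_per_pF=6.0),
    "immediate": dict(m_V_half=-38.0, m_k=4.5, h_V_half=-58.0, h_k=5.0,
                      tau_h=1.2, n_V_half=-32.0, n_k=5.0, tau_n=2.8,
                      g_Na_per_pF=35.0, g_K_per_pF=3.0),
}

_MAHP = {
    "delayed": MAHPBlock(g_mAHP=30.0, tau_mAHP=50.0),
    "immediate": MAHPBlock(g_mAHP=80.0, tau_mAHP=130.0),
}


def _solve_E_L(params: ModelParams, rmp: float) -> float:
    """Leak reversal such that the steady-state I–V is zero at ``rmp``."""
    comp = steady_state_currents(params, rmp)
    gated = comp["total"][0] - comp["leak"][0]
    return rmp + gated / params.g_L


def make_preset(subtype: str, week: int, noise_sd: float = 0.0,
                seed: int = 0) -> ModelParams:
    """Return the ground-truth parameter set for one subtype/week preset."""
    if subtype not in SUBTYPES:
        raise InvalidArgumentError(
            f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    if week not in WEEKS:
        raise InvalidArgumentError(
            f"unknown week {week!r}; expected one of {WEEKS}")
    spec = _PRESETS[(subtype, week)]
    sp = _SPIKE[subtype]
    spike = SpikeBlock(
        g_Na=sp["g_Na_per_pF"] * spec["C_m"],
        m_V_half=sp["m_V_half"],
        m_k=sp["m_k"],
        h_V_half=sp["h_V_half"],
        h_k=sp["h_k"],
        tau_h=sp["tau_h"],
        n_V_half=sp["n_V_half"],
        n_k=sp["n_k"],
        tau_n=sp["tau_n"],
        g_K=sp["g_K_per_pF"] * spec["C_m"],
    )
    params = ModelParams(
        C_m=spec["C_m"], g_L=spec["g_L"], E_L=-65.0,
        spike_block=spike, mAHP_block=_MAHP[subtype],
        g_NaP=spec["g_NaP"], V_half_NaP=spec["V_half_NaP"], k_NaP=spec["k_NaP"],
        g_CaL=spec["g_CaL"], V_half_CaL=-20.0, k_CaL=5.0,
        g_H=spec["g_H"], V_half_H=-80.0, k_H=8.0, tau_H=250.0,
        g_Kslow=spec["g_Kslow"], tau_b=2000.0, tau_b_spike=15.0,
        noise_sd=noise_sd, seed=seed,
    )
    return params.replace(E_L=_solve_E_L(params, spec["rmp"]))


def preset_manifest(subtype: str, week: int) -> dict:
    """Ground-truth phenotype manifest used by recovery tests."""
    p = make_preset(subtype, week)
    return {
        "subtype": subtype,
        "week": week,
        "params": p.to_dict(),
        "rmp_mV": _PRESETS[(subtype, week)]["rmp"],
        "R_in_MOhm": p.R_in,
        "tau_m_ms": p.tau_m,
    }


def sample_cohort_params(subtype: str, week: int, rng: np.random.Generator,
                         cv: float = 0.15, noise_sd: float = 5.0) -> ModelParams:
    """Draw one synthetic cell around a preset with lognormal inter-cell
    variability (coefficient of variation ``cv``) on size and conductances.

    Size (C_m, g_L, spike conductances) shares one lognormal factor so that
    larger cells have proportionally lower input resistance, preserving the
    size-principle correlation between rheobase and passive properties.
    Gated conductances get independent factors.
    """
    base = make_preset(subtype, week, noise_sd=noise_sd,
                       seed=int(rng.integers(0, 2**31 - 1)))
    sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))

    def ln():
        return float(rng.lognormal(-0.5 * sigma ** 2, sigma))

    size = ln()
    p = base.replace(
        C_m=base.C_m * size,
        g_L=base.g_L * size,
        g_Na=base.spike_block.g_Na * size,
        g_K=base.spike_block.g_K * size,
        g_NaP=base.g_NaP * size * ln(),
        g_CaL=base.g_CaL * size * ln(),
        g_H=base.g_H * size * ln(),
        g_Kslow=base.g_Kslow * size * ln(),
    )
    # re-anchor the resting potential of the perturbed cell
    return p.replace(E_L=_solve_E_L(p, _PRESETS[(subtype, week)]["rmp"]))
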