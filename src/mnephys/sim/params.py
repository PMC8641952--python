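"""Ground-truth parameters of the single-compartment motoneuron model.

The membrane follows a Hodgkin–Huxley-style current balance

    C_m dV/dt = I_inj − I_L − I_Na − I_K − I_mAHP − I_NaP − I_CaL − I_H − I_Kslow + ξ(t)

with Boltzmann steady-state activation curves throughout. Fast activations
(transient-Na m, persistent-Na p, L-type-Ca c, slow-K activation a) are
treated as instantaneous; inactivations and slow activations (Na h,
delayed-rectifier n, spike-triggered AHP z, slow-K inactivation b, HCN r)
are first-order gates. Conductances are in nS, voltages in mV, capacitance
in pF, currents in pA, time in ms — so pA/pF integrates directly to mV/ms.

With all gated conductances set to zero the model is an exact RC circuit
(τ = C_m/g_L), which serves as the analytic oracle for passive tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from ..errors import InvalidArgumentError

# Parameter-vector layout consumed by the compiled integrator. Order is a
# frozen ABI between ModelParams.to_vector() and engine._integrate.
_VEC_FIELDS = (
    "C_m", "g_L", "E_L",
    "g_Na", "m_V_half", "m_k", "h_V_half", "h_k", "tau_h",
    "g_K", "n_V_half", "n_k", "tau_n",
    "E_Na", "E_K",
    "g_mAHP", "tau_mAHP",
    "g_NaP", "V_half_NaP", "k_NaP",
    "g_CaL", "V_half_CaL", "k_CaL", "E_Ca",
    "g_H", "V_half_H", "k_H", "tau_H", "E_H",
    "g_Kslow", "a_V_half", "a_k", "b_V_half", "b_k", "tau_b", "tau_b_spike",
)


@dataclass(frozen=True)
class SpikeBlock:
    """Transient spiking machinery: transient Na (instantaneous m³, gated h)
    and delayed-rectifier K (n⁴). Tuned so spikes exceed 60 mV from
    threshold with half-widths in the 0.5–3 ms range."""

    g_Na: float = 4000.0      # nS
    m_V_half: float = -33.0   # mV
    m_k: float = 6.0          # mV
    h_V_half: float = -50.0   # mV
    h_k: float = 6.0          # mV (inactivation slope, applied inverted)
    tau_h: float = 1.2        # ms
    g_K: float = 900.0        # nS
    n_V_half: float = -32.0   # mV
    n_k: float = 5.0          # mV
    tau_n: float = 1.5        # ms
    E_Na: float = 55.0        # mV
    E_K: float = -85.0        # mV


@dataclass(frozen=True)
class MAHPBlock:
    """Spike-triggered slow K conductance producing the medium AHP. The gate
    z charges rapidly while V is above ~0 mV (i.e. during a spike) and
    decays with tau_mAHP; reversal shared with E_K."""

    g_mAHP: float = 60.0      # nS
    tau_mAHP: float = 80.0    # ms


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set; the synthetic ground truth for recovery tests."""

    C_m: float = 150.0        # pF
    g_L: float = 8.0          # nS
    E_L: float = -65.0        # mV
    spike_block: SpikeBlock = field(default_factory=SpikeBlock)
    mAHP_block: MAHPBlock = field(default_factory=MAHPBlock)

    # Persistent Na (NaP), hyperpolarized-activating
    g_NaP: float = 0.0        # nS
    V_half_NaP: float = -45.0  # mV
    k_NaP: float = 5.0        # mV

    # L-type Ca (CaL), depolarized-activating
    g_CaL: float = 0.0        # nS
    V_half_CaL: float = -20.0  # mV
    k_CaL: float = 5.0        # mV
    E_Ca: float = 60.0        # mV

    # HCN (Ih): activates with hyperpolarization (inverted slope k_H)
    g_H: float = 0.0          # nS
    V_half_H: float = -80.0   # mV
    k_H: float = 8.0          # mV
    tau_H: float = 250.0      # ms (voltage-independent by design)
    E_H: float = -35.0        # mV

    # Slowly inactivating low-threshold K (Kv1-like), delays firing onset
    g_Kslow: float = 0.0      # nS
    a_V_half: float = -50.0   # mV
    a_k: float = 6.0          # mV
    b_V_half: float = -65.0   # mV
    b_k: float = 6.0          # mV
    tau_b: float = 2000.0     # ms
    #: extra (cumulative) inactivation rate while V is above ~0 mV; spikes
    #: progressively inactivate the slow K current, accelerating the rate
    tau_b_spike: float = float("inf")  # ms

    noise_sd: float = 0.0     # pA, additive current noise at output rate
    seed: int = 0

    def __post_init__(self):
        if self.C_m <= 0:
            raise InvalidArgumentError("C_m must be positive")
        for name in ("g_L", "g_NaP", "g_CaL", "g_H", "g_Kslow"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.spike_block.g_Na < 0 or self.spike_block.g_K < 0:
            raise InvalidArgumentError("spike conductances must be >= 0")
        if self.mAHP_block.g_mAHP < 0:
            raise InvalidArgumentError("g_mAHP must be >= 0")
        for name in ("k_NaP", "k_CaL", "k_H"):
            if getattr(self, name) == 0:
                raise InvalidArgumentError(f"{name} must be nonzero")
        if not (self.spike_block.E_K < self.E_H < 0.0):
            raise InvalidArgumentError(
                "E_H must lie strictly between E_K and 0 mV")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    # -- conversions ------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        sb, mb = self.spike_block, self.mAHP_block
        src = {**asdict(self), **asdict(sb),
               "g_mAHP": mb.g_mAHP, "tau_mAHP": mb.tau_mAHP}
        return np.array([src[f] for f in _VEC_FIELDS], dtype=np.float64)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with top-level fields replaced; spike/mAHP block
        fields may be given directly and are routed into their block."""
        sb_fields = {k: v for k, v in kwargs.items()
                     if k in SpikeBlock.__dataclass_fields__}
        mb_fields = {k: v for k, v in kwargs.items()
                     if k in MAHPBlock.__dataclass_fields__}
        top = {k: v for k, v in kwargs.items()
               if k not in sb_fields and k not in mb_fields}
        out = self
        if sb_fields:
            top["spike_block"] = replace(self.spike_block, **sb_fields)
        if mb_fields:
            top["mAHP_block"] = replace(self.mAHP_block, **mb_fields)
        return replace(out, **top)

    def passive_only(self) -> "ModelParams":
        """Copy with every gated conductance zeroed (exact RC circuit)."""
        return self.replace(g_Na=0.0, g_K=0.0, g_mAHP=0.0, g_NaP=0.0,
                            g_CaL=0.0, g_H=0.0, g_Kslow=0.0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if isinstance(d.get("spike_block"), dict):
            d["spike_block"] = SpikeBlock(**d["spike_block"])
        if isinstance(d.get("mAHP_block"), dict):
            d["mAHP_block"] = MAHPBlock(**d["mAHP_block"])
        return cls(**d)

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m/g_L in ms (pF/nS)."""
        return self.C_m / self.g_L

    @property
    def R_in(self) -> float:
        """Passive input resistance in MΩ (1000/nS)."""
        return 1000.0 / self.g_L
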