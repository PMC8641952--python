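"""End-to-end per-cell pipeline: protocol battery, simulation, extraction.

The battery mirrors a full intrinsic-property recording session:

1. passive hyperpolarizing step bringing the membrane from −60 to −70 mV
2. slow depolarizing current ramp (100 pA/s) from −60 mV
3. 5 s depolarizing step family bracketing rheobase (steps + FI)
4. triangular ramp to 2× ramp rheobase (5 s rise and fall)
5. brief (10 ms) suprathreshold pulse for the single-spike/mAHP waveform
6. 1 s hyperpolarizing step family for sag/gSag
7. voltage-clamp ramp (10 mV/s, −90 → −10 mV) for PICs
8. voltage-clamp Ih steps (−60 → −110 mV, 10 mV increments, 1 s)
9. voltage-clamp resting-Ih step (−50 mV down to the cell's RMP)

Step amplitudes that an experimenter would titrate on line (the current
needed to reach −70 mV, the rheobase bracketing, the brief-pulse intensity)
are solved from the model in the same adaptive spirit. The brief pulse is
applied 25% above the cell's measured brief-pulse threshold: in a single
compartment the somatic charge needed to fire within 10 ms exceeds
1.25× the slow-ramp rheobase, so the intensity is referenced to the pulse
threshold to preserve the measurement's intent.
"""

from __future__ import annotations

import numpy as np

from . import ccfeat, vcfeat
from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import MnephysError, NotFoundError
from .sweep import (CURRENT_CLAMP, VOLTAGE_CLAMP, ProtocolSpec, Sweep,
                    triangle_peak_rate)
from .sim import (ModelParams, simulate_protocol, steady_state_currents,
                  resting_potential)

#: Canonical per-cell feature columns (the intrinsic-property row).
FEATURE_COLUMNS = [
    "RMP", "R_in_initial", "R_in_ss", "tau_m", "C_m",
    "rheobase_step", "rheobase_ramp", "threshold_V",
    "ap_amplitude", "ap_rise_time", "ap_half_width",
    "mahp_amplitude", "mahp_half_width",
    "onset_latency", "rate_at_rheobase", "rate_at_2x", "max_rate",
    "subprimary_gain", "delta_I", "hysteresis_type",
    "accel_onset_V", "accel_amplitude", "ePIC",
    "sag_amplitude", "g_sag",
    # voltage-clamp extensions
    "pic_onset_V", "pic_peak_V", "pic_amplitude", "pic_density",
    "ih_amp_-70", "ih_amp_-110", "ih_tau_-110", "resting_ih",
    "resting_ih_density", "firing_type",
]


def _step_to_target(params: ModelParams, holding: float, target: float) -> float:
    """Injected-current step (pA) that moves the steady-state membrane
    potential from ``holding`` to ``target`` (the on-line titration an
    experimenter performs)."""
    iv = steady_state_currents(params, [holding, target])["total"]
    return float(iv[1] - iv[0])


def _first_spike_ramp(params: ModelParams, holding: float, seed: int,
                      config: AnalysisConfig, max_pA: float = 1600.0):
    """Simulate the 100 pA/s ramp, extending once if subthreshold."""
    for dur in (max_pA / config.ramp_rate * 1000.0,
                2 * max_pA / config.ramp_rate * 1000.0):
        prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="ramp", holding=holding,
                            rate=config.ramp_rate,
                            durations=(500.0, dur, 200.0))
        sw = simulate_protocol(params, prot, seed=seed)[0]
        try:
            ccfeat.rheobase_from_ramp(sw, config)
            return sw
        except NotFoundError:
            continue
    return sw  # subthreshold; caller decides


def _pulse_threshold(params: ModelParams, seed: int,
                     config: AnalysisConfig) -> float:
    """Minimal 10 ms pulse current eliciting a spike (bisection, pA)."""
    def n_spikes(amp):
        prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="pulse", holding=-60.0,
                            amplitudes=(amp,), durations=(200.0, 10.0, 500.0))
        sw = simulate_protocol(params, prot, seed=seed)[0]
        return ccfeat.detect_spikes(sw, config).n_spikes

    lo, hi = 50.0, 8000.0
    tries = 0
    while n_spikes(hi) == 0:
        hi *= 2
        tries += 1
        if tries > 4:
            raise NotFoundError("no spike from brief pulses up to 128 nA")
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if n_spikes(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def simulate_cell_battery(params: ModelParams, seed: int = 0,
                          config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Run the full protocol battery; returns ``{protocol_name: [Sweep]}``.

    Seeds are derived per protocol from ``seed`` so each protocol's noise is
    independent but the whole battery is reproducible.
    """
    rng = np.random.SeedSequence(seed)
    seeds = [int(s) for s in
             rng.generate_state(16) % (2**31 - 1)]
    sweeps: dict[str, list[Sweep]] = {}

    # 1. passive step, −60 → −70 mV
    amp70 = _step_to_target(params, -60.0, -70.0)
    prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="step", holding=-60.0,
                        amplitudes=(amp70,), durations=(500.0, 1000.0, 300.0))
    sweeps["passive_step"] = simulate_protocol(params, prot, seed=seeds[0])

    # 2. slow depolarizing ramp
    ramp_sw = _first_spike_ramp(params, -60.0, seeds[1], config)
    sweeps["ramp"] = [ramp_sw]
    try:
        ramp_rheo = ccfeat.rheobase_from_ramp(ramp_sw, config).rheobase_I
    except NotFoundError:
        ramp_rheo = None

    if ramp_rheo is not None:
        # 3. rheobase-bracketing 5 s step family + FI extension
        inc = 25.0 if ramp_rheo <= 500.0 else 50.0
        lo = max(inc, inc * np.floor(0.4 * ramp_rheo / inc))
        hi = inc * np.ceil(1.5 * ramp_rheo / inc)
        amps = list(np.arange(lo, hi + inc / 2, inc))
        amps += [round(f * ramp_rheo) for f in (1.7, 2.0, 2.3)]
        prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="step_family",
                            holding=-60.0, amplitudes=tuple(amps),
                            durations=(500.0, 5000.0, 300.0))
        sweeps["steps"] = simulate_protocol(params, prot, seed=seeds[2])

        # 4. triangular ramp to 2× ramp rheobase
        rate = triangle_peak_rate(2.0 * ramp_rheo)
        prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="triangle",
                            holding=-60.0, rate=rate,
                            durations=(500.0, 5000.0, 300.0))
        sweeps["triangle"] = simulate_protocol(params, prot, seed=seeds[3])

        # 5. brief pulse, 25% above the brief-pulse threshold
        try:
            pulse_thr = _pulse_threshold(params, seeds[4], config)
            prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="pulse",
                                holding=-60.0, amplitudes=(1.25 * pulse_thr,),
                                durations=(200.0, 10.0, 500.0))
            sweeps["pulse"] = simulate_protocol(params, prot, seed=seeds[4])
        except NotFoundError:
            pass

    # 6. sag step family: targets −70 … −100 mV
    sag_amps = tuple(_step_to_target(params, -60.0, v)
                     for v in (-70.0, -80.0, -90.0, -100.0))
    prot = ProtocolSpec(mode=CURRENT_CLAMP, kind="step_family", holding=-60.0,
                        amplitudes=sag_amps, durations=(500.0, 1000.0, 300.0))
    sweeps["sag_steps"] = simulate_protocol(params, prot, seed=seeds[5])

    # 7. voltage-clamp PIC ramp
    prot = ProtocolSpec(mode=VOLTAGE_CLAMP, kind="ramp", holding=-90.0,
                        rate=10.0, durations=(1500.0, 8000.0, 200.0))
    sweeps["vc_ramp"] = simulate_protocol(params, prot, seed=seeds[6])

    # 8. voltage-clamp Ih steps
    prot = ProtocolSpec(mode=VOLTAGE_CLAMP, kind="step_family", holding=-60.0,
                        amplitudes=tuple(np.arange(-60.0, -111.0, -10.0)),
                        durations=(1000.0, 1000.0, 300.0))
    sweeps["vc_ih_steps"] = simulate_protocol(params, prot, seed=seeds[7])

    # 9. resting Ih (−50 mV → RMP)
    rmp = resting_potential(params)
    if rmp < -50.0:
        prot = ProtocolSpec(mode=VOLTAGE_CLAMP, kind="step", holding=-50.0,
                            amplitudes=(rmp,), durations=(1000.0, 1000.0, 300.0))
        sweeps["vc_resting_ih"] = simulate_protocol(params, prot, seed=seeds[8])
    for group in sweeps.values():
        for sw in group:
            sw.meta["rmp_mV"] = rmp
    return sweeps


def extract_cell_features(sweeps: dict, config: AnalysisConfig = DEFAULT_CONFIG,
                          cell_id: str | None = None) -> dict:
    """Extract the canonical feature row from one cell's protocol battery.

    Missing protocols or analysis failures leave the corresponding features
    as NaN (explicitly missing, never silently zero).
    """
    row: dict = {c: np.nan for c in FEATURE_COLUMNS}
    if cell_id is not None:
        row["cell_id"] = cell_id
    row["firing_type"] = None

    rmp = None
    for group in sweeps.values():
        for sw in group:
            if "rmp_mV" in sw.meta:
                rmp = float(sw.meta["rmp_mV"])
                break
        if rmp is not None:
            break
    if rmp is not None:
        row["RMP"] = rmp

    if "passive_step" in sweeps:
        try:
            pp = ccfeat.measure_passive(sweeps["passive_step"][0], config)
            row.update(R_in_initial=pp.R_in_initial, R_in_ss=pp.R_in_ss,
                       tau_m=pp.tau_m, C_m=pp.C_m)
        except MnephysError:
            pass

    ramp_res = None
    if "ramp" in sweeps:
        try:
            ramp_res = ccfeat.acceleration_and_epic(sweeps["ramp"][0], config)
            row.update(rheobase_ramp=ramp_res.rheobase_I,
                       threshold_V=ramp_res.threshold_V,
                       accel_onset_V=ramp_res.accel_onset_V,
                       accel_amplitude=ramp_res.accel_amplitude,
                       ePIC=ramp_res.ePIC)
        except MnephysError:
            pass

    if "steps" in sweeps:
        try:
            row["rheobase_step"] = ccfeat.rheobase_from_steps(
                sweeps["steps"], config)
        except MnephysError:
            pass
        if np.isfinite(row.get("rheobase_step", np.nan)):
            for sw in sweeps["steps"]:
                win = ccfeat._step_window(sw.command,
                                          config.min_step_amplitude / 2.0)
                if win and abs((win[3] - win[2]) - row["rheobase_step"]) < 1e-6:
                    try:
                        fi = ccfeat.classify_firing_type(sw, config)
                        row.update(firing_type=fi.firing_type,
                                   onset_latency=fi.onset_latency)
                    except MnephysError:
                        pass
                    break
        try:
            fi_all = ccfeat.fi_analysis(
                sweeps["steps"], sweeps.get("triangle", [None])[0], config)
            row.update(rate_at_rheobase=fi_all.rate_at_rheobase,
                       rate_at_2x=fi_all.rate_at_2x_rheobase,
                       max_rate=fi_all.max_rate,
                       subprimary_gain=fi_all.subprimary_gain)
        except MnephysError:
            pass

    if "triangle" in sweeps:
        try:
            tri = ccfeat.triangle_hysteresis(sweeps["triangle"][0], config)
            row.update(delta_I=tri.delta_I,
                       hysteresis_type=tri.hysteresis_type)
        except MnephysError:
            pass

    if "pulse" in sweeps:
        try:
            ap = ccfeat.spike_ahp_features(sweeps["pulse"][0], config)
            row.update(ap_amplitude=ap.amplitude, ap_rise_time=ap.rise_time,
                       ap_half_width=ap.half_width,
                       mahp_amplitude=ap.mAHP_amplitude,
                       mahp_half_width=ap.mAHP_half_width)
        except MnephysError:
            pass

    if "sag_steps" in sweeps:
        try:
            sag = ccfeat.sag_analysis(sweeps["sag_steps"], config)
            row.update(g_sag=sag.g_sag,
                       sag_amplitude=float(np.max(sag.sag_amplitudes))
                       if sag.sag_amplitudes.size else np.nan)
        except MnephysError:
            pass

    c_m = row.get("C_m", np.nan)
    if "vc_ramp" in sweeps and np.isfinite(c_m):
        try:
            sub = vcfeat.leak_subtract(sweeps["vc_ramp"][0],
                                       fit_window="auto", config=config)
            pm = vcfeat.pic_measures(sub, c_m, config=config)
            row.update(pic_onset_V=pm.onset_V, pic_peak_V=pm.peak_V,
                       pic_amplitude=pm.amplitude, pic_density=pm.density)
        except MnephysError:
            pass

    if "vc_ih_steps" in sweeps and np.isfinite(c_m):
        try:
            ih = vcfeat.ih_from_steps(sweeps["vc_ih_steps"], c_m, config)
            for v_target, col in ((-70.0, "ih_amp_-70"),
                                  (-110.0, "ih_amp_-110")):
                hit = np.nonzero(np.abs(ih.command_V - v_target) < 1.0)[0]
                if hit.size:
                    row[col] = float(ih.amplitude[hit[0]])
                    if v_target == -110.0:
                        row["ih_tau_-110"] = float(ih.tau[hit[0]])
        except MnephysError:
            pass

    if "vc_resting_ih" in sweeps and np.isfinite(c_m) and rmp is not None:
        try:
            rih = vcfeat.resting_ih(sweeps["vc_resting_ih"][0], c_m, rmp,
                                    config)
            row.update(resting_ih=rih.resting_Ih,
                       resting_ih_density=rih.resting_Ih_density)
        except MnephysError:
            pass
    return row


def simulate_and_extract(params: ModelParams, seed: int = 0,
                         config: AnalysisConfig = DEFAULT_CONFIG,
                         cell_id: str | None = None) -> dict:
    """Battery + extraction in one call."""
    return extract_cell_features(simulate_cell_battery(params, seed, config),
                                 config, cell_id=cell_id)


# ---------------------------------------------------------------------------
# synthetic cohort studies
# ---------------------------------------------------------------------------

def generate_cohort(n_per_group: int = 10, seed: int = 0,
                    cv: float = 0.15, noise_sd: float = 5.0) -> list[dict]:
    """Draw a synthetic cohort: ``n_per_group`` cells for every
    subtype × week combination, with lognormal inter-cell variability.

    Returns a list of ``{"cell_id", "subtype", "week", "params", "seed"}``.
    """
    from .sim import sample_cohort_params, SUBTYPES, WEEKS
    rng = np.random.default_rng(seed)
    cells = []
    for subtype in SUBTYPES:
        for week in WEEKS:
            for i in range(n_per_group):
                params = sample_cohort_params(subtype, week, rng,
                                              cv=cv, noise_sd=noise_sd)
                cells.append({
                    "cell_id": f"{subtype[:3]}-w{week}-{i:02d}",
                    "subtype": subtype,
                    "week": week,
                    "params": params,
                    "seed": int(rng.integers(0, 2**31 - 1)),
                })
    return cells


def run_cohort_study(n_per_group: int = 10, seed: int = 0,
                     config: AnalysisConfig = DEFAULT_CONFIG,
                     drug: str | None = None, block_fraction: float = 1.0,
                     cv: float = 0.15, noise_sd: float = 5.0):
    """Simulate and extract a full synthetic cohort.

    Returns a pandas feature table with subtype/week labels (plus a
    ``drug`` column when a blocker is applied to every cell).
    """
    from .sim import apply_drug
    from .cohort import build_feature_table
    cells = generate_cohort(n_per_group, seed, cv=cv, noise_sd=noise_sd)
    rows, labels = [], []
    for cell in cells:
        params = cell["params"]
        if drug is not None:
            params = apply_drug(params, drug, block_fraction)
        rows.append(simulate_and_extract(params, seed=cell["seed"],
                                         config=config,
                                         cell_id=cell["cell_id"]))
        labels.append({"subtype": cell["subtype"], "week": cell["week"],
                       "drug": drug or "none"})
    return build_feature_table(rows, labels)
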