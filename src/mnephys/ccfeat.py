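"""Current-clamp feature extraction.

Implements the full intrinsic-property battery measured from current-clamp
sweeps: passive properties from small hyperpolarizing steps (C = τ/R),
spike detection by the 10 mV/ms derivative criterion, rheobase from 5 s
step families (first step with ≥ 3 spikes) and from slow 100 pA/s ramps,
delayed/immediate firing classification, the current-clamp PIC estimate
(ePIC = extrapolated "passive rheobase" − measured rheobase), triangular-
ramp ΔI hysteresis, depolarizing-sag analysis (gSag = 1/R_ss − 1/R_init),
single-spike/mAHP waveform measures, and frequency–current (FI) analysis
with the sub-primary-range gain.

Unit conventions: mV, pA, ms; resistances in MΩ; capacitance in pF under
pF = ms/GΩ (so C_m = 1000·τ_m/R_in with R_in in MΩ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import (DegenerateInputError, InsufficientFiringError,
                     InvalidSweepError, NotFoundError)
from .sweep import Sweep

#: Minimum spike-peak voltage; subthreshold bumps never reach this.
SPIKE_PEAK_MIN_MV = -20.0
#: Refractory separation between spike peaks (ms).
SPIKE_REFRACTORY_MS = 1.0
#: Rate difference separating overlapping from hysteretic FI branches (Hz).
HYSTERESIS_RATE_TOL_HZ = 2.0
#: |ΔI| below this counts as symmetric recruitment/derecruitment (pA).
DELTA_I_TOL_PA = 10.0


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class PassiveProps:
    R_in_initial: float   # MΩ
    R_in_ss: float        # MΩ
    tau_m: float          # ms
    C_m: float            # pF
    V_rest: float         # mV (pre-step baseline potential)
    flags: list = field(default_factory=list)


@dataclass
class SpikeTrain:
    spike_times: np.ndarray          # ms, threshold-crossing times
    threshold_voltages: np.ndarray   # mV per spike
    peak_times: np.ndarray           # ms
    peak_voltages: np.ndarray        # mV
    threshold_indices: np.ndarray    # sample index of each threshold
    peak_indices: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def instantaneous_rates(self) -> np.ndarray:
        """Hz between consecutive spikes (1000/ISI in ms)."""
        if self.n_spikes < 2:
            return np.empty(0)
        return 1000.0 / np.diff(self.spike_times)


@dataclass
class RampExcitability:
    rheobase_I: float          # pA
    threshold_V: float         # mV
    passive_slope: float = np.nan    # mV/pA
    accel_onset_V: float = np.nan    # mV
    accel_onset_I: float = np.nan    # pA
    accel_amplitude: float = np.nan  # mV
    passive_rheobase_I: float = np.nan  # pA
    ePIC: float = np.nan       # pA
    flags: list = field(default_factory=list)


@dataclass
class TriangleResult:
    I_recruit: float       # pA
    I_derecruit: float     # pA
    delta_I: float         # pA
    hysteresis_type: int   # 1 linear, 2 adapting, 3 sustained, 4 counterclockwise
    max_rate: float        # Hz


@dataclass
class SagResult:
    step_amplitudes: np.ndarray   # pA
    sag_amplitudes: np.ndarray    # mV, positive = depolarizing sag
    trough_V: np.ndarray          # mV
    plateau_V: np.ndarray         # mV
    R_in_initial: float = np.nan  # MΩ (slope of trough I–V)
    R_in_ss: float = np.nan       # MΩ (slope of plateau I–V)
    g_sag: float = np.nan         # nS
    flags: list = field(default_factory=list)


@dataclass
class APWaveform:
    threshold_V: float     # mV
    amplitude: float       # mV, from threshold
    rise_time: float       # ms, threshold -> peak
    half_width: float      # ms, at half amplitude-from-threshold
    mAHP_amplitude: float  # mV, baseline minus post-spike trough
    mAHP_half_width: float  # ms
    flags: list = field(default_factory=list)


@dataclass
class FIResult:
    firing_type: str | None = None   # delayed | immediate | unclassified
    onset_latency: float = np.nan    # ms
    rate_slope: float = np.nan       # Hz/s over the step
    rate_at_rheobase: float = np.nan  # Hz
    rate_at_2x_rheobase: float = np.nan  # Hz
    max_rate: float = np.nan         # Hz
    subprimary_gain: float = np.nan  # Hz/pA
    gain_points: int = 0             # FI points used for the gain fit
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smoothed_derivative(v: np.ndarray, dt: float, smoothing_ms: float):
    """Boxcar-smoothed central-difference dV/dt (mV/ms)."""
    w = max(1, int(round(smoothing_ms / dt)))
    if w % 2 == 0:
        w += 1  # odd window: no half-sample shift
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.pad(v, w // 2, mode="edge")
        v = np.convolve(padded, kernel, mode="valid")
    return np.gradient(v, dt), v


def _step_window(command: np.ndarray, resolution: float):
    """Indices [onset, offset) of the single largest command step.

    Returns (onset, offset, baseline_level, step_level)."""
    base = command[0]
    dev = np.abs(command - base) > resolution
    if not dev.any():
        return None
    onset = int(np.argmax(dev))
    offset = int(len(command) - np.argmax(dev[::-1]))
    level = float(np.median(command[onset:offset]))
    return onset, offset, float(base), level


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def detect_spikes(sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG) -> SpikeTrain:
    """Detect spikes and their voltage thresholds.

    A spike's threshold is the first sample at which the smoothed dV/dt
    reaches ``config.dvdt_threshold`` (default 10 mV/ms) on the upstroke
    preceding that spike's peak. Peaks closer than 1 ms are merged by the
    refractory rule. Subthreshold sweeps return an empty train.
    """
    v = sweep.recorded
    t = sweep.time
    dvdt, _ = _smoothed_derivative(v, sweep.dt, config.smoothing)
    distance = max(1, int(round(SPIKE_REFRACTORY_MS / sweep.dt)))
    peaks, _ = find_peaks(v, height=SPIKE_PEAK_MIN_MV, distance=distance)

    thr_idx, thr_v, pk_keep = [], [], []
    prev_peak = 0
    for pk in peaks:
        # search from the inter-spike voltage minimum so the previous
        # spike's upstroke cannot shadow this spike's threshold
        if prev_peak > 0 and pk > prev_peak + 1:
            lo = prev_peak + int(np.argmin(v[prev_peak:pk]))
        else:
            lo = prev_peak
        seg = dvdt[lo:pk + 1]
        at_or_above = np.nonzero(seg >= config.dvdt_threshold)[0]
        if at_or_above.size == 0:
            continue  # no upstroke reaching the criterion -> not a spike
        idx = int(at_or_above[0] + lo)
        thr_idx.append(idx)
        thr_v.append(v[idx])
        pk_keep.append(pk)
        prev_peak = pk
    thr_idx = np.asarray(thr_idx, dtype=int)
    pk_keep = np.asarray(pk_keep, dtype=int)
    return SpikeTrain(
        spike_times=t[thr_idx] if thr_idx.size else np.empty(0),
        threshold_voltages=np.asarray(thr_v),
        peak_times=t[pk_keep] if pk_keep.size else np.empty(0),
        peak_voltages=v[pk_keep] if pk_keep.size else np.empty(0),
        threshold_indices=thr_idx,
        peak_indices=pk_keep,
    )


def measure_passive(sweep: Sweep,
                    config: AnalysisConfig = DEFAULT_CONFIG) -> PassiveProps:
    """Passive properties from a small hyperpolarizing current step.

    R_in_initial is read at the early voltage trough (minimising the
    contribution of slow conductances such as Ih), R_in_ss at the late
    plateau. τ_m is estimated from the time to reach ``tau_fraction``
    (default 2/3) of the trough deflection, calibrated to an exponential:
    τ_m = t_f / (−ln(1 − f)), so an ideal RC trace returns its true time
    constant. C_m = τ_m/R_in_initial (pF = ms/GΩ).
    """
    win = _step_window(sweep.command, config.min_step_amplitude / 2.0)
    if win is None:
        raise DegenerateInputError("no current step found in command")
    onset, offset, base_i, step_i = win
    delta_i = step_i - base_i
    if abs(delta_i) < config.min_step_amplitude:
        raise DegenerateInputError(
            f"step amplitude {delta_i:.2f} pA below resolution")

    v = sweep.recorded
    t = sweep.time
    baseline = float(np.mean(v[max(0, onset - int(100.0 / sweep.dt)):onset]))

    flags = []
    trough_end = min(offset, onset + int(round(200.0 / sweep.dt)))
    seg = v[onset:trough_end]
    trough_rel = int(np.argmin(seg) if delta_i < 0 else np.argmax(seg))
    plateau_start = max(onset, offset - int(round(100.0 / sweep.dt)))
    v_ss = float(np.mean(v[plateau_start:offset]))
    v_trough = float(seg[trough_rel])
    if trough_rel >= len(seg) - 1:
        flags.append("no_trough_before_plateau")
        v_trough = v_ss

    r_init = (v_trough - baseline) / delta_i * 1000.0  # MΩ
    r_ss = (v_ss - baseline) / delta_i * 1000.0

    # time to tau_fraction of the trough deflection
    target = baseline + config.tau_fraction * (v_trough - baseline)
    seg_full = v[onset:onset + trough_rel + 1]
    if delta_i < 0:
        crossed = np.nonzero(seg_full <= target)[0]
    else:
        crossed = np.nonzero(seg_full >= target)[0]
    if crossed.size == 0:
        raise DegenerateInputError("voltage never reached the tau criterion")
    k = int(crossed[0])
    if k == 0:
        t_cross = 0.0
    else:
        # linear interpolation between samples k-1 and k
        v0, v1 = seg_full[k - 1], seg_full[k]
        frac = (target - v0) / (v1 - v0) if v1 != v0 else 0.0
        t_cross = (k - 1 + frac) * sweep.dt
    # calibrate the fractional crossing time to an exponential's tau
    tau = t_cross / (-np.log(1.0 - config.tau_fraction))
    c_m = 1000.0 * tau / r_init if r_init > 0 else np.nan
    return PassiveProps(R_in_initial=r_init, R_in_ss=r_ss, tau_m=tau,
                        C_m=c_m, V_rest=baseline, flags=flags)


def rheobase_from_steps(sweeps: list[Sweep],
                        config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Step rheobase: amplitude of the first (lowest) step producing at
    least ``min_spikes_step_rheobase`` spikes (default 3)."""
    if len(sweeps) < 2:
        raise DegenerateInputError("need at least two steps")
    amps, counts = [], []
    for sw in sweeps:
        win = _step_window(sw.command, config.min_step_amplitude / 2.0)
        if win is None:
            continue
        onset, offset, base_i, step_i = win
        train = detect_spikes(sw, config)
        in_step = ((train.threshold_indices >= onset)
                   & (train.threshold_indices < offset))
        amps.append(step_i - base_i)
        counts.append(int(np.sum(in_step)))
    order = np.argsort(amps)
    for i in order:
        if counts[i] >= config.min_spikes_step_rheobase:
            return float(amps[i])
    raise NotFoundError(
        "no step produced the required spike count",
        payload={"max_spike_count": max(counts) if counts else 0})


def rheobase_from_ramp(sweep: Sweep,
                       config: AnalysisConfig = DEFAULT_CONFIG) -> RampExcitability:
    """Ramp rheobase: command current at the first spike's threshold sample."""
    train = detect_spikes(sweep, config)
    if train.n_spikes == 0:
        raise NotFoundError("no spikes on the ramp")
    idx = int(train.threshold_indices[0])
    return RampExcitability(rheobase_I=float(sweep.command[idx]),
                            threshold_V=float(train.threshold_voltages[0]))


def classify_firing_type(sweep: Sweep,
                         config: AnalysisConfig = DEFAULT_CONFIG) -> FIResult:
    """Classify a rheobase-step sweep as delayed or immediate firing.

    Delayed: onset latency above the latency criterion (default 500 ms)
    with an accelerating rate; immediate: onset within the criterion with a
    flat or adapting rate. Other combinations are flagged unclassified.
    """
    win = _step_window(sweep.command, config.min_step_amplitude / 2.0)
    if win is None:
        raise DegenerateInputError("no current step found in command")
    onset, offset, _, _ = win
    train = detect_spikes(sweep, config)
    mask = ((train.threshold_indices >= onset)
            & (train.threshold_indices < offset))
    times = train.spike_times[mask]
    if times.size < 3:
        raise InsufficientFiringError(
            f"need >= 3 spikes to classify, got {times.size}")
    latency = float(times[0] - sweep.time[onset])
    rates = 1000.0 / np.diff(times)
    mid_t = 0.5 * (times[1:] + times[:-1]) / 1000.0  # s
    slope = float(np.polyfit(mid_t, rates, 1)[0]) if rates.size >= 2 else 0.0

    if latency > config.latency_criterion and slope > 0.0:
        ftype = "delayed"
    elif latency <= config.latency_criterion and slope <= config.flat_slope_tol:
        ftype = "immediate"
    else:
        ftype = "unclassified"
    mean_rate = float(np.mean(rates))
    return FIResult(firing_type=ftype, onset_latency=latency,
                    rate_slope=slope, rate_at_rheobase=mean_rate)


def acceleration_and_epic(sweep: Sweep,
                          config: AnalysisConfig = DEFAULT_CONFIG) -> RampExcitability:
    """Subthreshold trajectory analysis of a slow depolarizing ramp.

    Fits the initial passive (linear) phase of the membrane trajectory with
    an iteratively grown window, locates the acceleration onset where the
    voltage deviates from the line by more than the deviation criterion
    (default 1 mV, sustained ≥ 10 ms), extrapolates the line to the first
    spike's threshold voltage to obtain the hypothetical passive rheobase
    current, and reports ePIC = passive_rheobase − rheobase.
    """
    train = detect_spikes(sweep, config)
    if train.n_spikes == 0:
        raise NotFoundError("no spikes on the ramp")
    thr_idx = int(train.threshold_indices[0])
    thr_v = float(train.threshold_voltages[0])
    rheo_i = float(sweep.command[thr_idx])

    t, v, cmd = sweep.time, sweep.recorded, sweep.command
    # ramp onset: first command sample above baseline
    moving = np.abs(cmd - cmd[0]) > 1e-9
    i0 = int(np.argmax(moving)) if moving.any() else 0
    i1 = thr_idx
    n = i1 - i0
    if n < 20:
        raise DegenerateInputError("pre-spike ramp segment too short")

    # iteratively grown linear fit of the passive phase
    end = i0 + max(10, n // 4)
    while True:
        coef = np.polyfit(t[i0:end], v[i0:end], 1)
        dev = v[i0:i1] - np.polyval(coef, t[i0:i1])
        beyond = dev[end - i0:]
        ok = np.abs(beyond) <= config.deviation_criterion
        if ok.all():
            end = i1
            coef = np.polyfit(t[i0:end], v[i0:end], 1)
            break
        k = int(np.argmin(ok))  # first violation
        if k == 0:
            break
        end = end + k

    def _find_onset(coef, start):
        dev = v[i0:i1] - np.polyval(coef, t[i0:i1])
        sustain = max(1, int(round(config.sustain_ms / sweep.dt)))
        above = dev > config.deviation_criterion
        if not above.any():
            return None
        # first run of `sustain` consecutive deviating samples (a run that
        # extends to the spike threshold also counts)
        run = 0
        for j in range(start - i0, i1 - i0):
            run = run + 1 if above[j] else 0
            if run >= sustain:
                return i0 + j - run + 1
        if above[-1]:
            j = i1 - i0 - 1
            while j >= 0 and above[j]:
                j -= 1
            return i0 + j + 1
        return None

    onset_idx = _find_onset(coef, end)
    if onset_idx is not None:
        # refinement: refit the passive line away from the onset region so
        # the early deviation cannot tilt it, then re-locate the onset
        fit_end = i0 + max(10, int(0.9 * (onset_idx - i0)))
        if fit_end > i0 + 10:
            coef = np.polyfit(t[i0:fit_end], v[i0:fit_end], 1)
            onset_idx = _find_onset(coef, fit_end)

    slope_v = coef[0]  # mV/ms
    # command trend over the ramp (pA/ms), for extrapolating passive rheobase
    ccoef = np.polyfit(t[i0:i1], cmd[i0:i1], 1)
    passive_slope = slope_v / ccoef[0] if ccoef[0] != 0 else np.nan

    res = RampExcitability(rheobase_I=rheo_i, threshold_V=thr_v,
                           passive_slope=passive_slope)
    if onset_idx is None:
        res.ePIC = 0.0
        res.passive_rheobase_I = rheo_i
        res.flags.append("onset_undetected")
        return res
    t_star = (thr_v - coef[1]) / coef[0]
    res.passive_rheobase_I = float(np.polyval(ccoef, t_star))
    res.ePIC = res.passive_rheobase_I - rheo_i
    res.accel_onset_V = float(v[onset_idx])
    res.accel_onset_I = float(cmd[onset_idx])
    res.accel_amplitude = thr_v - res.accel_onset_V
    return res


def triangle_hysteresis(sweep: Sweep,
                        config: AnalysisConfig = DEFAULT_CONFIG) -> TriangleResult:
    """Recruitment/derecruitment analysis of a triangular current ramp.

    ΔI = derecruitment current (last spike, descending limb) minus
    recruitment current (first spike, ascending limb); negative ΔI marks
    PIC-mediated sustained firing. The hysteresis type compares ascending
    and descending FI branches at matched currents.
    """
    train = detect_spikes(sweep, config)
    if train.n_spikes < 2:
        raise InsufficientFiringError(
            f"need >= 2 spikes on the triangle, got {train.n_spikes}")
    cmd = sweep.command
    i_rec = float(cmd[train.threshold_indices[0]])
    i_derec = float(cmd[train.threshold_indices[-1]])
    delta_i = i_derec - i_rec
    isis = np.diff(train.spike_times)
    max_rate = float(1000.0 / isis.min())

    # branch rates vs command current at ISI midpoints
    apex = int(np.argmax(cmd))
    mid_idx = ((train.threshold_indices[1:] + train.threshold_indices[:-1])
               // 2).astype(int)
    rates = 1000.0 / isis
    mid_i = cmd[mid_idx]
    asc = mid_idx <= apex
    desc = ~asc
    diff = np.nan
    if asc.sum() >= 1 and desc.sum() >= 1:
        lo = max(mid_i[desc].min(), mid_i[asc].min())
        hi = min(mid_i[desc].max(), mid_i[asc].max())
        if hi > lo:
            grid = np.linspace(lo, hi, 25)
            a_ord = np.argsort(mid_i[asc])
            d_ord = np.argsort(mid_i[desc])
            ra = np.interp(grid, mid_i[asc][a_ord], rates[asc][a_ord])
            rd = np.interp(grid, mid_i[desc][d_ord], rates[desc][d_ord])
            diff = float(np.mean(rd - ra))

    if not np.isnan(diff) and diff > HYSTERESIS_RATE_TOL_HZ:
        htype = 4  # counterclockwise
    elif delta_i < -DELTA_I_TOL_PA:
        htype = 3  # sustained
    elif (not np.isnan(diff) and diff < -HYSTERESIS_RATE_TOL_HZ) \
            or delta_i > DELTA_I_TOL_PA:
        htype = 2  # adapting (clockwise)
    else:
        htype = 1  # linear
    return TriangleResult(I_recruit=i_rec, I_derecruit=i_derec,
                          delta_I=delta_i, hysteresis_type=htype,
                          max_rate=max_rate)


def sag_analysis(sweeps: list[Sweep],
                 config: AnalysisConfig = DEFAULT_CONFIG) -> SagResult:
    """Depolarizing sag and sag conductance from hyperpolarizing steps.

    Per step the sag amplitude is the steady-state plateau minus the early
    trough (positive = depolarizing sag). Across ≥ 2 steps the initial and
    steady-state input resistances come from the slopes of the trough and
    plateau I–V relations, and gSag = 1000/R_ss − 1000/R_init (nS from MΩ);
    a negative gSag indicates a slow hyperpolarization instead of a sag.
    """
    amps, sags, troughs, plateaus = [], [], [], []
    flags = []
    for sw in sweeps:
        win = _step_window(sw.command, config.min_step_amplitude / 2.0)
        if win is None:
            continue
        onset, offset, base_i, step_i = win
        v = sw.recorded
        baseline = float(np.mean(v[max(0, onset - int(100.0 / sw.dt)):onset]))
        trough_end = min(offset, onset + int(round(200.0 / sw.dt)))
        v_tr = float(np.min(v[onset:trough_end]))
        plateau_start = max(onset, offset - int(round(100.0 / sw.dt)))
        v_ss = float(np.mean(v[plateau_start:offset]))
        amps.append(step_i - base_i)
        troughs.append(v_tr - baseline)
        plateaus.append(v_ss - baseline)
        sags.append(v_ss - v_tr)
    amps = np.asarray(amps)
    res = SagResult(step_amplitudes=amps,
                    sag_amplitudes=np.asarray(sags),
                    trough_V=np.asarray(troughs),
                    plateau_V=np.asarray(plateaus),
                    flags=flags)
    if amps.size < 2:
        flags.append("g_sag_undefined")
        return res
    r_init = np.polyfit(amps, res.trough_V, 1)[0] * 1000.0   # MΩ
    r_ss = np.polyfit(amps, res.plateau_V, 1)[0] * 1000.0
    res.R_in_initial = float(r_init)
    res.R_in_ss = float(r_ss)
    res.g_sag = float(1000.0 / r_ss - 1000.0 / r_init)
    return res


def spike_ahp_features(sweep: Sweep,
                       config: AnalysisConfig = DEFAULT_CONFIG) -> APWaveform:
    """Single-spike waveform and mAHP measures from a brief pulse sweep.

    Requires exactly one spike. Threshold by the dV/dt criterion; amplitude,
    rise time and half-width measured from threshold; mAHP amplitude and
    half-width measured from the pre-pulse baseline.
    """
    train = detect_spikes(sweep, config)
    if train.n_spikes != 1:
        raise InvalidSweepError(
            f"expected exactly one spike, found {train.n_spikes}")
    v, t = sweep.recorded, sweep.time
    thr_idx = int(train.threshold_indices[0])
    pk_idx = int(train.peak_indices[0])
    thr_v = float(v[thr_idx])
    amp = float(v[pk_idx] - thr_v)
    rise = float(t[pk_idx] - t[thr_idx])

    half = thr_v + amp / 2.0
    end = len(v) - 1

    # rising half-amplitude crossing (threshold -> peak)
    i = thr_idx
    while i < pk_idx and v[i + 1] < half:
        i += 1
    frac = (half - v[i]) / (v[i + 1] - v[i]) if v[i + 1] != v[i] else 0.0
    t_up = t[i] + frac * sweep.dt

    # falling half-amplitude crossing (after the peak)
    i = pk_idx
    while i < end and v[i] > half:
        i += 1
    if i >= end:
        half_width = np.nan
    else:
        frac = (half - v[i - 1]) / (v[i] - v[i - 1])
        t_dn = t[i - 1] + frac * sweep.dt
        half_width = float(t_dn - t_up)

    # mAHP from baseline
    win = _step_window(sweep.command, config.min_step_amplitude / 2.0)
    onset = win[0] if win else thr_idx
    baseline = float(np.mean(v[max(0, onset - int(50.0 / sweep.dt)):onset]))
    flags = []
    # search after the spike has repolarized below threshold
    j = pk_idx
    while j < end and v[j] > thr_v:
        j += 1
    post = v[j:]
    if post.size == 0 or np.min(post) >= baseline - 0.1:
        mahp_amp = 0.0
        mahp_hw = np.nan
        flags.append("mahp_absent")
    else:
        tr_rel = int(np.argmin(post))
        mahp_amp = float(baseline - post[tr_rel])
        level = baseline - mahp_amp / 2.0
        # crossings around the trough
        a = tr_rel
        while a > 0 and post[a] < level:
            a -= 1
        b = tr_rel
        while b < post.size - 1 and post[b] < level:
            b += 1
        if a == 0 or b == post.size - 1:
            mahp_hw = np.nan
            flags.append("mahp_halfwidth_unresolved")
        else:
            ta = t[j + a] + (level - post[a]) / (post[a + 1] - post[a]) * sweep.dt \
                if post[a + 1] != post[a] else t[j + a]
            tb = t[j + b - 1] + (level - post[b - 1]) / (post[b] - post[b - 1]) \
                * sweep.dt if post[b] != post[b - 1] else t[j + b]
            mahp_hw = float(tb - ta)
    return APWaveform(threshold_V=thr_v, amplitude=amp, rise_time=rise,
                      half_width=half_width, mAHP_amplitude=mahp_amp,
                      mAHP_half_width=mahp_hw, flags=flags)


def _steady_rate(times: np.ndarray) -> float:
    """Mean instantaneous rate over the later half of a spike train (Hz)."""
    if times.size < 2:
        return np.nan
    rates = 1000.0 / np.diff(times)
    half = rates.size // 2
    return float(np.mean(rates[half:])) if rates.size > 1 else float(rates[0])


def fi_analysis(step_sweeps: list[Sweep],
                triangle: Sweep | None = None,
                config: AnalysisConfig = DEFAULT_CONFIG) -> FIResult:
    """Frequency–current analysis over a suprathreshold step family.

    Computes the mean steady-state rate per step, the sub-primary-range
    gain as the slope of a line fitted to the initial FI section (first
    four suprathreshold points, or fewer if the local slope drops by more
    than 50%), rates at rheobase and 2× rheobase, and the maximum rate
    (minimum ISI on the triangle sweep when provided).
    """
    amps, rates = [], []
    for sw in step_sweeps:
        win = _step_window(sw.command, config.min_step_amplitude / 2.0)
        if win is None:
            continue
        onset, offset, base_i, step_i = win
        train = detect_spikes(sw, config)
        mask = ((train.threshold_indices >= onset)
                & (train.threshold_indices < offset))
        times = train.spike_times[mask]
        if times.size >= 2:
            amps.append(step_i - base_i)
            rates.append(_steady_rate(times))
    if len(amps) < 3:
        raise InsufficientFiringError(
            f"need >= 3 suprathreshold steps, got {len(amps)}")
    order = np.argsort(amps)
    amps = np.asarray(amps)[order]
    rates = np.asarray(rates)[order]
    # merge duplicate amplitudes (families may repeat a level)
    uniq, inv = np.unique(amps, return_inverse=True)
    rates = np.bincount(inv, weights=rates) / np.bincount(inv)
    amps = uniq
    if amps.size < 3:
        raise InsufficientFiringError(
            f"need >= 3 distinct suprathreshold levels, got {amps.size}")

    # initial FI section: up to 4 points, stopping if the local slope drops
    # by more than 50% of the first segment's slope
    n_use = 2
    s0 = (rates[1] - rates[0]) / (amps[1] - amps[0])
    for k in range(2, min(4, len(amps))):
        sk = (rates[k] - rates[k - 1]) / (amps[k] - amps[k - 1])
        if s0 > 0 and sk < 0.5 * s0:
            break
        n_use = k + 1
    gain = float(np.polyfit(amps[:n_use], rates[:n_use], 1)[0])

    res = FIResult(subprimary_gain=gain, gain_points=n_use,
                   rate_at_rheobase=float(rates[0]))
    rheo = amps[0]
    idx2 = int(np.argmin(np.abs(amps - 2.0 * rheo)))
    res.rate_at_2x_rheobase = float(rates[idx2])
    if triangle is not None:
        tri = triangle_hysteresis(triangle, config)
        res.max_rate = tri.max_rate
    else:
        res.max_rate = float(np.max(rates))
        res.flags.append("max_rate_from_steps")
    return res
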