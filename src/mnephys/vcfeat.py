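"""Voltage-clamp feature extraction.

Persistent inward currents (PICs) are measured from slow depolarizing
voltage ramps (10 mV/s, −90 → −10 mV): the recorded current is low-pass
filtered (5 Hz Bessel, 4-pole, zero-phase), a leak line is fitted over a
subthreshold window (default −90 to −75 mV, below NaP activation) and
subtracted, and PIC onset/peak/amplitude/density are read from the
subtracted trace. Ih is quantified from 1 s hyperpolarizing voltage steps
(−60 → −110 mV in 10 mV increments) as the initial-minus-steady-state
current difference, with the activation time read at 2/3 of the peak
difference; a resting Ih uses the same differencing on a single step from
−50 mV to the cell's resting potential. Drug-sensitive currents are
pointwise differences between protocol-matched sweep families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import bessel, sosfiltfilt

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import (InvalidArgumentError, InvalidProtocolError,
                     ProtocolMismatchError)
from .sweep import Sweep, VOLTAGE_CLAMP


@dataclass
class LeakSubtractedTrace:
    """Leak-subtracted, low-pass filtered ramp current vs command voltage."""
    command_V: np.ndarray   # mV
    current: np.ndarray     # pA, leak-subtracted
    filtered: np.ndarray    # pA, filtered but not subtracted
    leak_slope: float       # nS
    leak_intercept: float   # pA (at 0 mV)
    fit_window: tuple = (np.nan, np.nan)   # mV window used for the leak fit
    flags: list = field(default_factory=list)


@dataclass
class PICMeasures:
    onset_V: float        # mV
    peak_V: float         # mV
    amplitude: float      # pA (peak inward, <= 0)
    density: float        # pA/pF
    leak_slope: float     # nS
    leak_intercept: float  # pA
    filtered: bool = True
    flags: list = field(default_factory=list)


@dataclass
class IhMeasures:
    command_V: np.ndarray     # mV per step
    amplitude: np.ndarray     # pA per step (I_ss - I_initial, inward < 0)
    tau: np.ndarray           # ms per step (time to 2/3 of peak Ih)
    density: np.ndarray       # pA/pF per step
    resting_Ih: float = np.nan
    resting_Ih_density: float = np.nan
    flags: list = field(default_factory=list)


def _require_vc(sweep: Sweep):
    if sweep.mode != VOLTAGE_CLAMP:
        raise InvalidProtocolError("voltage-clamp sweep required")


def lowpass_bessel(current: np.ndarray, sample_rate_hz: float,
                   corner_hz: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase 4-pole Bessel low-pass (forward-backward)."""
    sos = bessel(order, corner_hz, btype="low", fs=sample_rate_hz,
                 output="sos", norm="mag")
    return sosfiltfilt(sos, current)


#: Width of the sliding window used by the "auto" leak fit (mV).
AUTO_LEAK_WINDOW_MV = 15.0
#: "auto" leak windows must end below this voltage (above it PICs engage).
AUTO_LEAK_CEILING_MV = -55.0


def _most_linear_window(cmd_v: np.ndarray, current: np.ndarray):
    """(lo, hi) of the 15 mV stretch with the smallest maximum deviation
    from its own line fit, among windows ending below the ceiling."""
    v_lo = float(cmd_v.min())
    best = None
    lo = v_lo
    while lo + AUTO_LEAK_WINDOW_MV <= AUTO_LEAK_CEILING_MV + 1e-9:
        hi = lo + AUTO_LEAK_WINDOW_MV
        m = (cmd_v >= lo) & (cmd_v <= hi)
        if m.sum() >= 10:
            coef = np.polyfit(cmd_v[m], current[m], 1)
            score = float(np.max(np.abs(current[m]
                                        - np.polyval(coef, cmd_v[m]))))
            if best is None or score < best[0]:
                best = (score, lo, hi)
        lo += 1.0
    if best is None:
        raise InvalidArgumentError(
            "ramp span too short for an automatic leak window")
    return best[1], best[2]


def leak_subtract(sweep: Sweep,
                  fit_window: tuple[float, float] | None = None,
                  config: AnalysisConfig = DEFAULT_CONFIG) -> LeakSubtractedTrace:
    """Filter a voltage-ramp current sweep and subtract the ohmic leak.

    The leak line is fitted to filtered current vs command voltage over
    ``fit_window`` (mV; default from config, −90 to −75). Passing
    ``fit_window="auto"`` instead selects the most linear 15 mV stretch of
    the subthreshold trace (lowest maximum residual, windows ending below
    −55 mV) — the programmatic analogue of an analyst fitting the visually
    linear region, which matters for cells whose resting HCN conductance
    bends the trace near the hyperpolarized end of the ramp. Filtering is
    zero-phase so the subtracted trace stays aligned with the command
    voltage axis; brief escape-spike transients are suppressed rather than
    blanked.
    """
    _require_vc(sweep)
    auto = isinstance(fit_window, str) and fit_window == "auto"
    if fit_window is None:
        fit_window = config.leak_fit_window

    filt = lowpass_bessel(sweep.recorded, sweep.sample_rate,
                          config.pic_filter_hz)
    # restrict to the rising ramp segment
    cmd = sweep.command
    ramp = np.nonzero(np.diff(cmd) > 0)[0]
    i0, i1 = int(ramp[0]), int(ramp[-1] + 1)
    cmd_r = cmd[i0:i1 + 1]
    filt_r = filt[i0:i1 + 1]

    if auto:
        lo, hi = _most_linear_window(cmd_r, filt_r)
    else:
        lo, hi = sorted(fit_window)
        if lo < cmd.min() - 1e-9 or hi > cmd.max() + 1e-9:
            raise InvalidArgumentError(
                f"fit window ({lo}, {hi}) mV outside ramp span "
                f"({cmd.min():.1f}, {cmd.max():.1f}) mV")

    mask = (cmd_r >= lo) & (cmd_r <= hi)
    if mask.sum() < 10:
        raise InvalidArgumentError("fit window contains too few samples")
    slope, intercept = np.polyfit(cmd_r[mask], filt_r[mask], 1)
    flags = []
    if slope <= 0:
        flags.append("non_ohmic_leak")
    subtracted = filt_r - (slope * cmd_r + intercept)
    return LeakSubtractedTrace(command_V=cmd_r, current=subtracted,
                               filtered=filt_r, leak_slope=float(slope),
                               leak_intercept=float(intercept),
                               fit_window=(float(lo), float(hi)), flags=flags)


def pic_measures(subtracted: LeakSubtractedTrace, C_m: float,
                 onset_criterion: float | None = None,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> PICMeasures:
    """PIC onset, peak voltage, amplitude and density from a
    leak-subtracted ramp trace.

    Onset is the first command voltage where the subtracted current stays
    below ``onset_criterion`` (default −10 pA) over ≥ 1 mV of command;
    the peak is the most negative subtracted current before net outward
    rectification, and density = amplitude/C_m.
    """
    if onset_criterion is None:
        onset_criterion = config.pic_onset_criterion
    v = subtracted.command_V
    i_sub = subtracted.current
    n = v.size

    # terminal outward rectification: the trailing run where the subtracted
    # current has gone and stayed positive (delayed-rectifier dominated)
    rect_start = n
    k = n - 1
    while k >= 0 and i_sub[k] > 0.0:
        k -= 1
    if k < n - 1:
        rect_start = k + 1

    seg = i_sub[:rect_start]
    if seg.size == 0 or seg.min() >= onset_criterion:
        return PICMeasures(onset_V=np.nan, peak_V=np.nan, amplitude=0.0,
                           density=0.0, leak_slope=subtracted.leak_slope,
                           leak_intercept=subtracted.leak_intercept,
                           flags=["pic_absent"])
    peak_idx = int(np.argmin(seg))

    # onset: start of the contiguous below-criterion run containing the
    # peak, requiring the run to span >= 1 mV of command
    j = peak_idx
    while j > 0 and i_sub[j - 1] < onset_criterion:
        j -= 1
    onset_idx = j
    k = peak_idx
    while k < rect_start - 1 and i_sub[k + 1] < onset_criterion:
        k += 1
    if v[k] - v[onset_idx] < 1.0:
        return PICMeasures(onset_V=np.nan, peak_V=np.nan, amplitude=0.0,
                           density=0.0, leak_slope=subtracted.leak_slope,
                           leak_intercept=subtracted.leak_intercept,
                           flags=["pic_absent"])

    flags = []
    # flag additional deep local minima outside the peak's neighbourhood
    local_min = (np.diff(np.sign(np.diff(seg))) > 0).nonzero()[0] + 1
    deep = [m for m in local_min
            if seg[m] < 0.9 * seg[peak_idx] and abs(m - peak_idx) > 5]
    if deep:
        flags.append("multimodal_inward_current")
    amp = float(seg[peak_idx])
    return PICMeasures(onset_V=float(v[onset_idx]), peak_V=float(v[peak_idx]),
                       amplitude=amp, density=amp / C_m,
                       leak_slope=subtracted.leak_slope,
                       leak_intercept=subtracted.leak_intercept, flags=flags)


def _step_levels(sweep: Sweep):
    """(onset, offset, holding_mV, step_mV) of a voltage-clamp step."""
    cmd = sweep.command
    base = cmd[0]
    dev = np.abs(cmd - base) > 0.5
    if not dev.any():
        return None
    onset = int(np.argmax(dev))
    offset = int(len(cmd) - np.argmax(dev[::-1]))
    return onset, offset, float(base), float(np.median(cmd[onset:offset]))


#: Initial-current window after the capacitive transient (ms post-onset).
IH_INITIAL_WINDOW_MS = (5.0, 20.0)
#: Steady-state window: final portion of the step (ms).
IH_STEADY_WINDOW_MS = 100.0
#: Initial-window SD above which the transient is flagged unsettled (pA).
IH_TRANSIENT_SD_PA = 50.0


def _ih_single_step(sweep: Sweep, config: AnalysisConfig):
    """(step_V, amplitude_pA, tau_ms, flags) for one hyperpolarizing step."""
    win = _step_levels(sweep)
    if win is None:
        # command never leaves holding (e.g. the −60 → −60 step of a
        # family): zero-amplitude measurement at the holding level
        return float(sweep.command[0]), 0.0, np.nan, ["zero_amplitude_step"]
    onset, offset, base_v, step_v = win
    i = sweep.recorded
    dt = sweep.dt
    w0 = onset + int(IH_INITIAL_WINDOW_MS[0] / dt)
    w1 = onset + int(IH_INITIAL_WINDOW_MS[1] / dt)
    flags = []
    i_init = float(np.mean(i[w0:w1]))
    if float(np.std(i[w0:w1])) > IH_TRANSIENT_SD_PA:
        flags.append("transient_unsettled")
    # keep clear of the offset capacitive transient (1 ms guard)
    off_g = offset - max(1, int(round(1.0 / dt)))
    ss0 = max(onset, off_g - int(IH_STEADY_WINDOW_MS / dt))
    i_ss = float(np.mean(i[ss0:off_g]))
    amplitude = i_ss - i_init

    # time from step onset to tau_fraction (2/3) of the peak Ih
    target = i_init + config.tau_fraction * amplitude
    seg = i[onset:off_g]
    if amplitude < 0:
        crossed = np.nonzero(seg <= target)[0]
    else:
        crossed = np.nonzero(seg >= target)[0]
    # ignore crossings inside the capacitive transient
    crossed = crossed[crossed >= (w0 - onset)]
    tau = float(crossed[0] * dt) if crossed.size else np.nan
    return step_v, amplitude, tau, flags


def ih_from_steps(sweeps: list[Sweep], C_m: float,
                  config: AnalysisConfig = DEFAULT_CONFIG) -> IhMeasures:
    """Ih amplitude, activation time and density per hyperpolarizing step.

    Amplitude is the steady-state minus initial current (inward negative
    for HCN); the activation time constant proxy is the time from step
    onset to 2/3 of the amplitude (τ·ln 3 for a single exponential).
    """
    rows = []
    all_flags = []
    for sw in sweeps:
        _require_vc(sw)
        step_v, amp, tau, flags = _ih_single_step(sw, config)
        rows.append((step_v, amp, tau))
        all_flags.append(flags)
    rows.sort(key=lambda r: -r[0])  # order by command, −60 first
    v = np.array([r[0] for r in rows])
    amp = np.array([r[1] for r in rows])
    tau = np.array([r[2] for r in rows])
    flat = [f for fl in all_flags for f in fl]
    return IhMeasures(command_V=v, amplitude=amp, tau=tau,
                      density=amp / C_m, flags=flat)


def resting_ih(sweep: Sweep, C_m: float, rmp: float,
               config: AnalysisConfig = DEFAULT_CONFIG) -> IhMeasures:
    """Resting Ih from a single step, −50 mV down to the cell's RMP."""
    _require_vc(sweep)
    if rmp >= -50.0:
        raise InvalidProtocolError(
            f"resting potential {rmp:.1f} mV is not below the −50 mV holding")
    step_v, amp, tau, flags = _ih_single_step(sweep, config)
    return IhMeasures(command_V=np.array([step_v]),
                      amplitude=np.array([amp]), tau=np.array([tau]),
                      density=np.array([amp / C_m]),
                      resting_Ih=amp, resting_Ih_density=amp / C_m,
                      flags=flags)


def drug_sensitive_current(before: list[Sweep], after: list[Sweep],
                           config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Steady-state difference current (after − before) per command level.

    Protocols must match exactly (commands, durations, sample rate).
    Returns ``{"command_V": array, "delta_pA": array, "at_-70": float,
    "at_-110": float}`` with NaN summaries when a level is absent.
    """
    if len(before) != len(after):
        raise ProtocolMismatchError("sweep counts differ",
                                    fields=["n_sweeps"])
    levels, deltas = [], []
    for sb, sa in zip(before, after):
        mism = []
        if sb.n_samples != sa.n_samples:
            mism.append("n_samples")
        if abs(sb.dt - sa.dt) > 1e-9:
            mism.append("sample_rate")
        if sb.n_samples == sa.n_samples and \
                not np.allclose(sb.command, sa.command):
            mism.append("command")
        if mism:
            raise ProtocolMismatchError(
                f"protocols differ in {mism}", fields=mism)
        win = _step_levels(sb)
        if win is None:
            continue
        onset, offset, _, step_v = win
        off_g = offset - max(1, int(round(1.0 / sb.dt)))
        ss0 = max(onset, off_g - int(IH_STEADY_WINDOW_MS / sb.dt))
        delta = float(np.mean(sa.recorded[ss0:off_g])
                      - np.mean(sb.recorded[ss0:off_g]))
        levels.append(step_v)
        deltas.append(delta)
    levels = np.asarray(levels)
    deltas = np.asarray(deltas)

    def _at(v):
        hit = np.nonzero(np.abs(levels - v) < 1.0)[0]
        return float(deltas[hit[0]]) if hit.size else np.nan

    return {"command_V": levels, "delta_pA": deltas,
            "at_-70": _at(-70.0), "at_-110": _at(-110.0)}
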