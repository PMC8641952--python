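"""Sweep and protocol containers.

Units are fixed across the whole pipeline: millivolts, picoamps,
milliseconds. A :class:`Sweep` is one clamp-mode recording — the recorded
trace, the command waveform that produced it, and uniform sample times.
In current clamp ``recorded`` is membrane potential (mV) and ``command``
injected current (pA, excluding any standing bias current, which is kept in
``meta['bias_pA']``); in voltage clamp the roles of the units swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidProtocolError, InvalidSweepError

CURRENT_CLAMP = "current"
VOLTAGE_CLAMP = "voltage"

#: Acquisition default matching a 20 kHz digitiser.
DEFAULT_SAMPLE_RATE_HZ = 20_000.0


@dataclass
class Sweep:
    """One clamp-mode recording with its command waveform.

    Attributes
    ----------
    time : np.ndarray
        Sample times in ms, strictly increasing and uniformly spaced.
    recorded : np.ndarray
        mV in current clamp, pA in voltage clamp.
    command : np.ndarray
        pA in current clamp, mV in voltage clamp.
    mode : str
        ``"current"`` or ``"voltage"``.
    meta : dict
        Protocol identity, cell identity, drug condition, and (for
        synthetic sweeps) a ground-truth parameter manifest.
    """

    time: np.ndarray
    recorded: np.ndarray
    command: np.ndarray
    mode: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.recorded = np.asarray(self.recorded, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise InvalidSweepError(f"unknown clamp mode {self.mode!r}")
        n = self.time.size
        if self.recorded.size != n or self.command.size != n:
            raise InvalidSweepError(
                "time, recorded and command must have equal length "
                f"(got {n}, {self.recorded.size}, {self.command.size})"
            )
        if n >= 2:
            dts = np.diff(self.time)
            if dts.min() <= 0:
                raise InvalidSweepError("time must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise InvalidSweepError("time must be uniformly spaced")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        """Sample rate in Hz."""
        return 1000.0 / self.dt

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class ProtocolSpec:
    """Declarative description of a stimulation protocol.

    ``holding`` is the pre-stimulus membrane potential target in mV: in
    current clamp a bias current is solved so the cell rests there; in
    voltage clamp it is the commanded holding potential. ``amplitudes`` are
    stimulus amplitudes relative to holding (pA in current clamp, absolute
    mV targets in voltage clamp for step protocols). ``rate`` is the ramp
    slope (pA/s or mV/s). ``durations`` is (pre, stimulus, post) in ms.
    """

    mode: str
    kind: str  # step | ramp | triangle | step_family | pulse
    holding: float
    amplitudes: tuple = ()
    rate: float = 0.0
    durations: tuple = (500.0, 5000.0, 500.0)
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ

    _KINDS = ("step", "ramp", "triangle", "step_family", "pulse")

    def __post_init__(self):
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise InvalidProtocolError(f"unknown clamp mode {self.mode!r}")
        if self.kind not in self._KINDS:
            raise InvalidProtocolError(f"unknown protocol kind {self.kind!r}")
        if self.sample_rate <= 0:
            raise InvalidProtocolError("sample_rate must be positive")
        if any(d <= 0 for d in self.durations[:2]):
            raise InvalidProtocolError("pre and stimulus durations must be positive")
        if self.kind in ("ramp", "triangle") and self.rate == 0.0:
            raise InvalidProtocolError(f"{self.kind} protocol needs a nonzero rate")
        self.amplitudes = tuple(float(a) for a in self.amplitudes)

    @property
    def dt(self) -> float:
        return 1000.0 / self.sample_rate

    def command_waveforms(self):
        """Build one command array per sweep (stimulus relative to holding in
        current clamp; absolute mV in voltage clamp).

        Returns ``(time_ms, [command, ...])``. Triangle protocols have equal
        rise and fall times (the stimulus duration covers the rise; the fall
        mirrors it, so the sweep is pre + 2*stim + post long).
        """
        dt = self.dt
        pre, stim, post = self.durations
        n_pre = int(round(pre / dt))
        n_stim = int(round(stim / dt))
        n_post = int(round(post / dt))
        base = self.holding if self.mode == VOLTAGE_CLAMP else 0.0

        commands = []
        if self.kind in ("step", "step_family", "pulse"):
            n = n_pre + n_stim + n_post
            for amp in self.amplitudes:
                cmd = np.full(n, base)
                cmd[n_pre:n_pre + n_stim] = amp
                commands.append(cmd)
        elif self.kind == "ramp":
            n = n_pre + n_stim + n_post
            ramp = self.rate / 1000.0 * dt * np.arange(1, n_stim + 1)  # rate is per s
            cmd = np.full(n, base)
            cmd[n_pre:n_pre + n_stim] = base + ramp
            cmd[n_pre + n_stim:] = base + (ramp[-1] if n_stim else 0.0)
            commands.append(cmd)
        elif self.kind == "triangle":
            n = n_pre + 2 * n_stim + n_post
            up = self.rate / 1000.0 * dt * np.arange(1, n_stim + 1)
            cmd = np.full(n, base)
            cmd[n_pre:n_pre + n_stim] = base + up
            cmd[n_pre + n_stim:n_pre + 2 * n_stim] = base + up[::-1]
            commands.append(cmd)
        else:  # pragma: no cover - guarded in __post_init__
            raise InvalidProtocolError(self.kind)

        n_total = len(commands[0])
        t = np.arange(n_total) * dt
        return t, commands


def triangle_peak_rate(peak_pA: float, rise_ms: float = 5000.0) -> float:
    """Ramp slope (pA/s) for a triangular ramp reaching ``peak_pA`` in
    ``rise_ms`` (default 5 s rise and fall times)."""
    if rise_ms <= 0:
        raise InvalidProtocolError("rise time must be positive")
    return peak_pA / (rise_ms / 1000.0)
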