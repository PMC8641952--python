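"""Analysis configuration.

All numeric criteria used by the feature extractors live here so a whole
study can be re-analysed under one declared configuration. Defaults follow
standard motoneuron patch-clamp practice: a 10 mV/ms derivative criterion
for spike threshold, a 1 mV deviation criterion for the onset of the
subthreshold acceleration phase, 100 pA/s ramps, and a three-spike rule for
step rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import yaml

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class AnalysisConfig:
    #: Spike-threshold derivative criterion (mV/ms).
    dvdt_threshold: float = 10.0
    #: Deviation from the passive linear fit marking acceleration onset (mV).
    deviation_criterion: float = 1.0
    #: Depolarizing ramp slope (pA/s).
    ramp_rate: float = 100.0
    #: Minimum spike count defining step rheobase.
    min_spikes_step_rheobase: int = 3
    #: Fraction of peak deflection at which the membrane time constant and
    #: the Ih activation time are read out (2/3 of peak).
    tau_fraction: float = 2.0 / 3.0
    #: Boxcar smoothing window applied before differentiation (ms).
    smoothing: float = 0.2
    #: Onset-latency criterion separating delayed from immediate firing (ms).
    latency_criterion: float = 500.0
    #: |rate slope| below which a firing profile counts as flat (Hz/s).
    flat_slope_tol: float = 2.0
    #: Minimum |step amplitude| treated as a real stimulus (pA).
    min_step_amplitude: float = 5.0
    #: Sustained-deviation window for acceleration onset (ms).
    sustain_ms: float = 10.0
    #: Voltage-clamp PIC onset criterion (pA, inward negative).
    pic_onset_criterion: float = -10.0
    #: Leak-fit window for voltage-ramp PICs (mV), below NaP activation.
    leak_fit_window: tuple = (-90.0, -75.0)
    #: Low-pass corner applied to voltage-clamp ramp current (Hz).
    pic_filter_hz: float = 5.0

    def __post_init__(self):
        for name in ("dvdt_threshold", "deviation_criterion", "ramp_rate",
                     "smoothing", "latency_criterion", "min_step_amplitude"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if not 0.0 < self.tau_fraction < 1.0:
            raise InvalidArgumentError("tau_fraction must lie in (0, 1)")
        if self.min_spikes_step_rheobase < 1:
            raise InvalidArgumentError("min_spikes_step_rheobase must be >= 1")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["leak_fit_window"] = list(self.leak_fit_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "leak_fit_window" in d:
            d = dict(d, leak_fit_window=tuple(d["leak_fit_window"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
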