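"""Run configuration: every algorithm constant in one place.

Defaults are the published values; a YAML file can override any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigurationError, ValidationError
from .io_formats import ChannelRole, Stage


@dataclass
class RunConfig:
    # channel roles: label -> frontal|central|parietal|other
    roles: dict = field(default_factory=dict)
    channels: list = None              # subset of channels to analyse (None = all)
    stages: tuple = ("S2",)
    band_mode: str = "auto"            # "auto" or "fixed"
    fixed_slow: tuple = (11.0, 12.9)
    fixed_fast: tuple = (13.1, 16.0)
    fixed_stop: float = 9.0

    # algorithm constants (defaults are the published values)
    emg_threshold_uv: float = 5.75
    emg_pad_s: float = 3.0
    alpha_ratio: float = 1.1
    sa_factor: float = 55.0
    sp_factor: float = 80.0
    bt_spectrum_scale: float = 0.10
    bt_min_clean_s: float = 60.0
    min_duration_s: float = 0.5
    f0: float = 2.0
    grid_step_hz: float = 0.1
    smooth_window_hz: float = 0.7
    min_scan_spindles: int = 30
    agreement_resolution_s: float = 0.1
    min_overlap_s: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("emg_threshold_uv", "alpha_ratio", "sa_factor", "sp_factor",
                     "min_duration_s", "grid_step_hz", "smooth_window_hz",
                     "agreement_resolution_s", "min_overlap_s", "bt_spectrum_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.band_mode not in ("auto", "fixed"):
            raise ConfigurationError("band_mode must be 'auto' or 'fixed'")
        if self.band_mode == "fixed":
            from .band_adjust import SpindleBands, BandSource

            SpindleBands(self.fixed_slow, self.fixed_fast, self.fixed_stop,
                         source=BandSource.USER_FIXED)  # raises if invalid

    def stage_set(self) -> set:
        return {Stage(s) if not isinstance(s, Stage) else s for s in self.stages}

    def role_map(self) -> dict:
        return {k: ChannelRole(v) if not isinstance(v, ChannelRole) else v
                for k, v in self.roles.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fixed_slow", "fixed_fast", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
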