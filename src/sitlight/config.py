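"""Runtime configuration.

All tunable constants of the processing chain and the light mappings live in
one dataclass so that every stage reads the same defaults.  The defaults are
the values the system was designed around: a 400 ms beat-detection window,
a 40-beat recursive HRV window, sedentary time 10-30 min mapped to brightness
10-255, inter-beat intervals 550-1150 ms mapped to brightness 10-255, and a
breathing-mode saturation ceiling of 250 (deliberately distinct from the
intervention ceiling of 255).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class Config:
    # --- signal acquisition / BCG pipeline ---
    fs: float = 256.0                 # Hz; level-4 Haar detail band is fs/32..fs/16
    mad_window_ms: float = 150.0      # moving mean-absolute-deviation window
    beat_window_ms: float = 400.0     # moving-maximum beat detection window
    ibi_gate_lo_ms: float = 300.0     # validity gate: physiological range 40-200 bpm
    ibi_gate_hi_ms: float = 1500.0
    ibi_gate_rel_jump: float = 0.30   # max relative jump vs previous valid IBI
    hrv_window_beats: int = 40        # N in the recursive IBI_N / HRV_N estimator

    # --- ambient intervention mapping ---
    sedentary_lo_min: float = 10.0
    sedentary_hi_min: float = 30.0
    brightness_lo: float = 10.0
    brightness_hi: float = 255.0
    intervention_sat_lo: float = 10.0
    intervention_sat_hi: float = 255.0
    intervention_hue: float = 30.0    # orange

    # --- breathing biofeedback mapping ---
    biofeedback_ibi_lo_ms: float = 550.0
    biofeedback_ibi_hi_ms: float = 1150.0
    biofeedback_sat_lo: float = 10.0
    biofeedback_sat_hi: float = 250.0
    biofeedback_hue: float = 200.0    # user-choosable relaxing color

    # --- stretch guidance ---
    stretch_hue_start: float = 240.0  # blue cue
    stretch_hue_target: float = 120.0 # green on target
    lateral_shift_threshold: float = 0.35
    hold_duration_s: float = 3.0
    wipe_speed_leds_s: float = 14.0
    tick_hz: float = 20.0

    # --- posture / occupancy ---
    occupancy_threshold: float = 124.0  # ~20% of the seated-archetype total load
    breathing_slope_fraction: float = 0.10  # HRV rise per 30 s, as fraction of range

    # --- display ---
    n_leds: int = 28

    seed: int = 0

    def validate(self) -> "Config":
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        for name in ("mad_window_ms", "beat_window_ms", "hold_duration_s",
                     "tick_hz", "wipe_speed_leds_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.ibi_gate_lo_ms < self.ibi_gate_hi_ms):
            raise ConfigError("ibi gate must satisfy 0 < lo < hi")
        if self.hrv_window_beats < 1:
            raise ConfigError("hrv_window_beats must be >= 1")
        if self.n_leds < 1:
            raise ConfigError("n_leds must be >= 1")
        if not (0 < self.lateral_shift_threshold <= 1):
            raise ConfigError("lateral_shift_threshold must be in (0, 1]")
        return self


def config_from_dict(d: dict) -> Config:
    """Build a Config from a (possibly partial) mapping; unknown keys error."""
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return Config(**d).validate()


def load_config(path: str | Path) -> Config:
    """Load JSON or YAML; unspecified fields take the package defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2) + "\n")


DEFAULT_CONFIG = Config()
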