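"""Run configuration: one YAML file binding stimulus, staircase and observer
parameters into a reproducible workflow.

Chord indices in config files follow the 1-based convention used when
describing the stimuli (e.g. the detection figure "starts on chord 15-20");
they are converted to 0-based indices internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

_DEFAULTS = {
    "stimulus": {
        "task": "same_frequency",      # detection | same_frequency | coherent_roving | complex_roving
        "n_stimuli": 4,
        "tmr_db": 0.0,
        "sample_rate": 44100,
        "formant_track": "synthetic",  # path to CSV, fixture name, or "synthetic"
        "grid": {"f_min_hz": 179.0, "f_max_hz": 7246.0, "steps_per_octave": 24},
        "detection_onset_chords_1based": [15, 20],
    },
    "staircase": {
        "start_tmr_db": 6.0,
        "initial_step_db": 2.0,
        "final_step_db": 0.5,
        "step_switch_reversals": 3,
        "stop_reversals": 10,
        "max_trials": 200,
        "interleave": "alternate",
    },
    "observer": {
        "kind": "psychometric",        # psychometric | coherence
        "mu_db": 0.0,
        "slope_per_db": 1.0,
        "guess": 0.5,
        "lapse": 0.02,
        "window_chords": 10,
        "decision_noise": 1.0,
    },
    "detection": {"n_trials": 50},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k in override:
        if k not in base:
            raise ValueError(f"unknown config key: {k!r}")
    return out


@dataclass(frozen=True)
class RunConfig:
    stimulus: dict = field(default_factory=lambda: dict(_DEFAULTS["stimulus"]))
    staircase: dict = field(default_factory=lambda: dict(_DEFAULTS["staircase"]))
    observer: dict = field(default_factory=lambda: dict(_DEFAULTS["observer"]))
    detection: dict = field(default_factory=lambda: dict(_DEFAULTS["detection"]))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        merged = _merge(_DEFAULTS, d or {})
        return cls(**merged)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the defaults above."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
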