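"""Logarithmic frequency grid and the ERB-number (auditory filter) scale.

Tone-cloud stimuli draw their component frequencies from a fixed grid of
1/24th-octave-spaced frequencies between 179 and 7246 Hz.  Figure components
are additionally constrained to be separated by more than one equivalent
rectangular bandwidth (ERB), expressed on the Glasberg–Moore ERB-number
("cam") scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrequencyGrid", "build_frequency_grid", "erb_number"]

#: Default grid bounds (Hz) and resolution for the tone clouds.
DEFAULT_F_MIN = 179.0
DEFAULT_F_MAX = 7246.0
DEFAULT_STEPS_PER_OCTAVE = 24


@dataclass(frozen=True)
class FrequencyGrid:
    """An ordered geometric series of candidate tone frequencies.

    Consecutive frequencies are separated by exactly ``2**(1/steps_per_octave)``;
    the first frequency equals ``f_min`` and no frequency exceeds ``f_max``.
    """

    frequencies: np.ndarray
    f_min: float
    f_max: float
    steps_per_octave: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        ratios = f[1:] / f[:-1]
        expected = 2.0 ** (1.0 / self.steps_per_octave)
        if f.size > 1 and not np.allclose(ratios, expected, rtol=1e-9):
            raise ValueError("grid frequencies are not geometrically spaced")

    def __len__(self) -> int:
        return int(self.frequencies.size)

    def nearest_channel(self, frequency: float | np.ndarray) -> np.ndarray:
        """Index of the grid channel nearest (in log frequency) to ``frequency``."""
        logf = np.log(np.atleast_1d(np.asarray(frequency, dtype=float)))
        idx = np.argmin(np.abs(logf[:, None] - np.log(self.frequencies)[None, :]), axis=1)
        return idx if idx.size > 1 else idx[0]


def build_frequency_grid(
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    steps_per_octave: int = DEFAULT_STEPS_PER_OCTAVE,
) -> FrequencyGrid:
    """Enumerate ``f_min * 2**(k/steps_per_octave) <= f_max`` for k = 0, 1, 2, ...

    With the defaults this yields 129 frequencies spanning 179–7246 Hz at
    1/24th-octave separation.
    """
    if f_min <= 0:
        raise ValueError(f"f_min must be positive, got {f_min}")
    if f_max <= f_min:
        raise ValueError(f"f_max ({f_max}) must exceed f_min ({f_min})")
    if steps_per_octave < 1:
        raise ValueError(f"steps_per_octave must be >= 1, got {steps_per_octave}")
    n_octaves = np.log2(f_max / f_min)
    k_max = int(np.floor(n_octaves * steps_per_octave + 1e-12))
    k = np.arange(k_max + 1)
    freqs = f_min * 2.0 ** (k / steps_per_octave)
    # guard against floating overshoot at the top of the range
    freqs = freqs[freqs <= f_max * (1 + 1e-12)]
    return FrequencyGrid(
        frequencies=freqs, f_min=f_min, f_max=f_max, steps_per_octave=steps_per_octave
    )


def erb_number(frequency: float | np.ndarray) -> float | np.ndarray:
    """ERB-number (in cams) of ``frequency`` on the Glasberg–Moore scale.

    ``E(f) = 21.4 * log10(4.37 * f/1000 + 1)``.  Two tones are "more than one
    ERB apart" when their ERB-numbers differ by more than 1 cam.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    e = 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)
    return float(e) if np.isscalar(frequency) else e
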