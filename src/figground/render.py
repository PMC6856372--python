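"""Audio realisation of symbolic stimuli.

Each tone element becomes a sinusoid spanning its chords, gated by 10-ms
raised-cosine onset/offset ramps; chords abut with zero inter-chord
interval.  The summed waveform is peak-normalised to -1 dBFS.  Absolute
playback level is a presentation concern and out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .stimulus import FigureGroundStimulus

__all__ = ["RenderedAudio", "render_waveform", "write_wav", "write_sidecar", "read_sidecar"]

DEFAULT_SAMPLE_RATE = 44100
RAMP_MS = 10.0
PEAK_DBFS = -1.0


@dataclass(frozen=True)
class RenderedAudio:
    sample_rate: int
    samples: np.ndarray
    duration_ms: float


def _raised_cosine_ramp(n_ramp: int, n_total: int) -> np.ndarray:
    """Unit envelope with raised-cosine (Hann-shaped) on/off ramps of
    ``n_ramp`` samples; the first ramp sample is exactly 0."""
    env = np.ones(n_total)
    if n_ramp > 0:
        t = np.arange(n_ramp) / n_ramp
        ramp = 0.5 * (1 - np.cos(np.pi * t))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def render_waveform(
    stimulus: FigureGroundStimulus,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    normalise: bool = True,
) -> RenderedAudio:
    """Render a symbolic stimulus to a mono float waveform."""
    max_freq = max(e.frequency for e in stimulus.elements)
    if sample_rate < 2 * max_freq:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates Nyquist for {max_freq:.0f} Hz tone"
        )
    samples_per_chord = int(round(stimulus.chord_ms * sample_rate / 1000.0))
    n_total = stimulus.n_chords * samples_per_chord
    n_ramp = int(round(RAMP_MS * sample_rate / 1000.0))
    out = np.zeros(n_total)
    t = np.arange(n_total) / sample_rate
    for e in stimulus.elements:
        i0 = e.chord_start * samples_per_chord
        i1 = i0 + e.n_chords * samples_per_chord
        seg_t = t[i0:i1]
        env = _raised_cosine_ramp(n_ramp, i1 - i0)
        out[i0:i1] += e.amplitude * env * np.sin(2 * np.pi * e.frequency * seg_t)
    if normalise:
        peak = np.max(np.abs(out))
        if peak > 0:
            out = out * (10.0 ** (PEAK_DBFS / 20.0) / peak)
    return RenderedAudio(
        sample_rate=sample_rate,
        samples=out,
        duration_ms=n_total / sample_rate * 1000.0,
    )


def write_wav(audio: RenderedAudio, path: str | Path, dtype: str = "float32") -> None:
    """Write mono WAV (float32 by default, or 16-bit PCM)."""
    if dtype == "float32":
        wavfile.write(path, audio.sample_rate, audio.samples.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(audio.samples, -1.0, 1.0) * 32767.0
        wavfile.write(path, audio.sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV dtype: {dtype!r}")


def write_sidecar(stimulus: FigureGroundStimulus, path: str | Path) -> None:
    """Write the JSON sidecar from which the audio regenerates bit-exactly."""
    Path(path).write_text(json.dumps(stimulus.to_dict(), indent=1))


def read_sidecar(path: str | Path) -> FigureGroundStimulus:
    return FigureGroundStimulus.from_dict(json.loads(Path(path).read_text()))
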