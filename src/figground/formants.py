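"""Formant tracks: per-50-ms-bin F1/F2/F3 trajectories.

Roving figures are built from the first three formants of spoken sentences,
averaged into 50-ms bins (34-50 bins per sentence, median 42).  Formant
extraction itself is out of scope: tracks are *inputs*, read from CSV with
columns ``bin,f1_hz,f2_hz,f3_hz``.  The package ships a few small synthetic
fixture tracks (see :data:`FIXTURE_NAMES`) and a generator of synthetic
tracks for simulation at scale; both emulate the broad statistics of
sentence formants (slow, bounded trajectories with F1 < F2 < F3), not any
real recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormantTrack",
    "read_formant_track",
    "write_formant_track",
    "load_fixture_track",
    "make_synthetic_formant_track",
    "FIXTURE_NAMES",
]

BIN_MS = 50.0
MIN_BINS = 34
MAX_BINS = 50
MEDIAN_BINS = 42

#: Synthetic fixture tracks shipped with the package (bin counts 34/42/50).
FIXTURE_NAMES = (
    "synthetic_sentence_34bins.csv",
    "synthetic_sentence_42bins.csv",
    "synthetic_sentence_50bins.csv",
)


@dataclass(frozen=True)
class FormantTrack:
    """Equal-length F1/F2/F3 trajectories sampled in 50-ms bins."""

    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    bin_ms: float = BIN_MS
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("f1", "f2", "f3"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not (len(self.f1) == len(self.f2) == len(self.f3)):
            raise ValueError("formant tracks must have equal length")
        if len(self.f1) == 0:
            raise ValueError("formant track is empty")
        if min(self.f1.min(), self.f2.min(), self.f3.min()) <= 0:
            raise ValueError("formant frequencies must be positive")

    def __len__(self) -> int:
        return int(len(self.f1))

    @property
    def n_bins(self) -> int:
        return len(self)


def read_formant_track(path: str | Path) -> FormantTrack:
    """Read a track from CSV with header ``bin,f1_hz,f2_hz,f3_hz``."""
    df = pd.read_csv(path)
    required = {"bin", "f1_hz", "f2_hz", "f3_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"formant CSV {path} missing columns: {sorted(missing)}")
    df = df.sort_values("bin")
    return FormantTrack(
        f1=df["f1_hz"].to_numpy(),
        f2=df["f2_hz"].to_numpy(),
        f3=df["f3_hz"].to_numpy(),
        name=Path(path).stem,
    )


def write_formant_track(track: FormantTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin": np.arange(len(track)),
            "f1_hz": track.f1,
            "f2_hz": track.f2,
            "f3_hz": track.f3,
        }
    ).to_csv(path, index=False, float_format="%.1f")


def load_fixture_track(name: str = "synthetic_sentence_42bins.csv") -> FormantTrack:
    """Load one of the synthetic fixture tracks bundled with the package."""
    ref = resources.files("figground").joinpath("data", name)
    with resources.as_file(ref) as path:
        return read_formant_track(path)


def _smooth_walk(
    rng: np.random.Generator, n: int, lo: float, hi: float, smoothness: int = 5
) -> np.ndarray:
    """Bounded slowly-varying trajectory: moving-average-smoothed noise mapped
    into [lo, hi] on a log-frequency axis."""
    raw = rng.standard_normal(n + 2 * smoothness)
    kernel = np.hanning(2 * smoothness + 1)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    # squash to (0, 1) then map to the band in log frequency
    u = 0.5 * (1 + np.tanh(smooth))
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def make_synthetic_formant_track(
    rng: np.random.Generator, n_bins: int | None = None, name: str = "synthetic"
) -> FormantTrack:
    """Generate a synthetic sentence-like formant track.

    F1 wanders in 300-900 Hz, F2 in 900-2300 Hz and F3 in 2300-3200 Hz on a
    log-frequency axis, each smoothed over ~5 bins so trajectories change
    slowly, as vowel formants do.  ``n_bins`` defaults to a draw from the
    34-50 bin range of the sentence material.
    """
    if n_bins is None:
        n_bins = int(rng.integers(MIN_BINS, MAX_BINS + 1))
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    f1 = _smooth_walk(rng, n_bins, 300.0, 900.0)
    f2 = _smooth_walk(rng, n_bins, 900.0, 2300.0)
    f3 = _smooth_walk(rng, n_bins, 2300.0, 3200.0)
    return FormantTrack(f1=f1, f2=f2, f3=f3, name=name)
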