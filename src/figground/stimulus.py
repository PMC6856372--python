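"""Symbolic construction of stochastic figure-ground tone-cloud stimuli.

A stimulus is a grid of 50-ms "chords", each containing several simultaneous
pure tones.  The *ground* is 5-15 tones per chord with frequencies drawn
independently at random from a 1/24th-octave grid spanning 179-7246 Hz.  The
*figure* is 3 tone components that repeat coherently across chords and come
in three classes:

``same_frequency``
    the 3 components keep constant frequencies, pairwise separated by more
    than one ERB;
``coherent_roving``
    the components follow the first-formant trajectory of a spoken sentence,
    scaled by the sentence-average F2/F1 and F3/F2 ratios, so all three
    change frequency at the same rate;
``complex_roving``
    the components are the F1/F2/F3 trajectories themselves, so the three
    change frequency at different rates.

Stimuli are built symbolically first (lists of :class:`ToneElement`); audio
rendering lives in :mod:`figground.render`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .formants import FormantTrack
from .grid import FrequencyGrid, build_frequency_grid, erb_number

__all__ = [
    "ToneElement",
    "GapSpec",
    "FigureGroundStimulus",
    "ConstraintError",
    "sample_ground",
    "make_same_frequency_figure",
    "make_coherent_roving_figure",
    "make_complex_roving_figure",
    "assemble_detection_stimulus",
    "assemble_detection_pair",
    "assemble_discrimination_pair",
    "apply_tmr",
]

CHORD_MS = 50.0
GROUND_MIN_TONES = 5
GROUND_MAX_TONES = 15
N_FIGURE_COMPONENTS = 3  # the "coherence level"

Role = Literal["ground", "figure", "decoy"]
Task = Literal["detection", "same_frequency", "coherent_roving", "complex_roving"]


class ConstraintError(RuntimeError):
    """A stimulus constraint could not be satisfied (e.g. rejection sampling failed)."""


@dataclass(frozen=True)
class ToneElement:
    """One pure tone: a frequency occupying ``n_chords`` consecutive chords."""

    frequency: float
    chord_start: int
    n_chords: int = 1
    amplitude: float = 1.0
    role: Role = "ground"

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("tone frequency must be positive")
        if self.n_chords < 1:
            raise ValueError("tone must span at least one chord")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class GapSpec:
    """Where the 300-ms gap sits: in the figure, in the ground, or nowhere."""

    location: Literal["figure", "ground", "none"] = "none"
    onset_chord: int = 0
    n_chords: int = 6
    n_components_removed: int = 3  # ground gaps only

    def span(self) -> range:
        return range(self.onset_chord, self.onset_chord + self.n_chords)


@dataclass(frozen=True)
class FigureGroundStimulus:
    """Symbolic chord-grid description of one figure-ground stimulus."""

    task: Task
    n_chords: int
    elements: tuple[ToneElement, ...]
    figure_onset_chord: int
    figure_n_chords: int
    figure_component_tracks: tuple[np.ndarray, ...]
    gap: GapSpec
    tmr_db: float
    seed: int | None = None
    chord_ms: float = CHORD_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        tracks = tuple(np.asarray(t, dtype=float) for t in self.figure_component_tracks)
        object.__setattr__(self, "figure_component_tracks", tracks)
        if tracks and len(tracks) != N_FIGURE_COMPONENTS:
            raise ValueError(f"expected {N_FIGURE_COMPONENTS} figure component tracks")
        if self.figure_n_chords and not (
            0 <= self.figure_onset_chord
            and self.figure_onset_chord + self.figure_n_chords <= self.n_chords
        ):
            raise ValueError("figure span must lie inside the stimulus")

    @property
    def duration_ms(self) -> float:
        return self.n_chords * self.chord_ms

    def elements_with_role(self, role: Role) -> tuple[ToneElement, ...]:
        return tuple(e for e in self.elements if e.role == role)

    def tone_chord_count(self, role: Role | None = None) -> int:
        """Total number of (tone, chord) occupancies, optionally per role."""
        els = self.elements if role is None else self.elements_with_role(role)
        return sum(e.n_chords for e in els)

    def ground_counts_per_chord(self) -> np.ndarray:
        counts = np.zeros(self.n_chords, dtype=int)
        for e in self.elements_with_role("ground"):
            counts[e.chord_start : e.chord_start + e.n_chords] += 1
        return counts

    # -- JSON sidecar serialisation ------------------------------------
    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_chords": self.n_chords,
            "chord_ms": self.chord_ms,
            "figure_onset_chord": self.figure_onset_chord,
            "figure_n_chords": self.figure_n_chords,
            "figure_component_tracks": [t.tolist() for t in self.figure_component_tracks],
            "gap": {
                "location": self.gap.location,
                "onset_chord": self.gap.onset_chord,
                "n_chords": self.gap.n_chords,
                "n_components_removed": self.gap.n_components_removed,
            },
            "tmr_db": self.tmr_db,
            "seed": self.seed,
            "elements": [
                [e.frequency, e.chord_start, e.n_chords, e.amplitude, e.role]
                for e in self.elements
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FigureGroundStimulus":
        return cls(
            task=d["task"],
            n_chords=int(d["n_chords"]),
            chord_ms=float(d.get("chord_ms", CHORD_MS)),
            elements=tuple(
                ToneElement(
                    frequency=float(f), chord_start=int(c), n_chords=int(n),
                    amplitude=float(a), role=r,
                )
                for f, c, n, a, r in d["elements"]
            ),
            figure_onset_chord=int(d["figure_onset_chord"]),
            figure_n_chords=int(d["figure_n_chords"]),
            figure_component_tracks=tuple(
                np.asarray(t, dtype=float) for t in d["figure_component_tracks"]
            ),
            gap=GapSpec(**d["gap"]),
            tmr_db=float(d["tmr_db"]),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------

def sample_ground(
    n_chords: int, grid: FrequencyGrid, rng: np.random.Generator
) -> list[ToneElement]:
    """Draw the stochastic background: 5-15 tones per chord, frequencies
    sampled without replacement from the grid, independently at each chord."""
    if n_chords < 1:
        raise ValueError("n_chords must be >= 1")
    elements: list[ToneElement] = []
    freqs = grid.frequencies
    for chord in range(n_chords):
        count = int(rng.integers(GROUND_MIN_TONES, GROUND_MAX_TONES + 1))
        chosen = rng.choice(freqs, size=count, replace=False)
        elements.extend(
            ToneElement(frequency=float(f), chord_start=chord, role="ground")
            for f in chosen
        )
    return elements


def make_same_frequency_figure(
    figure_n_chords: int,
    grid: FrequencyGrid,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three constant-frequency component tracks, pairwise > 1 ERB apart.

    Frequencies are rejection-sampled from the grid until the ERB-number
    separation constraint holds for all three pairs.
    """
    if len(grid) < N_FIGURE_COMPONENTS:
        raise ConstraintError("grid too small for a 3-component figure")
    erbs = erb_number(grid.frequencies)
    for _ in range(max_attempts):
        idx = rng.choice(len(grid), size=N_FIGURE_COMPONENTS, replace=False)
        e = erbs[idx]
        if min(abs(e[0] - e[1]), abs(e[0] - e[2]), abs(e[1] - e[2])) > 1.0:
            freqs = np.sort(grid.frequencies[idx])
            return tuple(np.full(figure_n_chords, f) for f in freqs)
    raise ConstraintError(
        f"could not satisfy ERB separation after {max_attempts} attempts"
    )


def make_coherent_roving_figure(
    track: FormantTrack, method: Literal["ratio", "linear_offset"] = "ratio"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component tracks that follow F1, all changing frequency at the same rate.

    Component 1 is the F1 trajectory bin-by-bin.  Component 2 is component 1
    scaled by the sentence-average F2/F1 relationship, component 3 is
    component 2 scaled by the average F3/F2 relationship.  With the default
    ``ratio`` method the averages are mean frequency *ratios* (so components
    stay in a constant ratio and move together on a log-frequency axis);
    ``linear_offset`` uses mean differences in Hz instead.
    """
    f1, f2, f3 = (np.asarray(x, dtype=float) for x in (track.f1, track.f2, track.f3))
    if np.any(f1 <= 0) or np.any(f2 <= 0) or np.any(f3 <= 0):
        raise ValueError("formant frequencies must be positive")
    c1 = f1.copy()
    if method == "ratio":
        r12 = float(np.mean(f2 / f1))
        r23 = float(np.mean(f3 / f2))
        c2 = c1 * r12
        c3 = c2 * r23
    elif method == "linear_offset":
        d12 = float(np.mean(f2 - f1))
        d23 = float(np.mean(f3 - f2))
        c2 = c1 + d12
        c3 = c2 + d23
    else:
        raise ValueError(f"unknown coherent-roving method: {method!r}")
    return c1, c2, c3


def make_complex_roving_figure(
    track: FormantTrack,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component tracks equal to the F1, F2 and F3 trajectories bin-by-bin,
    so the three components change frequency at different rates."""
    f1, f2, f3 = (np.asarray(x, dtype=float) for x in (track.f1, track.f2, track.f3))
    if np.any(f1 <= 0) or np.any(f2 <= 0) or np.any(f3 <= 0):
        raise ValueError("formant frequencies must be positive")
    return f1.copy(), f2.copy(), f3.copy()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _figure_elements(
    tracks: Sequence[np.ndarray],
    onset: int,
    skip_chords: range | None = None,
    amplitude: float = 1.0,
) -> list[ToneElement]:
    """Materialise component tracks as one 1-chord tone per component per chord,
    omitting chords inside ``skip_chords`` (the figure gap)."""
    elements: list[ToneElement] = []
    n = len(tracks[0])
    for i in range(n):
        chord = onset + i
        if skip_chords is not None and chord in skip_chords:
            continue
        for tr in tracks:
            elements.append(
                ToneElement(
                    frequency=float(tr[i]), chord_start=chord,
                    amplitude=amplitude, role="figure",
                )
            )
    return elements


def apply_tmr(stimulus: FigureGroundStimulus, tmr_db: float) -> FigureGroundStimulus:
    """Set every figure (and decoy) tone's amplitude to ``10**(tmr_db/20)``
    times the per-tone ground amplitude (fixed at 1)."""
    gain = 10.0 ** (tmr_db / 20.0)
    new_elements = tuple(
        e if e.role == "ground" else replace(e, amplitude=gain)
        for e in stimulus.elements
    )
    return replace(stimulus, elements=new_elements, tmr_db=tmr_db)


DETECTION_N_CHORDS = 40
DETECTION_FIGURE_CHORDS = 6
# the figure "starts on chord 15-20" in 1-based counting -> 0-based onsets 14..19
DETECTION_ONSET_RANGE = (14, 19)


def assemble_detection_stimulus(
    figure_present: bool,
    rng: np.random.Generator,
    grid: FrequencyGrid | None = None,
    tmr_db: float = 0.0,
    seed: int | None = None,
    _ground: list[ToneElement] | None = None,
    _onset: int | None = None,
) -> FigureGroundStimulus:
    """One 40-chord (2000-ms) yes/no detection stimulus.

    Figure-present stimuli carry a 6-chord same-frequency figure starting on
    chord 15-20 (1-based).  Figure-absent stimuli instead carry 3 decoy
    components with the same onset and duration whose frequencies are redrawn
    independently at every chord, so matched present/absent stimuli contain
    the same number of tones (and at equal amplitudes the same energy).
    """
    grid = grid or build_frequency_grid()
    ground = _ground if _ground is not None else sample_ground(DETECTION_N_CHORDS, grid, rng)
    lo, hi = DETECTION_ONSET_RANGE
    onset = _onset if _onset is not None else int(rng.integers(lo, hi + 1))

    if figure_present:
        tracks = make_same_frequency_figure(DETECTION_FIGURE_CHORDS, grid, rng)
        fig_elements = _figure_elements(tracks, onset)
    else:
        tracks = tuple(np.zeros(0) for _ in range(N_FIGURE_COMPONENTS))
        fig_elements = []
        for chord in range(onset, onset + DETECTION_FIGURE_CHORDS):
            chosen = rng.choice(grid.frequencies, size=N_FIGURE_COMPONENTS, replace=False)
            fig_elements.extend(
                ToneElement(frequency=float(f), chord_start=chord, role="decoy")
                for f in chosen
            )

    stim = FigureGroundStimulus(
        task="detection",
        n_chords=DETECTION_N_CHORDS,
        elements=tuple(ground) + tuple(fig_elements),
        figure_onset_chord=onset,
        figure_n_chords=DETECTION_FIGURE_CHORDS if figure_present else 0,
        figure_component_tracks=tracks if figure_present else (),
        gap=GapSpec(location="none"),
        tmr_db=0.0,
        seed=seed,
    )
    return apply_tmr(stim, tmr_db)


def assemble_detection_pair(
    rng: np.random.Generator,
    grid: FrequencyGrid | None = None,
    tmr_db: float = 0.0,
) -> tuple[FigureGroundStimulus, FigureGroundStimulus]:
    """A matched (figure-present, figure-absent) pair sharing ground and onset."""
    grid = grid or build_frequency_grid()
    ground = sample_ground(DETECTION_N_CHORDS, grid, rng)
    lo, hi = DETECTION_ONSET_RANGE
    onset = int(rng.integers(lo, hi + 1))
    present = assemble_detection_stimulus(
        True, rng, grid, tmr_db, _ground=ground, _onset=onset
    )
    absent = assemble_detection_stimulus(
        False, rng, grid, tmr_db, _ground=ground, _onset=onset
    )
    return present, absent


DISCRIMINATION_N_CHORDS = 70
SAME_FREQUENCY_FIGURE_CHORDS = 42
GAP_CHORDS = 6


def _build_discrimination_stimulus(
    task: Task,
    tracks: Sequence[np.ndarray],
    figure_onset: int,
    gap: GapSpec,
    grid: FrequencyGrid,
    rng: np.random.Generator,
    tmr_db: float,
) -> FigureGroundStimulus:
    n_fig = len(tracks[0])
    ground = sample_ground(DISCRIMINATION_N_CHORDS, grid, rng)

    if gap.location == "figure":
        fig_elements = _figure_elements(tracks, figure_onset, skip_chords=gap.span())
    else:
        fig_elements = _figure_elements(tracks, figure_onset)

    if gap.location == "ground":
        # remove n_components_removed ground tones at each chord of the window
        by_chord: dict[int, list[int]] = {}
        for i, e in enumerate(ground):
            by_chord.setdefault(e.chord_start, []).append(i)
        drop: set[int] = set()
        for chord in gap.span():
            idx = by_chord.get(chord, [])
            take = rng.choice(len(idx), size=gap.n_components_removed, replace=False)
            drop.update(idx[t] for t in take)
        ground = [e for i, e in enumerate(ground) if i not in drop]

    stim = FigureGroundStimulus(
        task=task,
        n_chords=DISCRIMINATION_N_CHORDS,
        elements=tuple(ground) + tuple(fig_elements),
        figure_onset_chord=figure_onset,
        figure_n_chords=n_fig,
        figure_component_tracks=tuple(tracks),
        gap=gap,
        tmr_db=0.0,
    )
    return apply_tmr(stim, tmr_db)


def assemble_discrimination_pair(
    task: Task,
    tmr_db: float,
    gap_interval: int,
    rng: np.random.Generator,
    track: FormantTrack | None = None,
    grid: FrequencyGrid | None = None,
) -> tuple[FigureGroundStimulus, FigureGroundStimulus]:
    """One 2I-2AFC discrimination trial: two 70-chord (3500-ms) stimuli.

    Both intervals contain the same figure (same component tracks, same
    onset) over independent random grounds.  The interval numbered
    ``gap_interval`` (1 or 2) has a 6-chord gap in the figure; the other has
    3 ground tones removed at each of 6 consecutive chords overlapping the
    figure's span.  ``tmr_db`` sets the per-tone figure level re ground.
    """
    if gap_interval not in (1, 2):
        raise ValueError("gap_interval must be 1 or 2")
    grid = grid or build_frequency_grid()

    if task == "same_frequency":
        tracks = make_same_frequency_figure(SAME_FREQUENCY_FIGURE_CHORDS, grid, rng)
    elif task == "coherent_roving":
        if track is None:
            raise ValueError("coherent_roving task requires a FormantTrack")
        tracks = make_coherent_roving_figure(track)
    elif task == "complex_roving":
        if track is None:
            raise ValueError("complex_roving task requires a FormantTrack")
        tracks = make_complex_roving_figure(track)
    else:
        raise ValueError(f"not a discrimination task: {task!r}")

    n_fig = len(tracks[0])
    if n_fig > DISCRIMINATION_N_CHORDS:
        raise ConstraintError(
            f"figure ({n_fig} chords) longer than background ({DISCRIMINATION_N_CHORDS})"
        )
    if n_fig < GAP_CHORDS + 2:
        raise ConstraintError("figure too short to contain an interior gap")

    figure_onset = int(rng.integers(0, DISCRIMINATION_N_CHORDS - n_fig + 1))
    # figure gap: flanked by >= 1 figure chord on each side
    fig_gap_onset = figure_onset + int(rng.integers(1, n_fig - GAP_CHORDS))
    fig_gap = GapSpec(location="figure", onset_chord=fig_gap_onset, n_chords=GAP_CHORDS)
    # ground gap: any 6-chord window overlapping the figure span
    g_lo = max(0, figure_onset - GAP_CHORDS + 1)
    g_hi = min(DISCRIMINATION_N_CHORDS - GAP_CHORDS, figure_onset + n_fig - 1)
    gnd_gap_onset = int(rng.integers(g_lo, g_hi + 1))
    gnd_gap = GapSpec(location="ground", onset_chord=gnd_gap_onset, n_chords=GAP_CHORDS)

    gaps = (fig_gap, gnd_gap) if gap_interval == 1 else (gnd_gap, fig_gap)
    first = _build_discrimination_stimulus(task, tracks, figure_onset, gaps[0], grid, rng, tmr_db)
    second = _build_discrimination_stimulus(task, tracks, figure_onset, gaps[1], grid, rng, tmr_db)
    return first, second
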