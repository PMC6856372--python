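"""Simulated listeners and signal-detection scoring.

Two observer families:

:class:`PsychometricObserver`
    a parametric observer whose probability of a correct response follows a
    logistic psychometric function of trial TMR.  It is a test harness for
    the adaptive procedure, not a model of hearing.

:class:`CoherenceObserver`
    a temporal-coherence observer that "listens" to the symbolic chord grid.
    It maps tones into frequency channels, computes sliding-window Pearson
    correlations between channel time-courses, and accumulates significantly
    positive correlations as figure evidence — the mechanism by which
    coherent figure components (which rise, fall and gap together across
    channels) stand out from the incoherent random ground.  It operates on
    the symbolic stimulus, not rendered audio: it is a demonstration of the
    grouping mechanism, not an auditory-periphery model.

Neither observer is fit to human data; both are artifact constructions for
exercising the task machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from .formants import FormantTrack, make_synthetic_formant_track
from .grid import FrequencyGrid, build_frequency_grid
from .staircase import TrialFn
from .stimulus import FigureGroundStimulus, Task, assemble_discrimination_pair


@dataclass(frozen=True)
class PsychometricObserver:
    """Logistic psychometric observer: p(correct) as a function of TMR (dB).

    ``mu`` is the TMR at which the underlying logistic crosses its midpoint
    (the 50%-correct point when ``guess = lapse = 0``); ``slope`` is in
    1/dB; ``guess`` is the lower asymptote (0.5 for 2AFC) and ``lapse`` the
    upper-asymptote shortfall.
    """

    mu: float
    slope: float = 1.0
    guess: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.guess <= 1 and 0 <= self.lapse <= 1):
            raise ValueError("guess and lapse must be probabilities")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def prob_correct(self, tmr_db: float) -> float:
        # correctness is *lower* for harder (lower-TMR) trials
        return self.guess + (1 - self.guess - self.lapse) * float(
            expit(self.slope * (tmr_db - self.mu))
        )

    def respond(self, tmr_db: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.prob_correct(tmr_db))

    def trial_fn(self) -> TrialFn:
        return self.respond


def _critical_r(n: int, alpha: float = 0.05) -> float:
    """One-sided significance threshold for a Pearson r over n paired samples."""
    if n < 3:
        return 1.0
    df = n - 2
    tc = float(t_dist.ppf(1 - alpha, df))
    return tc / np.sqrt(df + tc * tc)


@dataclass
class CoherenceObserver:
    """Temporal-coherence observer over the symbolic chord grid.

    An "object" is a set of frequency channels whose activity is correlated
    over time.  The observer maps every tone to its nearest channel of the
    stimulus frequency grid, slides a short window along the chord axis,
    Pearson-correlates the channel time-courses within each window, and
    accumulates significantly positive correlations as figure evidence.
    Coherent figure events — onset, offset, and the edges of a figure gap —
    drive several channels up or down together and light up the correlator;
    the i.i.d. ground contributes only chance coincidences.

    Parameters
    ----------
    window_chords:
        length of the sliding correlation window, in 50-ms chords.
    grid:
        frequency channels; every tone (including off-grid roving
        components) is assigned to its nearest channel in log frequency.
    decision_noise:
        SD of Gaussian internal noise added to the decision variable.
    alpha:
        one-sided significance level for counting a channel-pair
        correlation as figure evidence.
    top_channels:
        salience bottleneck: only the most active channels within a window
        (by mean activation) enter the correlation stage.  Without it the
        score is dominated by chance coincidences among the ~10^4 sparse
        ground channel pairs; with it, figure channels — which carry
        sustained energy — compete for the correlator only against the few
        densest ground channels, and only when the figure is intense enough
        to be salient.  This bottleneck is also what makes the observer
        TMR-sensitive: Pearson correlations themselves are
        amplitude-invariant.
    """

    window_chords: int = 10
    grid: FrequencyGrid = field(default_factory=build_frequency_grid)
    decision_noise: float = 1.0
    alpha: float = 0.05
    top_channels: int = 12

    def __post_init__(self) -> None:
        if self.window_chords < 2:
            raise ValueError("window_chords must be >= 2")
        self._r_crit = _critical_r(self.window_chords, self.alpha)
        self._log_channels = np.log(self.grid.frequencies)

    # -- evidence ------------------------------------------------------
    def activation_matrix(self, stimulus: FigureGroundStimulus) -> np.ndarray:
        """channels x chords amplitude map of the symbolic stimulus."""
        act = np.zeros((len(self.grid), stimulus.n_chords))
        for e in stimulus.elements:
            ch = int(np.argmin(np.abs(np.log(e.frequency) - self._log_channels)))
            act[ch, e.chord_start : e.chord_start + e.n_chords] += e.amplitude
        return act

    def coherence_score(self, stimulus: FigureGroundStimulus) -> np.ndarray:
        """Figure-evidence trace: one score per sliding window position.

        Within each window the ``top_channels`` most active channel
        time-courses (those with non-zero variance) are pairwise
        Pearson-correlated; the score is the sum of the correlations
        exceeding the one-sided significance threshold.
        """
        w = self.window_chords
        if stimulus.n_chords < w:
            raise ValueError(
                f"stimulus ({stimulus.n_chords} chords) shorter than window ({w})"
            )
        act = self.activation_matrix(stimulus)
        n_windows = stimulus.n_chords - w + 1
        trace = np.zeros(n_windows)
        for k in range(n_windows):
            sub = act[:, k : k + w]
            varying = sub.std(axis=1) > 0
            if varying.sum() < 2:
                continue
            energy = np.where(varying, sub.mean(axis=1), -np.inf)
            top = np.argsort(energy)[::-1][: self.top_channels]
            active = top[np.isfinite(energy[top])]
            if active.size < 2:
                continue
            r = np.corrcoef(sub[active])
            vals = r[np.triu_indices(active.size, 1)]
            trace[k] = float(vals[vals > self._r_crit].sum())
        return trace

    # -- decisions -----------------------------------------------------
    def evidence(self, stimulus: FigureGroundStimulus) -> float:
        """Total coherent-event mass of the trace (sum over windows)."""
        return float(self.coherence_score(stimulus).sum())

    def respond_2afc(
        self,
        pair: tuple[FigureGroundStimulus, FigureGroundStimulus],
        rng: np.random.Generator,
    ) -> int:
        """Choose the interval whose trace carries more coherent-event mass.

        The figure gap adds two coherent transitions (all figure channels
        switch off at the gap onset and back on at its offset) on top of
        the figure's own onset and offset; the ground gap removes tones
        from unrelated channels and adds no coherent structure.  The
        figure-gap interval therefore carries the larger evidence mass —
        increasingly so as the TMR raises the figure channels into the
        salience bottleneck.
        """
        e1 = self.evidence(pair[0]) + self.decision_noise * rng.standard_normal()
        e2 = self.evidence(pair[1]) + self.decision_noise * rng.standard_normal()
        if e1 == e2:
            return int(rng.integers(1, 3))
        return 1 if e1 > e2 else 2

    def respond_detection(
        self,
        stimulus: FigureGroundStimulus,
        rng: np.random.Generator,
        criterion: float,
    ) -> bool:
        """Yes/no response: peak trace evidence (plus internal noise)
        compared against a fixed criterion."""
        ev = float(self.coherence_score(stimulus).max())
        return ev + self.decision_noise * rng.standard_normal() > criterion

    def discrimination_trial_fn(
        self,
        task: Task,
        track_source: Callable[[np.random.Generator], FormantTrack] | None = None,
    ) -> TrialFn:
        """Trial function for the adaptive procedure: builds a fresh 2I-2AFC
        stimulus pair at the requested TMR and scores the observer's choice.

        ``track_source`` supplies a formant track per trial for the roving
        tasks (defaults to the synthetic sentence generator)."""
        if track_source is None and task in ("coherent_roving", "complex_roving"):
            track_source = make_synthetic_formant_track

        def trial(tmr_db: float, rng: np.random.Generator) -> bool:
            gap_interval = int(rng.integers(1, 3))
            track = track_source(rng) if track_source is not None else None
            pair = assemble_discrimination_pair(
                task, tmr_db, gap_interval, rng, track=track, grid=self.grid
            )
            return self.respond_2afc(pair, rng) == gap_interval

        return trial


# ---------------------------------------------------------------------------
# Signal-detection scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionScore:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    dprime: float

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


def dprime(hits: int, false_alarms: int, n_signal: int, n_noise: int) -> float:
    """Yes/no sensitivity d' = z(hit rate) - z(false-alarm rate).

    Extreme rates are clipped to [1/(2N), 1 - 1/(2N)] on each side so that
    perfect scores yield a finite d'.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be positive")
    if not (0 <= hits <= n_signal and 0 <= false_alarms <= n_noise):
        raise ValueError("counts inconsistent with trial numbers")
    h = np.clip(hits / n_signal, 1 / (2 * n_signal), 1 - 1 / (2 * n_signal))
    f = np.clip(false_alarms / n_noise, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise))
    return float(norm.ppf(h) - norm.ppf(f))


def score_detection(trial_log: Sequence[tuple[bool, bool]]) -> DetectionScore:
    """Tabulate a (figure_present, responded_present) trial log into SDT
    counts and d'."""
    hits = sum(1 for p, r in trial_log if p and r)
    misses = sum(1 for p, r in trial_log if p and not r)
    fas = sum(1 for p, r in trial_log if not p and r)
    crs = sum(1 for p, r in trial_log if not p and not r)
    return DetectionScore(
        hits=hits,
        misses=misses,
        false_alarms=fas,
        correct_rejections=crs,
        dprime=dprime(hits, fas, hits + misses, fas + crs),
    )
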