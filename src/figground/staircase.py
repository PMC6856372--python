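"""1-up/1-down adaptive TMR staircases and session structure.

Each discrimination run starts at +6 dB TMR, moves down one step after a
correct response and up one step after an error, switches from 2-dB to
0.5-dB steps after the 3rd reversal, and terminates after 10 reversals.
The run threshold is the median of the last 6 reversal TMRs; the session
threshold averages two interleaved runs.  The yes/no detection task instead
uses fixed stimulus parameters over 50 trials, scored with d'.

A 1-up/1-down rule converges on the 50%-correct point of the psychometric
function; the task instructions described it the same way and it is
implemented verbatim (see docs/methods.md for the 2AFC chance-level caveat).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "RunResult",
    "SessionResult",
    "StaircaseError",
    "NonConvergenceError",
    "staircase_init",
    "staircase_update",
    "threshold_from_run",
    "run_staircase",
    "run_adaptive_session",
    "run_detection_session",
]

#: A trial function maps the trial TMR (dB) to whether the response was correct.
TrialFn = Callable[[float, np.random.Generator], bool]


class StaircaseError(RuntimeError):
    """Invalid staircase state transition."""


class NonConvergenceError(StaircaseError):
    """A run exceeded the maximum trial count without reaching 10 reversals."""


@dataclass(frozen=True)
class StaircaseConfig:
    start_tmr: float = 6.0
    initial_step: float = 2.0
    final_step: float = 0.5
    step_switch_reversals: int = 3
    stop_reversals: int = 10
    max_trials: int = 200  # guard for non-converging simulated observers

    def __post_init__(self) -> None:
        if self.initial_step <= 0 or self.final_step <= 0:
            raise ValueError("step sizes must be positive")
        if self.stop_reversals < self.step_switch_reversals:
            raise ValueError("stop_reversals must be >= step_switch_reversals")


@dataclass(frozen=True)
class StaircaseState:
    config: StaircaseConfig
    current_tmr: float
    current_step: float
    last_direction: Literal["up", "down", "none"] = "none"
    reversal_tmrs: tuple[float, ...] = ()
    trial_log: tuple[tuple[float, bool], ...] = ()

    @property
    def finished(self) -> bool:
        return len(self.reversal_tmrs) >= self.config.stop_reversals

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)


@dataclass(frozen=True)
class RunResult:
    reversal_tmrs: tuple[float, ...]
    threshold: float
    trial_log: tuple[tuple[float, bool], ...] = ()


@dataclass(frozen=True)
class SessionResult:
    task: str
    run1: RunResult
    run2: RunResult

    @property
    def threshold(self) -> float:
        return 0.5 * (self.run1.threshold + self.run2.threshold)


def staircase_init(config: StaircaseConfig | None = None) -> StaircaseState:
    config = config or StaircaseConfig()
    return StaircaseState(
        config=config,
        current_tmr=config.start_tmr,
        current_step=config.initial_step,
    )


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the track by one trial presented at ``state.current_tmr``.

    A direction change (relative to the previous move) records a reversal at
    the TMR of the current trial — the extremum of the track.  After the
    3rd reversal subsequent moves use the final 0.5-dB step; after the 10th
    the run is finished.
    """
    if state.finished:
        raise StaircaseError("cannot update a finished staircase")
    cfg = state.config
    direction = "down" if correct else "up"
    reversals = state.reversal_tmrs
    if state.last_direction != "none" and direction != state.last_direction:
        reversals = reversals + (state.current_tmr,)
    step = cfg.final_step if len(reversals) >= cfg.step_switch_reversals else cfg.initial_step
    new_tmr = state.current_tmr - step if correct else state.current_tmr + step
    return replace(
        state,
        current_tmr=new_tmr,
        current_step=step,
        last_direction=direction,
        reversal_tmrs=reversals,
        trial_log=state.trial_log + ((state.current_tmr, correct),),
    )


def threshold_from_run(run: RunResult | Sequence[float]) -> float:
    """Run threshold: median of the last 6 of the 10 reversal TMRs."""
    reversals = run.reversal_tmrs if isinstance(run, RunResult) else tuple(run)
    if len(reversals) != 10:
        raise StaircaseError(f"expected 10 reversals, got {len(reversals)}")
    return float(np.median(np.asarray(reversals[4:10])))


def run_staircase(
    trial_fn: TrialFn,
    rng: np.random.Generator,
    config: StaircaseConfig | None = None,
) -> RunResult:
    """Drive one staircase to completion with a simulated observer."""
    state = staircase_init(config)
    while not state.finished:
        if state.n_trials >= state.config.max_trials:
            raise NonConvergenceError(
                f"staircase did not reach {state.config.stop_reversals} reversals "
                f"within {state.config.max_trials} trials"
            )
        state = staircase_update(state, bool(trial_fn(state.current_tmr, rng)))
    return RunResult(
        reversal_tmrs=state.reversal_tmrs,
        threshold=threshold_from_run(state.reversal_tmrs),
        trial_log=state.trial_log,
    )


def run_adaptive_session(
    trial_fn: TrialFn,
    rng: np.random.Generator,
    config: StaircaseConfig | None = None,
    task: str = "",
    interleave: Literal["alternate", "random"] = "alternate",
) -> SessionResult:
    """Two interleaved, otherwise identical runs; each trial presents a fresh
    stimulus via ``trial_fn``.  Default schedule is strict alternation."""
    states = [staircase_init(config), staircase_init(config)]
    turn = 0
    while not all(s.finished for s in states):
        if interleave == "alternate":
            i = turn % 2
            if states[i].finished:
                i = 1 - i
        else:
            active = [j for j, s in enumerate(states) if not s.finished]
            i = int(rng.choice(active))
        if states[i].n_trials >= states[i].config.max_trials:
            raise NonConvergenceError(
                f"run {i + 1} did not finish within {states[i].config.max_trials} trials"
            )
        states[i] = staircase_update(states[i], bool(trial_fn(states[i].current_tmr, rng)))
        turn += 1
    runs = [
        RunResult(
            reversal_tmrs=s.reversal_tmrs,
            threshold=threshold_from_run(s.reversal_tmrs),
            trial_log=s.trial_log,
        )
        for s in states
    ]
    return SessionResult(task=task, run1=runs[0], run2=runs[1])


def run_detection_session(
    respond_fn: Callable[[bool, object, np.random.Generator], bool],
    rng: np.random.Generator,
    n_trials: int = 50,
    stimulus_factory: Callable[[bool, np.random.Generator], object] | None = None,
) -> list[tuple[bool, bool]]:
    """Fixed-parameter yes/no detection session.

    Exactly half of the ``n_trials`` trials are figure-present, in shuffled
    order.  ``respond_fn(present, stimulus, rng)`` returns the simulated
    "figure present" response; ``stimulus_factory`` optionally builds the
    actual stimulus handed to the observer (None is passed otherwise).
    Returns the trial log as (figure_present, responded_present) pairs.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even for a balanced present/absent split")
    presence = np.array([True] * (n_trials // 2) + [False] * (n_trials // 2))
    rng.shuffle(presence)
    log: list[tuple[bool, bool]] = []
    for present in presence:
        stim = stimulus_factory(bool(present), rng) if stimulus_factory else None
        log.append((bool(present), bool(respond_fn(bool(present), stim, rng))))
    return log
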