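"""Transformed up-down (3-down / 1-up) adaptive staircase.

The staircase operates in integer *signal-element* units (coherence is the
derived quantity 100 * level / total): after three consecutive correct
responses the signal count drops by the current step, after any error it
rises by the step.  The asymmetric rule converges where the probability of
three correct responses in a row is one half, i.e. p^3 = 1/2, so trials
concentrate around the coherence supporting p = 2^(-1/3) ~= 79.37% correct.

Step-size schedule: the initial step equals the total element count and is
halved (integer halving, floor one element) at every reversal — a change in
the direction of movement.  A run terminates once six reversals have
occurred at the one-element step, and the threshold estimate is the mean of
the last six reversal levels, expressed as a coherence percentage.  A
session threshold is the arithmetic mean of at least four staircases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .observers import PsychometricObserver, prob_correct

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "SessionResult",
    "update_staircase",
    "estimate_threshold",
    "run_staircase",
    "run_session",
]

#: equilibrium accuracy of the 3-down/1-up rule: p**3 = 1/2
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive run, in integer element units."""

    total_elements: int = 200
    n_down: int = 3
    n_up: int = 1
    initial_level_elements: int | None = None  # default: total (100% coherence)
    initial_step_elements: int | None = None   # default: total
    step_floor_elements: int = 1
    required_reversals_at_floor: int = 6
    max_trials: int = 10_000
    # "last_overall": estimate from the last six reversals of any step size
    # (under the floor-termination rule these are necessarily floor-step
    # reversals); "floor_only": estimate from reversals at the floor step.
    estimate_from: str = "last_overall"

    def __post_init__(self) -> None:
        if self.total_elements <= 0:
            raise ValueError("total_elements must be positive")
        if self.n_down < 1 or self.n_up != 1:
            raise ValueError("rule must be n-down / 1-up with n >= 1")
        if self.step_floor_elements < 1:
            raise ValueError("step floor must be at least one element")
        if self.initial_step is not None and self.initial_step > self.total_elements:
            raise ValueError("initial step cannot exceed the element count")
        if self.estimate_from not in ("last_overall", "floor_only"):
            raise ValueError("estimate_from must be 'last_overall' or 'floor_only'")

    @property
    def initial_level(self) -> int:
        return self.total_elements if self.initial_level_elements is None \
            else self.initial_level_elements

    @property
    def initial_step(self) -> int | None:
        return self.initial_step_elements

    def start_state(self) -> "StaircaseState":
        step = self.total_elements if self.initial_step_elements is None \
            else self.initial_step_elements
        return StaircaseState(level=self.initial_level, step=step)


@dataclass
class StaircaseState:
    """Evolving record of one staircase run."""

    level: int
    step: int
    consecutive_correct: int = 0
    direction: str = "none"  # {"none", "descending", "ascending"}
    reversal_levels: list[int] = field(default_factory=list)
    reversal_steps: list[int] = field(default_factory=list)
    floor_reversals: int = 0
    trial_log: list[tuple[int, bool]] = field(default_factory=list)
    terminated: bool = False

    def trial_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_log, columns=["level_elements", "correct"])


@dataclass
class SessionResult:
    """Aggregate of several independent staircases on the same observer."""

    staircase_thresholds: list[float]
    states: list[StaircaseState]

    @property
    def n_staircases(self) -> int:
        return len(self.staircase_thresholds)

    @property
    def session_threshold_pct(self) -> float:
        return float(np.mean(self.staircase_thresholds))

    def to_json(self) -> str:
        return json.dumps({"staircase_thresholds": self.staircase_thresholds,
                           "session_threshold_pct": self.session_threshold_pct,
                           "n_staircases": self.n_staircases}, sort_keys=True)


def update_staircase(state: StaircaseState, config: StaircaseConfig,
                     correct: bool) -> StaircaseState:
    """Advance the staircase by one trial (the state is mutated and returned).

    An error moves the level up immediately; the ``n_down``-th consecutive
    correct response moves it down.  A move opposite to the previous
    movement direction is a reversal: the pre-move level is recorded and the
    step halves before the move is applied.  Moves clamped at the 0/total
    boundaries count as reversals only if the intended direction changed.
    """
    if state.terminated:
        raise RuntimeError("staircase already terminated")
    state.trial_log.append((state.level, bool(correct)))

    move = 0
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= config.n_down:
            state.consecutive_correct = 0
            move = -1
    else:
        state.consecutive_correct = 0
        move = +1
    if move == 0:
        return state

    new_direction = "descending" if move < 0 else "ascending"
    if state.direction != "none" and new_direction != state.direction:
        # reversal: record the level and the step in force, then halve the step
        state.reversal_levels.append(state.level)
        state.reversal_steps.append(state.step)
        if state.step == config.step_floor_elements:
            state.floor_reversals += 1
            if state.floor_reversals >= config.required_reversals_at_floor:
                state.terminated = True
        state.step = max(config.step_floor_elements, state.step // 2)
    state.direction = new_direction
    state.level = int(np.clip(state.level + move * state.step, 0, config.total_elements))
    return state


def estimate_threshold(state: StaircaseState, config: StaircaseConfig) -> float:
    """Coherence threshold (%) from the mean of the last six reversal levels."""
    if not state.terminated:
        raise RuntimeError("staircase has not terminated")
    k = config.required_reversals_at_floor
    if config.estimate_from == "floor_only":
        levels = [lv for lv, st in zip(state.reversal_levels, state.reversal_steps)
                  if st == config.step_floor_elements][-k:]
    else:
        levels = state.reversal_levels[-k:]
    return 100.0 * float(np.mean(levels)) / config.total_elements


def run_staircase(observer: PsychometricObserver | None, config: StaircaseConfig,
                  seed, trial_fn: Callable[[float, np.random.Generator], bool] | None = None,
                  ) -> StaircaseState:
    """Run one staircase to termination.

    Responses come from ``trial_fn(coherence_pct, rng) -> correct`` when
    given (e.g. full stimulus generation plus a stimulus-driven decision),
    otherwise from Bernoulli draws against the observer's psychometric
    function.  Raises ``RuntimeError`` if ``config.max_trials`` is reached
    without termination.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if trial_fn is None:
        if observer is None:
            raise ValueError("need an observer or a trial_fn")
        def trial_fn(coherence_pct, rng):  # noqa: F811 - default responder
            return bool(rng.random() < prob_correct(observer, coherence_pct))

    state = config.start_state()
    for _ in range(config.max_trials):
        coherence = 100.0 * state.level / config.total_elements
        update_staircase(state, config, trial_fn(coherence, rng))
        if state.terminated:
            return state
    raise RuntimeError(
        f"staircase failed to terminate within {config.max_trials} trials "
        f"(level={state.level}, step={state.step}, "
        f"floor_reversals={state.floor_reversals})")


def run_session(observer: PsychometricObserver | None, config: StaircaseConfig,
                seed, n_staircases: int = 4,
                trial_fn: Callable[[float, np.random.Generator], bool] | None = None,
                ) -> SessionResult:
    """Run ``n_staircases`` independent staircases and average their estimates."""
    if n_staircases < 4:
        raise ValueError("a session requires at least four staircases")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    states, thresholds = [], []
    for child in root.spawn(n_staircases):
        st = run_staircase(observer, config, np.random.default_rng(child), trial_fn=trial_fn)
        states.append(st)
        thresholds.append(estimate_threshold(st, config))
    return SessionResult(thresholds, states)
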