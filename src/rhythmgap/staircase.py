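"""Interleaved 2-down/1-up adaptive tracking of the gap deviation.

Within a block of 40 trials, early-onset and late-onset trials (20
each, in random order) drive two independent 2-down/1-up tracks on the
gap deviation dT/T.  The step is multiplicative: half the current level
until a track's second reversal, a quarter of the level thereafter.
Levels are clipped to the track bounds ([0, 1] early, [0, 2] late);
at a bound the level simply repeats until the rule moves it back in the
opposite direction.  The 2-down/1-up rule converges on the level where
the probability of two consecutive correct responses is one half, i.e.
the 70.7%-correct point of the psychometric function.  A block
threshold is the mean of the last four reversal levels; a condition
threshold is the mean over three blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TrackState",
    "BlockResult",
    "ThresholdEstimate",
    "update_track",
    "run_block",
    "estimate_threshold",
]

#: step size as a fraction of the current level, before/after the 2nd reversal
COARSE_STEP = 0.5
FINE_STEP = 0.25


@dataclass(frozen=True)
class TrackState:
    """State of one adaptive track (immutable; updates return new states)."""

    direction: str  # 'early' or 'late'
    level: float
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    consecutive_correct: int = 0
    reversals: tuple[float, ...] = ()
    last_move: str | None = None  # 'up' | 'down' | None
    step_phase: str = "coarse"  # 'coarse' (1/2) | 'fine' (1/4)

    def __post_init__(self) -> None:
        if not self.lower_bound <= self.level <= self.upper_bound:
            raise ValueError(
                f"level {self.level} outside bounds "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )

    @classmethod
    def initial(cls, direction: str) -> "TrackState":
        """Track at its experiment starting point: 1.0 in [0,1] for early
        onsets, 1.5 in [0,2] for late onsets."""
        if direction == "early":
            return cls("early", level=1.0, lower_bound=0.0, upper_bound=1.0)
        if direction == "late":
            return cls("late", level=1.5, lower_bound=0.0, upper_bound=2.0)
        raise ValueError(f"unknown direction {direction!r}")


def update_track(state: TrackState, correct: bool) -> TrackState:
    """Apply one response to a track under the 2-down/1-up rule.

    The step is computed from the level *before* the move.  A reversal
    is a change in the direction of movement; the level recorded for it
    is the pre-move level.  The move that produces a track's second
    reversal still uses the coarse half-step; subsequent moves use the
    quarter-step.  Clipping happens after the step; a move entirely
    absorbed by a bound (level unchanged) is a repetition, not a
    movement, so it neither sets the movement direction nor can it
    create a reversal.
    """
    if correct:
        streak = state.consecutive_correct + 1
        if streak < 2:
            return dataclasses.replace(state, consecutive_correct=streak)
        move = -1.0  # two in a row: level goes down
    else:
        move = +1.0  # any error: level goes up
    step_frac = COARSE_STEP if state.step_phase == "coarse" else FINE_STEP
    new_level = state.level + move * step_frac * state.level
    new_level = min(max(new_level, state.lower_bound), state.upper_bound)
    if new_level == state.level:
        return dataclasses.replace(state, consecutive_correct=0)
    this_move = "down" if move < 0 else "up"
    reversals = state.reversals
    step_phase = state.step_phase
    if state.last_move is not None and this_move != state.last_move:
        reversals = reversals + (state.level,)
        if len(reversals) >= 2:
            step_phase = "fine"
    return dataclasses.replace(
        state,
        level=new_level,
        consecutive_correct=0,
        reversals=reversals,
        last_move=this_move,
        step_phase=step_phase,
    )


@dataclass
class BlockResult:
    """Per-block outcome: final track states and the per-trial log."""

    tracks: dict  # direction -> final TrackState
    trial_log: list = field(default_factory=list)  # list of dict rows

    def reversals(self, direction: str) -> tuple[float, ...]:
        return self.tracks[direction].reversals


def run_block(
    tracks: dict[str, TrackState],
    respond: Callable[[str, float, np.random.Generator], bool],
    rng: np.random.Generator,
    trials_per_track: int = 20,
    trial_factory: Callable[[str, float, np.random.Generator], object] | None = None,
) -> BlockResult:
    """Run one interleaved block.

    ``tracks`` maps each direction to its starting :class:`TrackState`
    (tracks continue within a block only; each block restarts them).
    ``respond(direction, level, rng)`` returns whether the simulated
    listener answered correctly at the track's current level.  An
    optional ``trial_factory(direction, level, rng)`` builds a trial
    spec per trial purely for logging.
    """
    order = list(tracks) * trials_per_track
    order = [order[i] for i in rng.permutation(len(order))]
    tracks = dict(tracks)
    log: list[dict] = []
    for i, direction in enumerate(order):
        state = tracks[direction]
        trial = trial_factory(direction, state.level, rng) if trial_factory else None
        correct = bool(respond(direction, state.level, rng))
        new_state = update_track(state, correct)
        row = {
            "trial_index": i,
            "direction": direction,
            "level_before": state.level,
            "correct": correct,
            "level_after": new_state.level,
        }
        if trial is not None:
            row.update(
                rhythm_condition=trial.rhythm_condition,
                delta_frac=trial.delta_frac,
                altered_position=trial.altered_position,
                response=trial.altered_position if correct
                else ("second" if trial.altered_position == "first" else "first"),
            )
        log.append(row)
        tracks[direction] = new_state
    return BlockResult(tracks=tracks, trial_log=log)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Reversal-based threshold for one direction within one condition."""

    direction: str
    block_thresholds: tuple[float, ...]
    invalid_blocks: int = 0
    n_reversals_used: int = 4

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.block_thresholds))


def estimate_threshold(
    reversals_per_block: Sequence[Sequence[float]],
    direction: str = "",
    n_reversals: int = 4,
) -> ThresholdEstimate:
    """Mean of the last ``n_reversals`` reversal levels per block,
    averaged over blocks.

    Blocks with fewer than ``n_reversals`` reversals cannot support the
    estimator; they are flagged and excluded from the across-block mean.
    """
    block_thresholds = []
    invalid = 0
    for reversals in reversals_per_block:
        if len(reversals) < n_reversals:
            invalid += 1
            continue
        block_thresholds.append(float(np.mean(list(reversals)[-n_reversals:])))
    if not block_thresholds:
        raise ValueError("no block provided enough reversals for a threshold")
    return ThresholdEstimate(
        direction=direction,
        block_thresholds=tuple(block_thresholds),
        invalid_blocks=invalid,
        n_reversals_used=n_reversals,
    )
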