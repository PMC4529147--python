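"""1-up 2-down interleaved staircase calibration.

Two staircases (one starting below, one above the expected threshold) run in
strict alternation.  The rule raises the contrast after every error and
lowers it after two consecutive correct responses, so the converged level
satisfies ``P(correct)^2 = 0.5``, i.e. about 70.7% correct.  The threshold
estimate is the arithmetic mean of the last ``n_reversals_for_threshold``
reversal levels of each staircase, pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigError
from .observer import draw_trial
from .types import ObserverParams


@dataclass(frozen=True)
class StaircaseConfig:
    start_levels: tuple[float, float] = (0.02, 0.2)
    step_factor: float = 1.26  # 0.1 log10 units per step
    n_trials_total: int = 120
    n_reversals_for_threshold: int = 6
    min_level: float = 0.001
    max_level: float = 0.9

    def __post_init__(self):
        object.__setattr__(
            self, "start_levels", tuple(float(s) for s in self.start_levels)
        )
        if len(self.start_levels) != 2 or not self.start_levels[0] < self.start_levels[1]:
            raise ConfigError("start_levels must be (ascending, descending) with asc < desc")
        if not self.step_factor > 1:
            raise ConfigError("step_factor must be > 1")
        if self.n_trials_total < 2 or self.n_trials_total % 2 != 0:
            raise ConfigError("n_trials_total must be a positive even number")
        if self.n_reversals_for_threshold < 1:
            raise ConfigError("n_reversals_for_threshold must be >= 1")
        if not (0 < self.min_level < self.max_level):
            raise ConfigError("need 0 < min_level < max_level")
        if not all(self.min_level <= s <= self.max_level for s in self.start_levels):
            raise ConfigError("start_levels must lie within [min_level, max_level]")


@dataclass(frozen=True)
class StaircaseState:
    current_level: float
    consecutive_correct: int = 0
    last_move: str = "none"  # "up" | "down" | "none"
    reversal_levels: tuple = field(default_factory=tuple)
    trials_run: int = 0


def staircase_update(
    state: StaircaseState, correct: bool, cfg: StaircaseConfig
) -> StaircaseState:
    """Apply one trial outcome to the 1-up 2-down rule; pure function.

    An error moves the level up by ``step_factor``; two consecutive correct
    responses move it down by the same factor.  When a move changes
    direction, the pre-move level is recorded as a reversal.  Levels are
    clamped to [min_level, max_level]; a clamped move never counts as a
    reversal.
    """
    level = state.current_level
    if not correct:
        move, counter = "up", 0
        raw = level * cfg.step_factor
    elif state.consecutive_correct == 0:
        return replace(state, consecutive_correct=1, trials_run=state.trials_run + 1)
    else:
        move, counter = "down", 0
        raw = level / cfg.step_factor

    new_level = min(max(raw, cfg.min_level), cfg.max_level)
    clamped = new_level != raw
    reversals = state.reversal_levels
    if state.last_move in ("up", "down") and move != state.last_move and not clamped:
        reversals = reversals + (level,)
    return StaircaseState(
        current_level=new_level,
        consecutive_correct=counter,
        last_move=move,
        reversal_levels=reversals,
        trials_run=state.trials_run + 1,
    )


def run_staircases(
    respond,
    cfg: StaircaseConfig,
) -> tuple[float, pd.DataFrame]:
    """Run the two interleaved staircases against ``respond(level) -> bool``.

    Trials strictly alternate between the ascending-start and
    descending-start staircases (``n_trials_total`` trials in all).  Returns
    the pooled reversal-mean threshold and the trial-by-trial table.
    """
    states = [
        StaircaseState(current_level=cfg.start_levels[0]),
        StaircaseState(current_level=cfg.start_levels[1]),
    ]
    names = ("ascending", "descending")
    rows = []
    for t in range(cfg.n_trials_total):
        s = t % 2
        level = states[s].current_level
        correct = bool(respond(level))
        states[s] = staircase_update(states[s], correct, cfg)
        rows.append(
            {
                "trial_index": t + 1,
                "staircase": names[s],
                "contrast": level,
                "correct": correct,
                "n_reversals": len(states[s].reversal_levels),
            }
        )

    k = cfg.n_reversals_for_threshold
    pooled = []
    for name, st in zip(names, states):
        if len(st.reversal_levels) < k:
            raise CalibrationError(
                f"{name} staircase produced {len(st.reversal_levels)} reversals; "
                f"{k} required for a threshold"
            )
        pooled.extend(st.reversal_levels[-k:])
    return float(np.mean(pooled)), pd.DataFrame(rows)


def run_calibration(
    params: ObserverParams,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
) -> tuple[float, pd.DataFrame]:
    """Calibrate the contrast threshold for a simulated observer.

    Wraps :func:`run_staircases` with the signal-detection observer of
    :mod:`stressmeta.observer`; deterministic given the generator state.
    """
    def respond(level: float) -> bool:
        return draw_trial(params, level, rng)[2]

    return run_staircases(respond, cfg)
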