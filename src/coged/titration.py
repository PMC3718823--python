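"""Adjusting-amount staircase titration to indifference points.

One staircase per (condition, base amount): the participant repeatedly
chooses between a fixed larger offer for the hard (or delayed) option and
a variable smaller offer for the easy (or immediate) option.  Choosing the
hard option raises the easy offer by the current step; choosing the easy
option lowers it.  Each step is half the previous one.  With the canonical
parameters (start $1.00, first adjustment $0.50, six choices at a $2.00
base) the sixth adjustment is $0.015625 -- $0.015 at millicent truncation
-- and the post-final amount is the indifference point.

Every reachable amount is ``start +/- sum of a subset of {step/2^i}``; with
dyadic start and step these are exact binary floats, so no rounding error
accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARD",
    "EASY",
    "TitrationState",
    "IndifferenceRecord",
    "TrialSchedule",
    "StateExhaustedError",
    "ProtocolError",
    "apply_choice",
    "run_titration",
    "build_schedule",
]

#: Choice token for the larger-harder / larger-later option.
HARD = "HARD"
#: Choice token for the smaller-easier / smaller-sooner option.
EASY = "EASY"

DEFAULT_N_CHOICES = 6


class StateExhaustedError(RuntimeError):
    """A choice was applied after the configured maximum."""


class ProtocolError(ValueError):
    """An agent returned an invalid choice token."""


@dataclass(frozen=True)
class TitrationState:
    """Evolving adjusting-amount state for one staircase.

    ``variable_amount`` is the current easy offer; ``step`` is the size of
    the *next* adjustment.  After k choices the step is initial_step/2^k.
    """

    base_amount: float
    variable_amount: float
    step: float
    max_choices: int = DEFAULT_N_CHOICES
    choices_made: int = 0
    history: tuple[str, ...] = ()
    clamp: bool = False  # optional clamp to [0.01, base - 0.01]

    @property
    def exhausted(self) -> bool:
        return self.choices_made >= self.max_choices


@dataclass(frozen=True)
class IndifferenceRecord:
    """Indifference point for one (condition, base amount) staircase."""

    condition: Hashable
    base_amount: float
    indifference_amount: float
    n_choices: int
    history: tuple[str, ...] = ()


@dataclass(frozen=True)
class TrialSchedule:
    """Randomized non-nested trial order.

    ``trials`` is an ordered sequence of (condition, base_amount,
    choice_index) tuples; within each round all (condition, amount) pairs
    appear once in an independently shuffled order, so staircases are
    interleaved rather than run to completion one at a time.
    """

    trials: tuple[tuple[Hashable, float, int], ...]
    seed: int
    per_round_shuffle: bool = True

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.trials, columns=["condition", "base_amount", "choice_index"]
        )


def apply_choice(state: TitrationState, choice: str) -> TitrationState:
    """Apply one choice: HARD raises the easy offer, EASY lowers it.

    The adjustment uses the current step; the step then halves.
    """
    if state.exhausted:
        raise StateExhaustedError(
            f"staircase already has {state.choices_made} of "
            f"{state.max_choices} choices"
        )
    if choice == HARD:
        v = state.variable_amount + state.step
    elif choice == EASY:
        v = state.variable_amount - state.step
    else:
        raise ProtocolError(f"invalid choice token: {choice!r}")
    if state.clamp:
        v = min(max(v, 0.01), state.base_amount - 0.01)
    return replace(
        state,
        variable_amount=v,
        step=state.step / 2,
        choices_made=state.choices_made + 1,
        history=state.history + (choice,),
    )


def run_titration(
    agent: Callable[[float, float, Hashable], str],
    condition: Hashable,
    base_amount: float,
    start_amount: float | None = None,
    initial_step: float | None = None,
    n_choices: int = DEFAULT_N_CHOICES,
    clamp: bool = False,
) -> IndifferenceRecord:
    """Run one full staircase and return the indifference record.

    Parameters
    ----------
    agent : callable
        ``agent(easy_offer, base_amount, condition) -> "HARD" | "EASY"``.
    condition : hashable
        Load level N (effort) or delay in days (delay).
    base_amount : float
        Fixed offer for the hard/delayed option.
    start_amount, initial_step : float, optional
        Default to base/2 and base/4 -- the $1.00 start and $0.50 first
        adjustment at the canonical $2.00 base, and the
        adjusting-immediate-amount convention (50%/25% of the delayed
        amount) for delay discounting.
    n_choices : int
        Number of choices (default 6; the sixth adjustment is then
        initial_step/32 = $0.015625 at the defaults).

    Returns
    -------
    IndifferenceRecord
        The post-final variable amount; for any deterministic threshold
        agent it is within one final step of the true threshold.
    """
    if n_choices < 1:
        raise ValueError("n_choices must be >= 1")
    if base_amount <= 0:
        raise ValueError("base_amount must be positive")
    if start_amount is None:
        start_amount = base_amount / 2
    if initial_step is None:
        initial_step = base_amount / 4
    if start_amount <= 0:
        raise ValueError("start_amount must be positive")

    state = TitrationState(
        base_amount=base_amount,
        variable_amount=start_amount,
        step=initial_step,
        max_choices=n_choices,
        clamp=clamp,
    )
    for _ in range(n_choices):
        choice = agent(state.variable_amount, base_amount, condition)
        if choice not in (HARD, EASY):
            raise ProtocolError(f"agent returned invalid choice token: {choice!r}")
        state = apply_choice(state, choice)
    return IndifferenceRecord(
        condition=condition,
        base_amount=base_amount,
        indifference_amount=state.variable_amount,
        n_choices=n_choices,
        history=state.history,
    )


def build_schedule(
    conditions: Sequence[Hashable],
    base_amounts: Sequence[float] = (2.0,),
    n_choices: int = DEFAULT_N_CHOICES,
    seed: int = 0,
    per_round_shuffle: bool = True,
) -> TrialSchedule:
    """Build a randomized, non-nested trial schedule.

    For each round k = 1..n_choices every (condition, base_amount) pair is
    emitted once in a freshly shuffled order, interleaving staircases.
    With ``per_round_shuffle=False`` one global pair order is shuffled once
    and reused for every round.  Total trials = |conditions| x
    |base_amounts| x n_choices (e.g. 5 levels x 1 amount x 6 = 30 for the
    younger-adult effort design; 6 delays x 2 amounts x 6 = 72 for delay).
    """
    if not conditions:
        raise ValueError("conditions must be non-empty")
    if not base_amounts:
        raise ValueError("base_amounts must be non-empty")
    rng = np.random.default_rng(seed)
    pairs = [(c, float(a)) for c in conditions for a in base_amounts]
    trials: list[tuple[Hashable, float, int]] = []
    if per_round_shuffle:
        for k in range(1, n_choices + 1):
            order = rng.permutation(len(pairs))
            trials.extend((*pairs[i], k) for i in order)
    else:
        order = rng.permutation(len(pairs))
        for k in range(1, n_choices + 1):
            trials.extend((*pairs[i], k) for i in order)
    return TrialSchedule(trials=tuple(trials), seed=seed, per_round_shuffle=per_round_shuffle)
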