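"""Constrained N-back stimulus generation and run scoring.

The N-back working-memory task presents a stream of consonants; the
participant responds "target" whenever the current item matches the item
exactly N positions back.  Lists are built to exact constraint counts:

* **target** -- item identical to the item exactly N back,
* **lure** -- item that is not a target but repeats at some lag L with
  1 <= L <= N+2 and L != N (lures elicit false alarms and raise the
  effective difficulty of a level),
* **filler** -- item matching no prior item at any lag <= N+2.

The canonical run is 64 items with 16 targets and a level-dependent lure
count (8 for N=1, 6 for N=2, 5 for N=3, 3 for N=4..6).  Performance is
summarised with signal-detection sensitivity d' and correct-trial mean RT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CONSONANTS",
    "DEFAULT_LURE_COUNTS",
    "StimulusList",
    "RunPerformance",
    "ConstraintInfeasibleError",
    "generate_stimulus_list",
    "validate_stimulus_list",
    "score_run",
    "dprime",
]

#: Uppercase English consonants excluding the ambiguous Y.
CONSONANTS: str = "BCDFGHJKLMNPQRSTVWXZ"

#: Lures per level for the canonical 64-item run.
DEFAULT_LURE_COUNTS: dict[int, int] = {1: 8, 2: 6, 3: 5, 4: 3, 5: 3, 6: 3}

#: Display/timing metadata carried with each list; no real-time behaviour.
DISPLAY_METADATA: dict[str, float | str] = {
    "response_window_s": 1.5,
    "inter_item_interval_s": 3.5,
    "font": "Courier New 24pt",
}

GOOD_FEEDBACK = "Good job!"
BAD_FEEDBACK = "Please try harder!"

#: Maximum lure lag is level + this margin.
LURE_LAG_MARGIN = 2

MAX_ATTEMPTS = 10_000


class ConstraintInfeasibleError(ValueError):
    """Raised when the requested target/lure counts cannot be placed."""


@dataclass(frozen=True)
class StimulusList:
    """An ordered consonant sequence for one N-back run.

    Attributes
    ----------
    level : int
        Load level N (>= 1).
    items : tuple of str
        The consonant sequence.
    roles : tuple of str
        Per-item label in {"target", "lure", "filler"}.
    n_targets, n_lures : int
        Constraint counts the list was built to satisfy.
    seed : int
        RNG seed used for generation (reproducibility contract).
    """

    level: int
    items: tuple[str, ...]
    roles: tuple[str, ...]
    n_targets: int
    n_lures: int
    seed: int
    metadata: Mapping[str, float | str] = field(default_factory=lambda: dict(DISPLAY_METADATA))

    @property
    def length(self) -> int:
        return len(self.items)

    def is_target(self, i: int) -> bool:
        return self.roles[i] == "target"

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready representation (position, item, role, level)."""
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "item": list(self.items),
                "role": list(self.roles),
                "level": self.level,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.level,
                "items": list(self.items),
                "roles": list(self.roles),
                "n_targets": self.n_targets,
                "n_lures": self.n_lures,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "StimulusList":
        d = json.loads(payload)
        return cls(
            level=d["level"],
            items=tuple(d["items"]),
            roles=tuple(d["roles"]),
            n_targets=d["n_targets"],
            n_lures=d["n_lures"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class RunPerformance:
    """Signal-detection summary of one scored run."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    mean_rt: float
    pct_targets_correct: float
    pct_nontargets_correct: float
    feedback: str


def _classify(items: Sequence[str], level: int, i: int) -> str:
    """Role of position ``i`` by brute-force scan over all lags <= N+2."""
    it = items[i].upper()
    if i >= level and it == items[i - level].upper():
        return "target"
    max_lag = min(i, level + LURE_LAG_MARGIN)
    for lag in range(1, max_lag + 1):
        if lag == level:
            continue
        if it == items[i - lag].upper():
            return "lure"
    return "filler"


def generate_stimulus_list(
    level: int,
    length: int = 64,
    n_targets: int = 16,
    n_lures: int | None = None,
    seed: int = 0,
) -> StimulusList:
    """Generate a stimulus list with exact target and lure counts.

    Items are drawn from the 20-consonant alphabet.  Construction is
    sequential: a role plan (which positions are targets, which are lures)
    is sampled, then items are placed left to right so that every position
    realises exactly its planned role -- fillers avoid all lags <= N+2,
    lures copy a non-N lag without accidentally matching lag N, targets
    copy lag N.  Infeasible plans are rejected and resampled up to a
    bounded number of attempts.

    Parameters
    ----------
    level : int
        Load N >= 1.
    length : int
        Total item count (default 64).
    n_targets : int
        Exact number of targets (default 16).
    n_lures : int, optional
        Exact number of lures; defaults to the level's canonical count
        ({1: 8, 2: 6, 3: 5, >=4: 3}).
    seed : int
        RNG seed; same seed -> identical list.

    Raises
    ------
    ConstraintInfeasibleError
        If the counts cannot be placed within the attempt budget.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if length <= level:
        raise ConstraintInfeasibleError(
            f"length ({length}) must exceed level ({level})"
        )
    if n_lures is None:
        n_lures = DEFAULT_LURE_COUNTS.get(level, 3)
    if n_targets < 0 or n_lures < 0:
        raise ValueError("n_targets and n_lures must be non-negative")
    # Targets need i >= N; lures need i >= 1 and a usable non-N lag.
    if n_targets > length - level:
        raise ConstraintInfeasibleError(
            f"cannot place {n_targets} targets: only {length - level} positions "
            f"have a lag-{level} predecessor"
        )
    min_lure_pos = 1 if level != 1 else 2  # N=1 lures need lag 2 or 3
    if n_targets + n_lures > length - min_lure_pos:
        raise ConstraintInfeasibleError(
            f"cannot place {n_targets} targets and {n_lures} lures in {length} items"
        )

    rng = np.random.default_rng(seed)
    target_eligible = np.arange(level, length)
    lure_eligible = np.arange(min_lure_pos, length)

    for _ in range(MAX_ATTEMPTS):
        targets = set(rng.choice(target_eligible, size=n_targets, replace=False).tolist())
        remaining = np.array([p for p in lure_eligible if p not in targets])
        if len(remaining) < n_lures:
            continue
        lures = set(rng.choice(remaining, size=n_lures, replace=False).tolist())

        items: list[str] = []
        ok = True
        for i in range(length):
            if i in targets:
                items.append(items[i - level])
            elif i in lures:
                lags = [
                    lag
                    for lag in range(1, min(i, level + LURE_LAG_MARGIN) + 1)
                    if lag != level
                    # the copied item must not coincide with the lag-N item,
                    # which would silently promote the lure to a target
                    and not (i >= level and items[i - lag] == items[i - level])
                ]
                if not lags:
                    ok = False
                    break
                lag = int(rng.choice(lags))
                items.append(items[i - lag])
            else:
                forbidden = {
                    items[i - lag]
                    for lag in range(1, min(i, level + LURE_LAG_MARGIN) + 1)
                }
                allowed = [c for c in CONSONANTS if c not in forbidden]
                items.append(str(rng.choice(allowed)))
        if not ok:
            continue

        roles = tuple(_classify(items, level, i) for i in range(length))
        if roles.count("target") == n_targets and roles.count("lure") == n_lures:
            return StimulusList(
                level=level,
                items=tuple(items),
                roles=roles,
                n_targets=n_targets,
                n_lures=n_lures,
                seed=seed,
            )

    raise ConstraintInfeasibleError(
        f"could not satisfy (targets={n_targets}, lures={n_lures}) for level "
        f"{level}, length {length} after {MAX_ATTEMPTS} attempts"
    )


def validate_stimulus_list(sl: StimulusList | Sequence[str], level: int | None = None) -> dict[str, int]:
    """Recount roles by brute-force scan, independent of generator bookkeeping.

    Accepts a :class:`StimulusList` or a bare item sequence plus ``level``.
    Returns ``{"targets": ..., "lures": ..., "fillers": ...}``.
    """
    if isinstance(sl, StimulusList):
        items, lvl = sl.items, sl.level
    else:
        if level is None:
            raise ValueError("level is required when passing a bare sequence")
        items, lvl = tuple(sl), level
    if not items:
        raise ValueError("empty stimulus sequence")
    counts = {"targets": 0, "lures": 0, "fillers": 0}
    for i in range(len(items)):
        role = _classify(items, lvl, i)
        counts[role + "s" if role != "filler" else "fillers"] += 1
    return counts


def dprime(hits: int, n_targets: int, fas: int, n_nontargets: int) -> float:
    """Signal-detection d' = z(H) - z(F) with 1/(2n) rate clamping.

    Hit and false-alarm rates are clamped to [1/(2n), 1 - 1/(2n)] of their
    respective trial counts so that perfect or empty cells stay finite.
    """
    if n_targets <= 0 or n_nontargets <= 0:
        raise ValueError("n_targets and n_nontargets must be positive")
    if hits < 0 or fas < 0:
        raise ValueError("counts must be non-negative")
    h = np.clip(hits / n_targets, 1 / (2 * n_targets), 1 - 1 / (2 * n_targets))
    f = np.clip(fas / n_nontargets, 1 / (2 * n_nontargets), 1 - 1 / (2 * n_nontargets))
    return float(norm.ppf(h) - norm.ppf(f))


def score_run(
    sl: StimulusList,
    responses: Sequence[str | None],
    rts: Sequence[float | None] | None = None,
) -> RunPerformance:
    """Score one run against per-item responses.

    Parameters
    ----------
    sl : StimulusList
    responses : sequence
        Per-item response in {"target", "nontarget", None}; None = no
        response, counted as a non-target response (miss on targets,
        correct rejection on non-targets).
    rts : sequence, optional
        Per-item response times in seconds (None where no response).
        Mean RT is computed over correct responded trials only.

    Notes
    -----
    The first N positions cannot be targets and are excluded from both
    scoring denominators.  Feedback is "Good job!" iff both the target
    and non-target percentage scores exceed 50%.
    """
    if len(responses) != sl.length:
        raise ValueError(
            f"responses length {len(responses)} != stimulus length {sl.length}"
        )
    if rts is not None and len(rts) != sl.length:
        raise ValueError(f"rts length {len(rts)} != stimulus length {sl.length}")

    hits = misses = fas = crs = 0
    correct_rts: list[float] = []
    for i in range(sl.level, sl.length):
        said_target = responses[i] == "target"
        is_target = sl.is_target(i)
        correct = said_target == is_target
        if is_target:
            hits += said_target
            misses += not said_target
        else:
            fas += said_target
            crs += not said_target
        if correct and rts is not None and rts[i] is not None:
            correct_rts.append(float(rts[i]))

    n_targets = hits + misses
    n_nontargets = fas + crs
    hit_rate = hits / n_targets if n_targets else 0.0
    fa_rate = fas / n_nontargets if n_nontargets else 0.0
    pct_t = 100.0 * hit_rate
    pct_nt = 100.0 * (1.0 - fa_rate) if n_nontargets else 0.0
    d = dprime(hits, max(n_targets, 1), fas, max(n_nontargets, 1))
    mean_rt = float(np.mean(correct_rts)) if correct_rts else float("nan")
    feedback = GOOD_FEEDBACK if (pct_t > 50.0 and pct_nt > 50.0) else BAD_FEEDBACK
    return RunPerformance(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=d,
        mean_rt=mean_rt,
        pct_targets_correct=pct_t,
        pct_nontargets_correct=pct_nt,
        feedback=feedback,
    )
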