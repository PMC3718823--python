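"""Experiment configuration, payment selection, and the end-to-end pipeline.

An :class:`ExperimentConfig` captures a full session design (load levels,
base amounts, delays, staircase parameters).  Two presets mirror the
published designs:

* ``exp1``: younger adults titrate levels N = 2-6 against a $2.00 base
  (30 choices); older adults levels N = 2-4 (18 choices).
* ``exp2``: both groups titrate levels N = 2-4 at $1 and $5 bases
  (36 effort choices) plus delay discounting over six delays (1 week to
  10 years) at $1,000 and $25,000 (72 delay choices).

``run_pipeline`` chains simulate -> titrate -> value -> infer and writes
every artifact as CSV/JSON with a manifest of seeds and checksums, so the
same seed reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import CohortSpec, simulate_cohort
from .inference import fit_sv_mlm, linear_contrast
from .titration import EASY, HARD
from .valuation import DELAY_DAYS, amount_effect, discount_auc, ntlx_composite, SVCurve

__all__ = [
    "ExperimentConfig",
    "PaymentOutcome",
    "select_payment",
    "run_pipeline",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """A session design (serialisable to/from JSON)."""

    name: str = "custom"
    levels: tuple[int, ...] = (2, 3, 4)
    base_amounts: tuple[float, ...] = (2.0,)
    delays: tuple[float, ...] = ()
    delay_amounts: tuple[float, ...] = ()
    n_choices: int = 6
    start_fraction: float = 0.5  # start amount as fraction of base
    step_fraction: float = 0.25  # first adjustment as fraction of base
    performance_levels: tuple[int, ...] | None = None
    n_practice_runs: int = 3
    repetitions_paid: int = 4
    seed: int = 0

    @classmethod
    def exp1(cls, group: str = "ya", seed: int = 0) -> "ExperimentConfig":
        """Single $2.00 base; levels 2-6 (ya) or 2-4 (oa)."""
        levels = (2, 3, 4, 5, 6) if group == "ya" else (2, 3, 4)
        return cls(
            name=f"exp1_{group}",
            levels=levels,
            base_amounts=(2.0,),
            performance_levels=tuple(range(1, max(levels) + 1)),
            seed=seed,
        )

    @classmethod
    def exp2(cls, seed: int = 0) -> "ExperimentConfig":
        """Levels 2-4 at $1/$5 plus delay discounting at $1,000/$25,000."""
        return cls(
            name="exp2",
            levels=(2, 3, 4),
            base_amounts=(1.0, 5.0),
            delays=DELAY_DAYS,
            delay_amounts=(1000.0, 25000.0),
            performance_levels=(1, 2, 3, 4),
            seed=seed,
        )

    @property
    def n_effort_trials(self) -> int:
        return len(self.levels) * len(self.base_amounts) * self.n_choices

    @property
    def n_delay_trials(self) -> int:
        return len(self.delays) * len(self.delay_amounts) * self.n_choices

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "ExperimentConfig":
        d = json.loads(payload)
        for key in ("levels", "base_amounts", "delays", "delay_amounts",
                    "performance_levels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PaymentOutcome:
    """One randomly selected choice trial, repeated and paid."""

    participant_id: object
    condition: object
    base_amount: float
    offered_amount: float
    choice: str
    repetitions: int
    payout: float


def select_payment(
    trial_log: pd.DataFrame, repetitions: int = 4, seed: int = 0
) -> PaymentOutcome:
    """Draw one choice trial uniformly and pay the chosen option's amount.

    The payout is the amount of the option the participant actually chose
    on the drawn trial (the fixed base for HARD, the offered variable
    amount for EASY), times the number of paid repetitions.
    """
    if trial_log.empty:
        raise ValueError("trial log is empty; nothing to select for payment")
    if repetitions < 0:
        raise ValueError("repetitions must be >= 0")
    rng = np.random.default_rng(seed)
    row = trial_log.iloc[int(rng.integers(len(trial_log)))]
    amount = float(row["base_amount"] if row["choice"] == HARD else row["offered_amount"])
    return PaymentOutcome(
        participant_id=row.get("participant_id"),
        condition=row["condition"],
        base_amount=float(row["base_amount"]),
        offered_amount=float(row["offered_amount"]),
        choice=str(row["choice"]),
        repetitions=repetitions,
        payout=amount * repetitions,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: ExperimentConfig,
    cohort: CohortSpec,
    out_dir: str | Path,
) -> dict:
    """Simulate a cohort, derive SV/AUC tables, fit models, write artifacts.

    Writes ``trials.csv``, ``sv_long.csv``, ``delay_long.csv``,
    ``ntlx.csv``, ``participants.csv``, ``auc.csv``, ``models.json``,
    ``config.json`` and ``manifest.json`` (seeds, versions, SHA-256
    checksums) under ``out_dir``.  Same config + cohort seed -> identical
    checksums.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_cohort(cohort, config)

    # per-participant AUC table (effort; plus delay when configured)
    auc_rows = [
        {
            "participant_id": r.participant_id,
            "domain": r.domain,
            "base_amount": r.base_amount,
            "auc": r.auc,
        }
        for r in map(discount_auc, data.effort_curves())
    ]
    for curve in data.delay_curves():
        r = discount_auc(curve)
        auc_rows.append(
            {
                "participant_id": r.participant_id,
                "domain": "delay",
                "base_amount": r.base_amount,
                "auc": r.auc,
            }
        )
    auc_df = pd.DataFrame(auc_rows)

    # NTLX composite per participant
    composites = []
    for pid, g in data.ntlx.groupby("participant_id"):
        scores = {
            scale: dict(zip(sub["level"], sub["rating"]))
            for scale, sub in g.groupby("scale")
        }
        composites.append(
            {"participant_id": pid, "ntlx_composite": ntlx_composite(scores)}
        )
    participants = data.participants.merge(
        pd.DataFrame(composites), on="participant_id", how="left"
    )

    # models: the anchored random-intercept fit at the first base amount,
    # with age terms when both groups are present
    models: dict = {}
    amt0 = config.base_amounts[0]
    sv0 = data.sv_long[data.sv_long["base_amount"] == amt0]
    sv0 = sv0[sv0["level"].isin([1, 2, 3, 4])]
    try:
        fit = fit_sv_mlm(sv0, include_anchor=True, age_terms=sv0["age"].nunique() > 1)
        models["sv_mlm"] = json.loads(
            fit.to_frame().to_json(orient="index", double_precision=10)
        )
        models["sv_mlm_variances"] = {
            "random_intercept": fit.random_intercept_var,
            "residual": fit.residual_var,
        }
    except ValueError as err:
        models["sv_mlm"] = {"error": str(err)}

    contrast_in = data.sv_long.dropna(subset=["sv"])
    contrast_in = contrast_in[contrast_in["base_amount"] == amt0]
    models["load_linear_contrast"] = linear_contrast(
        contrast_in.rename(columns={"level": "condition", "sv": "value"})
    )
    if len(config.base_amounts) == 2:
        eff = data.sv_long.dropna(subset=["sv"]).rename(columns={"level": "condition"})
        eff["domain"] = "effort"
        models["amount_effect"] = amount_effect(
            eff[["participant_id", "domain", "base_amount", "condition", "sv"]]
        )

    files = {
        "trials.csv": data.trials,
        "sv_long.csv": data.sv_long,
        "delay_long.csv": data.delay_long,
        "ntlx.csv": data.ntlx,
        "participants.csv": participants,
        "auc.csv": auc_df,
    }
    for name, df in files.items():
        _write_csv(df, out / name)
    (out / "config.json").write_text(config.to_json())
    (out / "models.json").write_text(json.dumps(models, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "config_name": config.name,
        "config_seed": config.seed,
        "cohort_seed": cohort.seed,
        "n_per_group": cohort.n_per_group,
        "checksums": {
            name: _sha256(out / name)
            for name in [*files, "config.json", "models.json"]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
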