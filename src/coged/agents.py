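"""Synthetic participants for closed-loop simulation and parameter recovery.

Each agent carries latent valuation parameters:

* effort: true SV(N) = clamp(1 - kappa * (N - 1) * base**(-gamma), 0, 1) --
  a linear decline in load whose steepness shrinks with the base amount
  when the amount-sensitivity exponent gamma > 0 (magnitude effect);
* delay: hyperbolic present value V = A / (1 + k(A) * D days), with
  k decreasing in amount so larger rewards are discounted less;
* choice: deterministic value comparison at temperature tau = 0 (ties go
  to EASY), else P(choose hard) = logistic(value difference / tau), so tau
  is interpretable as dollars of decision noise.

Performance is simulated as d' = d0 - delta*(N-1) + noise (floored at 0)
and RT = rt0 + rt_slope*(N-1) + noise, with age-group differences entering
through the cohort-level parameter distributions.

All randomness flows from a single cohort seed through per-agent
``numpy`` substreams, so a cohort is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .titration import EASY, HARD, build_schedule, TitrationState, apply_choice
from .valuation import DELAY_DAYS, NTLX_SCALES, SVCurve, discount_auc

__all__ = [
    "AgentParams",
    "GroupSpec",
    "CohortSpec",
    "CohortData",
    "true_effort_sv",
    "true_delay_value",
    "choose",
    "make_agent",
    "simulate_performance",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AgentParams:
    """Latent parameters of one synthetic participant."""

    kappa: float = 0.15  # effort cost per load step, fraction of base
    gamma: float = 0.0  # amount-sensitivity exponent (>= 0)
    k_delay: float | Mapping[float, float] = 0.01  # hyperbolic rate per day
    tau: float = 0.0  # choice temperature in dollars (0 = deterministic)
    age_group: int = 0  # 0 = younger adult, 1 = older adult
    d0: float = 3.42  # d' at N = 1
    delta: float = 0.59  # d' decline per load step
    rt0: float = 0.592  # mean correct RT at N = 1 (seconds)
    rt_slope: float = 0.04  # RT increase per load step (seconds)
    d_noise: float = 0.0  # run-level d' noise SD
    rt_noise: float = 0.0  # run-level RT noise SD (seconds)
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def true_effort_sv(params: AgentParams, level: int, base: float = 2.0) -> float:
    """Latent subjective value of the hard offer at a given load level.

    SV = clamp(1 - kappa*(level-1)*base^(-gamma), 0, 1): equal to 1 at the
    reference level N = 1, decreasing in level, and increasing in the base
    amount when gamma > 0.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    sv = 1.0 - params.kappa * (level - 1) * base ** (-params.gamma)
    return float(min(max(sv, 0.0), 1.0))


def _k_for_amount(params: AgentParams, amount: float) -> float:
    k = params.k_delay
    if isinstance(k, Mapping):
        if amount in k:
            return float(k[amount])
        # nearest configured amount
        nearest = min(k, key=lambda a: abs(a - amount))
        return float(k[nearest])
    return float(k)


def true_delay_value(params: AgentParams, amount: float, delay_days: float) -> float:
    """Hyperbolic present value of a delayed reward: A / (1 + k(A) * D)."""
    if delay_days < 0:
        raise ValueError("delay_days must be >= 0")
    return amount / (1.0 + _k_for_amount(params, amount) * delay_days)


def _hard_value(params: AgentParams, hard_offer: float, condition) -> float:
    domain, value = condition if isinstance(condition, tuple) else ("effort", condition)
    if domain == "delay":
        return true_delay_value(params, hard_offer, value)
    return true_effort_sv(params, value, hard_offer) * hard_offer


def choose(
    params: AgentParams,
    easy_offer: float,
    hard_offer: float,
    condition,
    rng: np.random.Generator | None = None,
) -> str:
    """One choice between the variable easy offer and the fixed hard offer.

    ``condition`` is a load level (effort) or a ("delay", days) tuple.
    Deterministic agents (tau = 0) pick the higher-valued option, with
    exact ties resolved to EASY; noisy agents choose HARD with probability
    ``logistic((value_hard - value_easy) / tau)``.
    """
    if easy_offer < 0 or hard_offer < 0:
        raise ValueError("offers must be non-negative")
    vh = _hard_value(params, hard_offer, condition)
    ve = float(easy_offer)
    if params.tau == 0:
        return HARD if vh > ve else EASY
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p_hard = float(expit((vh - ve) / params.tau))
    return HARD if rng.random() < p_hard else EASY


def make_agent(
    params: AgentParams, rng: np.random.Generator | None = None
) -> Callable[[float, float, Hashable], str]:
    """Bind parameters (and an RNG stream) into a titration callback."""
    if rng is None:
        rng = np.random.default_rng(params.seed)

    def agent(easy_offer: float, hard_offer: float, condition) -> str:
        return choose(params, easy_offer, hard_offer, condition, rng=rng)

    return agent


def simulate_performance(
    params: AgentParams,
    level: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulate (d', mean RT seconds) for one run at a load level."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    d = params.d0 - params.delta * (level - 1)
    if params.d_noise > 0:
        d += rng.normal(0.0, params.d_noise)
    rt = params.rt0 + params.rt_slope * (level - 1)
    if params.rt_noise > 0:
        rt += rng.normal(0.0, params.rt_noise)
    return float(max(d, 0.0)), float(max(rt, 0.2))


# ---------------------------------------------------------------------------
# Cohort-level simulation


@dataclass(frozen=True)
class GroupSpec:
    """Parameter distributions for one age group.

    Defaults emulate the qualitative published patterns: younger adults
    with a mean effort cost of 0.14 per load step (mean AUC near 0.72 over
    levels 2-4) and older adults near 0.30 (mean AUC near 0.4); d'
    intercepts/slopes and RT levels follow the observed load-performance
    profile for each group.
    """

    kappa_mean: float = 0.14
    kappa_sd: float = 0.10
    gamma_mean: float = 0.05
    gamma_sd: float = 0.05
    tau: float = 0.05
    k_delay_mean: float = 0.010  # per day, at the smaller delayed amount
    k_delay_log_sd: float = 0.8
    k_amount_factor: float = 0.5  # multiplies k at the larger amount
    d0_mean: float = 3.42
    d0_sd: float = 0.9
    delta_mean: float = 0.59
    delta_sd: float = 0.15
    rt0_mean: float = 0.592
    rt0_sd: float = 0.10
    rt_slope_mean: float = 0.040
    rt_slope_sd: float = 0.015
    d_noise: float = 0.30
    rt_noise: float = 0.05
    income_mean_bin: float = 5.0
    income_sd: float = 2.0


#: Older-adult defaults: steeper effort costs, stronger amount sensitivity,
#: lower d', slower RTs, and somewhat lower income bins.
OA_DEFAULTS = GroupSpec(
    kappa_mean=0.30,
    kappa_sd=0.14,
    gamma_mean=0.15,
    gamma_sd=0.10,
    k_delay_mean=0.007,
    d0_mean=3.13,
    d0_sd=0.8,
    delta_mean=0.58,
    rt0_mean=0.785,
    rt0_sd=0.11,
    rt_slope_mean=0.025,
    income_mean_bin=4.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """A two-group cohort: sample size and per-group distributions."""

    n_per_group: int = 25
    ya: GroupSpec = field(default_factory=GroupSpec)
    oa: GroupSpec = field(default_factory=lambda: OA_DEFAULTS)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass
class CohortData:
    """Synthetic cohort output in the shared tidy schemas.

    Attributes
    ----------
    participants : DataFrame
        One row per agent: covariates (age, ncs, income_bin, ratings),
        NTLX composite, AUCs, and the generating latent parameters
        (columns prefixed ``true_``).
    trials : DataFrame
        Trial log: (participant_id, phase, condition, base_amount,
        choice_index, offered_amount, choice, rt).
    sv_long : DataFrame
        Effort SV per participant x level x base amount with per-level
        performance (d_prime, mean_rt); N = 1 rows have sv = NaN (the
        anchor value 1.0 is a modelling choice applied downstream).
    delay_long : DataFrame
        Delay SV per participant x delay x amount.
    ntlx : DataFrame
        Ratings per participant x scale x level.
    """

    participants: pd.DataFrame
    trials: pd.DataFrame
    sv_long: pd.DataFrame
    delay_long: pd.DataFrame
    ntlx: pd.DataFrame

    def effort_curves(self, base_amount: float | None = None) -> list[SVCurve]:
        if self.sv_long.empty:
            return []
        df = self.sv_long.dropna(subset=["sv"])
        if base_amount is not None:
            df = df[df["base_amount"] == base_amount]
        return [
            SVCurve(pid, amt, dict(zip(g["level"], g["sv"])), domain="effort")
            for (pid, amt), g in df.groupby(["participant_id", "base_amount"])
        ]

    def delay_curves(self, amount: float | None = None) -> list[SVCurve]:
        if self.delay_long.empty:
            return []
        df = self.delay_long
        if amount is not None:
            df = df[df["base_amount"] == amount]
        return [
            SVCurve(pid, amt, dict(zip(g["delay_days"], g["sv"])), domain="delay")
            for (pid, amt), g in df.groupby(["participant_id", "base_amount"])
        ]


# NTLX generating profile: per-scale (rating at N=1, increase per load step),
# matching the published workload pattern in shape.
_NTLX_PROFILE = {
    "mental_demand": (6.3, 3.4),
    "physical_demand": (2.6, 0.9),
    "temporal_demand": (8.3, 1.6),
    "failure": (6.3, 2.2),
    "effort": (6.7, 2.9),
    "frustration": (5.9, 1.9),
}


def _draw_agent(group: GroupSpec, age: int, seed: int, rng: np.random.Generator) -> AgentParams:
    kappa = max(0.0, rng.normal(group.kappa_mean, group.kappa_sd))
    gamma = max(0.0, rng.normal(group.gamma_mean, group.gamma_sd))
    k_small = group.k_delay_mean * math.exp(rng.normal(0.0, group.k_delay_log_sd))
    return AgentParams(
        kappa=kappa,
        gamma=gamma,
        k_delay={1000.0: k_small, 25000.0: k_small * group.k_amount_factor},
        tau=group.tau,
        age_group=age,
        d0=max(0.5, rng.normal(group.d0_mean, group.d0_sd)),
        delta=max(0.0, rng.normal(group.delta_mean, group.delta_sd)),
        rt0=max(0.3, rng.normal(group.rt0_mean, group.rt0_sd)),
        rt_slope=rng.normal(group.rt_slope_mean, group.rt_slope_sd),
        d_noise=group.d_noise,
        rt_noise=group.rt_noise,
        seed=seed,
    )


def _run_interleaved(
    params: AgentParams,
    phase: str,
    conditions,
    base_amounts,
    n_choices: int,
    rng: np.random.Generator,
    schedule_seed: int,
    start_frac: float = 0.5,
    step_frac: float = 0.25,
) -> tuple[list[dict], dict]:
    """Run all staircases of one phase in randomized non-nested order."""
    sched = build_schedule(
        list(conditions), list(base_amounts), n_choices=n_choices, seed=schedule_seed
    )
    states: dict[tuple, TitrationState] = {
        (c, a): TitrationState(
            base_amount=a,
            variable_amount=a * start_frac,
            step=a * step_frac,
            max_choices=n_choices,
        )
        for c in conditions
        for a in base_amounts
    }
    rows = []
    for cond, amt, k in sched.trials:
        st = states[(cond, amt)]
        cond_token = ("delay", cond) if phase == "delay" else cond
        ch = choose(params, st.variable_amount, amt, cond_token, rng=rng)
        rows.append(
            {
                "phase": phase,
                "condition": cond,
                "base_amount": amt,
                "choice_index": k,
                "offered_amount": st.variable_amount,
                "choice": ch,
                "rt": float(rng.lognormal(0.3, 0.4)),
            }
        )
        states[(cond, amt)] = apply_choice(st, ch)
    indiff = {key: st.variable_amount for key, st in states.items()}
    return rows, indiff


def simulate_cohort(spec: CohortSpec, design) -> CohortData:
    """Simulate a full cohort through a session design.

    ``design`` provides the session structure (duck-typed; see
    :class:`coged.session.ExperimentConfig`): attributes ``levels``,
    ``base_amounts``, ``delays``, ``delay_amounts``, ``n_choices``,
    ``performance_levels``, ``n_practice_runs``.  Each agent runs every
    effort staircase (per base amount) and, if delays are configured,
    every delay staircase; practice performance is simulated per level and
    averaged across runs.  Reproducible under ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    n = spec.n_per_group
    agent_seeds = root.spawn(2 * n)
    trial_rows, sv_rows, delay_rows, ntlx_rows, part_rows = [], [], [], [], []

    delays = tuple(getattr(design, "delays", ()) or ())
    delay_amounts = tuple(getattr(design, "delay_amounts", ()) or ())
    perf_levels = tuple(
        getattr(design, "performance_levels", None)
        or sorted({1, *design.levels})
    )
    n_runs = int(getattr(design, "n_practice_runs", 3))

    for idx in range(2 * n):
        age = 0 if idx < n else 1
        group = spec.ya if age == 0 else spec.oa
        ss = agent_seeds[idx]
        rng = np.random.default_rng(ss)
        pid = f"{'ya' if age == 0 else 'oa'}{(idx % n) + 1:03d}"
        params = _draw_agent(group, age, int(ss.generate_state(1)[0] % 2**31), rng)

        # practice performance, averaged over runs per level
        perf: dict[int, tuple[float, float]] = {}
        for lvl in perf_levels:
            runs = [simulate_performance(params, lvl, rng) for _ in range(n_runs)]
            perf[lvl] = (
                float(np.mean([r[0] for r in runs])),
                float(np.mean([r[1] for r in runs])),
            )

        # effort discounting
        rows, indiff = _run_interleaved(
            params,
            "effort",
            list(design.levels),
            list(design.base_amounts),
            design.n_choices,
            rng,
            schedule_seed=int(ss.generate_state(2)[1] % 2**31),
        )
        for r in rows:
            r["participant_id"] = pid
        trial_rows.extend(rows)

        for amt in design.base_amounts:
            for lvl in sorted({1, *design.levels}):
                d_lvl, rt_lvl = perf.get(lvl, (np.nan, np.nan))
                sv = (
                    indiff[(lvl, amt)] / amt
                    if (lvl, amt) in indiff
                    else (np.nan if lvl == 1 else np.nan)
                )
                sv_rows.append(
                    {
                        "participant_id": pid,
                        "age": age,
                        "level": lvl,
                        "base_amount": amt,
                        "sv": sv,
                        "d_prime": d_lvl,
                        "mean_rt": rt_lvl,
                        "true_sv": true_effort_sv(params, lvl, amt),
                    }
                )

        # delay discounting
        if delays and delay_amounts:
            rows, dindiff = _run_interleaved(
                params,
                "delay",
                list(delays),
                list(delay_amounts),
                design.n_choices,
                rng,
                schedule_seed=int(ss.generate_state(3)[2] % 2**31),
            )
            for r in rows:
                r["participant_id"] = pid
            trial_rows.extend(rows)
            for (dd, amt), v in dindiff.items():
                delay_rows.append(
                    {
                        "participant_id": pid,
                        "age": age,
                        "delay_days": dd,
                        "base_amount": amt,
                        "sv": v / amt,
                        "true_sv": true_delay_value(params, amt, dd) / amt,
                    }
                )

        # NTLX ratings per scale per practiced level
        oa_shift = 1.0 if age == 1 else 0.0
        for scale in NTLX_SCALES:
            b0, slope = _NTLX_PROFILE[scale]
            for lvl in perf_levels:
                rating = b0 + oa_shift + slope * (lvl - 1) + rng.normal(0, 3.0)
                ntlx_rows.append(
                    {
                        "participant_id": pid,
                        "age": age,
                        "scale": scale,
                        "level": lvl,
                        "rating": float(np.clip(rating, 0, 21)),
                    }
                )

        # participant covariates
        auc_levels = [l for l in (2, 3, 4) if l in design.levels]
        amt0 = design.base_amounts[0]
        curve = SVCurve(
            pid,
            amt0,
            {l: indiff[(l, amt0)] / amt0 for l in design.levels},
            domain="effort",
        )
        auc0 = discount_auc(curve).auc if len(auc_levels) >= 2 else np.nan
        true_auc = np.nan
        if len(auc_levels) >= 2:
            tcurve = SVCurve(
                pid,
                amt0,
                {l: true_effort_sv(params, l, amt0) for l in auc_levels},
                domain="effort",
            )
            true_auc = discount_auc(tcurve).auc
        income = int(np.clip(round(rng.normal(group.income_mean_bin, group.income_sd)), 1, 9))
        ncs = float(40 + 30 * (true_auc if np.isfinite(true_auc) else 0.5) + rng.normal(0, 10))
        part_rows.append(
            {
                "participant_id": pid,
                "age": age,
                "ncs": ncs,
                "income_bin": income,
                "rating_amount_based": float(
                    np.clip(rng.normal(7.7 - 1.9 * age, 1.5), 1, 10)
                ),
                "rating_score_based": float(
                    np.clip(rng.normal(4.9 + 1.7 * age, 1.8), 1, 10)
                ),
                "auc_effort": auc0,
                "true_auc_effort": true_auc,
                "true_kappa": params.kappa,
                "true_gamma": params.gamma,
                "true_tau": params.tau,
            }
        )

    cols = [
        "participant_id",
        "phase",
        "condition",
        "base_amount",
        "choice_index",
        "offered_amount",
        "choice",
        "rt",
    ]
    return CohortData(
        participants=pd.DataFrame(part_rows),
        trials=pd.DataFrame(trial_rows)[cols] if trial_rows else pd.DataFrame(columns=cols),
        sv_long=pd.DataFrame(sv_rows),
        delay_long=pd.DataFrame(delay_rows),
        ntlx=pd.DataFrame(ntlx_rows),
    )
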