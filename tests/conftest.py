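"""Shared fixtures: small synthetic cohorts and deterministic agents."""

import numpy as np
import pandas as pd
import pytest

from coged import CohortSpec, ExperimentConfig, GroupSpec, simulate_cohort
from coged.titration import EASY, HARD


def threshold_agent(v_star: float):
    """Deterministic agent preferring HARD iff the easy offer < threshold."""

    def agent(easy_offer, base_amount, condition):
        return HARD if easy_offer < v_star else EASY

    return agent


@pytest.fixture(scope="session")
def small_exp2_cohort():
    """10 + 10 agents through the two-amount effort + delay design."""
    return simulate_cohort(CohortSpec(n_per_group=10, seed=11), ExperimentConfig.exp2(seed=11))


@pytest.fixture(scope="session")
def deterministic_cohort():
    """Noise-free choices (tau = 0): titrated SV must track true SV."""
    spec = CohortSpec(
        n_per_group=8,
        ya=GroupSpec(tau=0.0),
        oa=GroupSpec(tau=0.0, kappa_mean=0.30, kappa_sd=0.14),
        seed=5,
    )
    return simulate_cohort(spec, ExperimentConfig.exp1("ya", seed=5))


def mlm_cohort(
    n: int = 25,
    slope: float = -0.13,
    intercept_sd: float = 0.08,
    resid_sd: float = 0.05,
    beta_dprime: float = 0.0,
    beta_rt: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate directly from the random-intercept generative model.

    Levels 1-4 per participant; SV = 1 + b0_j + slope * (N - 2.5)
    + beta_d * d' + beta_rt * mRT + e_ij, with observed per-level
    performance predictors.  Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n):
        b0 = rng.normal(0.0, intercept_sd)
        for lvl in (1, 2, 3, 4):
            d = 3.4 - 0.6 * (lvl - 1) + rng.normal(0, 0.3)
            rt = 0.6 + 0.05 * (lvl - 1) + rng.normal(0, 0.05)
            sv = (
                0.675  # grand intercept placing SVs in a plausible band
                + b0
                + slope * (lvl - 2.5)
                + beta_dprime * d
                + beta_rt * rt
                + rng.normal(0, resid_sd)
            )
            rows.append(
                {
                    "participant_id": f"p{j:03d}",
                    "age": 0,
                    "level": lvl,
                    "sv": sv,
                    "d_prime": d,
                    "mean_rt": rt,
                    "base_amount": 2.0,
                }
            )
    return pd.DataFrame(rows)
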