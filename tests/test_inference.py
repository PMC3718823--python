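"""Multilevel-model estimation, contrasts, group tests, covariate models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from coged.inference import (
    RankDeficientError,
    SubjectiveValueModel,
    covariate_regressions,
    fit_sv_mlm,
    fit_sv_mlm_ratio,
    group_compare,
    hierarchical_delta_r2,
    linear_contrast,
)
from conftest import mlm_cohort


def noiseless_frame(n=6, slope=-0.1):
    """SV exactly linear in load; performance varies but has no effect."""
    rng = np.random.default_rng(0)
    rows = []
    for j in range(n):
        a, b = rng.normal(3.2, 0.4), rng.normal(0.6, 0.05)
        for lvl in (1, 2, 3, 4):
            rows.append(
                {
                    "participant_id": j,
                    "age": 0,
                    "level": lvl,
                    "sv": 1.0 + slope * (lvl - 1),
                    "d_prime": a - 0.5 * (lvl - 1) + rng.normal(0, 0.2),
                    "mean_rt": b + 0.04 * (lvl - 1) + rng.normal(0, 0.02),
                }
            )
    return pd.DataFrame(rows)


def test_noiseless_linear_sv_recovered_exactly():
    fit = fit_sv_mlm(noiseless_frame(slope=-0.1), include_anchor=True)
    assert fit.params["N_c"] == pytest.approx(-0.1, abs=1e-9)
    assert fit.params["d_prime"] == pytest.approx(0.0, abs=1e-9)
    assert fit.params["mean_rt"] == pytest.approx(0.0, abs=1e-9)
    assert fit.residual_var == pytest.approx(0.0, abs=1e-12)


def test_reml_matches_statsmodels_on_homogeneous_fit():
    import statsmodels.formula.api as smf

    df = mlm_cohort(n=25, intercept_sd=0.15, seed=4)
    fit = fit_sv_mlm(df, include_anchor=True)
    ref = df.copy()
    ref["N_c"] = ref["level"] - 2.5
    m = smf.mixedlm(
        "sv ~ d_prime + mean_rt + N_c", ref, groups=ref["participant_id"]
    ).fit(reml=True)
    np.testing.assert_allclose(fit.params.values, m.fe_params.values, atol=1e-4)
    assert fit.llf == pytest.approx(m.llf, abs=1e-5)
    assert fit.residual_var == pytest.approx(m.scale, rel=1e-3)
    assert fit.random_intercept_var == pytest.approx(
        float(m.cov_re.iloc[0, 0]), rel=5e-2, abs=1e-5
    )
    np.testing.assert_allclose(fit.bse.values, m.bse_fe.values, rtol=2e-2)


def test_df_convention_follows_within_between_split():
    df = mlm_cohort(n=25, seed=1)
    fit = fit_sv_mlm(df, include_anchor=True)
    # 100 obs - 25 participants - 3 within slopes = 72
    assert fit.df["N_c"] == 72
    assert fit.df["d_prime"] == 72
    two_group = pd.concat(
        [df, mlm_cohort(n=25, seed=2).assign(age=1,
         participant_id=lambda d: "oa_" + d.participant_id)],
        ignore_index=True,
    )
    fit2 = fit_sv_mlm(two_group, include_anchor=True, age_terms=True)
    assert fit2.df["N_c"] == 200 - 50 - 4
    assert fit2.df["Age"] == 50 - 1 - 1


def test_single_cohort_load_slope_recovery():
    df = mlm_cohort(n=25, slope=-0.13, seed=11)
    fit = fit_sv_mlm(df, include_anchor=True)
    ci = 1.96 * fit.bse["N_c"]
    assert abs(fit.params["N_c"] - (-0.13)) < 2.5 * fit.bse["N_c"]
    assert fit.pvalues["N_c"] < 0.01


def test_load_slope_interval_coverage_is_calibrated():
    """~95% of t-based intervals for the load slope cover the truth."""
    from scipy.stats import t as tdist

    hits = 0
    n_rep = 120
    for s in range(n_rep):
        df = mlm_cohort(n=10, slope=-0.13, seed=1000 + s)
        fit = fit_sv_mlm(df, include_anchor=True)
        crit = tdist.ppf(0.975, fit.df["N_c"])
        lo = fit.params["N_c"] - crit * fit.bse["N_c"]
        hi = fit.params["N_c"] + crit * fit.bse["N_c"]
        hits += lo <= -0.13 <= hi
    cover = hits / n_rep
    # binomial SE at 0.95 with 120 reps is ~0.02
    assert 0.88 <= cover <= 1.0


def test_rank_deficient_design_raises():
    df = noiseless_frame()
    df["mean_rt"] = 2 * df["d_prime"]  # exact collinearity
    with pytest.raises(RankDeficientError):
        SubjectiveValueModel(df)


def test_age_steeper_cohorts_give_negative_age_terms():
    rng = np.random.default_rng(3)
    rows = []
    for age, (b0, slope) in enumerate([(0.8, -0.10), (0.55, -0.20)]):
        for j in range(20):
            u = rng.normal(0, 0.06)
            for lvl in (1, 2, 3, 4):
                rows.append(
                    {
                        "participant_id": f"{age}_{j}",
                        "age": age,
                        "level": lvl,
                        "sv": b0 + u + slope * (lvl - 2.5) + rng.normal(0, 0.05),
                        "d_prime": 3.3 - 0.6 * (lvl - 1) + rng.normal(0, 0.3),
                        "mean_rt": 0.6 + 0.04 * (lvl - 1) + rng.normal(0, 0.05),
                    }
                )
    fit = fit_sv_mlm(pd.DataFrame(rows), include_anchor=False, age_terms=True)
    assert fit.params["Age"] < 0
    assert fit.params["Age:N_c"] < 0


def test_heterogeneous_variance_never_fits_worse():
    for seed in (0, 5, 9):
        df = pd.concat(
            [
                mlm_cohort(n=10, resid_sd=0.03, seed=seed),
                mlm_cohort(n=10, resid_sd=0.12, seed=seed + 100).assign(
                    age=1, participant_id=lambda d: "oa_" + d.participant_id
                ),
            ],
            ignore_index=True,
        )
        fit = fit_sv_mlm(df, age_terms=True, heterogeneous_by_age=True)
        lr = fit.lr_heterogeneous
        assert lr["stat"] >= 0
        assert fit.llf >= lr["llf_homogeneous"] - 1e-8
        assert isinstance(fit.residual_var, dict)
        # group 1 was generated noisier
        assert fit.residual_var[1] > fit.residual_var[0]


def test_anchor_rows_drive_the_age_by_load_interaction():
    """Older group whose decline is the N=1 -> N>1 drop: the interaction is
    carried by the anchor row and shrinks materially without it."""
    rng = np.random.default_rng(8)
    rows = []
    for age in (0, 1):
        for j in range(22):
            u = rng.normal(0, 0.05)
            for lvl in (1, 2, 3, 4):
                if age == 0:
                    sv = 1.0 - 0.10 * (lvl - 1)
                else:
                    sv = 1.0 if lvl == 1 else 0.62 - 0.10 * (lvl - 2)
                rows.append(
                    {
                        "participant_id": f"{age}_{j}",
                        "age": age,
                        "level": lvl,
                        "sv": sv + u + rng.normal(0, 0.04),
                        "d_prime": 3.3 - 0.6 * (lvl - 1) + rng.normal(0, 0.3),
                        "mean_rt": 0.6 + 0.04 * (lvl - 1) + rng.normal(0, 0.05),
                    }
                )
    df = pd.DataFrame(rows)
    with_anchor = fit_sv_mlm(df, include_anchor=True, age_terms=True)
    without = fit_sv_mlm(df, include_anchor=False, age_terms=True)
    assert with_anchor.params["Age:N_c"] < -0.05
    assert with_anchor.pvalues["Age:N_c"] < 0.01
    assert abs(without.params["Age:N_c"]) < abs(with_anchor.params["Age:N_c"]) / 2
    # the age main effect survives either way
    assert with_anchor.params["Age"] < 0
    assert without.params["Age"] < 0
    assert without.pvalues["Age"] < 0.01


def test_ratio_model_drops_constant_ratios_and_keeps_load_slope():
    df = noiseless_frame(slope=-0.12)
    base = df[df.level == 1].set_index("participant_id")
    # force performance identical across levels -> ratios are exactly 1
    for col in ("d_prime", "mean_rt"):
        df[col] = base.loc[df["participant_id"], col].to_numpy()
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_sv_mlm_ratio(df)
    assert fit.params["N_c"] == pytest.approx(-0.12, abs=1e-9)
    assert "ratio_d_prime" not in fit.params.index
    # anchor rows excluded by construction: participants x 3 levels
    assert fit.n_obs == df["participant_id"].nunique() * 3


def test_ratio_model_recovers_load_only_effect():
    df = mlm_cohort(n=20, slope=-0.16, seed=6)
    fit = fit_sv_mlm_ratio(df)
    assert fit.params["N_c"] < -0.10
    assert fit.pvalues["N_c"] < 0.01
    assert abs(fit.params["ratio_d_prime"]) < 0.15
    missing = df[df.level > 1]
    with pytest.raises(ValueError, match="N = 1"):
        fit_sv_mlm_ratio(missing)


# -- linear contrast --------------------------------------------------------


def brute_force_contrast(groups):
    """Independent sums-of-squares oracle."""
    conds = sorted(groups)
    w = np.array(conds, float) - np.mean(conds)
    means = np.array([np.mean(groups[c]) for c in conds])
    ns = np.array([len(groups[c]) for c in conds])
    ss_contrast = (w @ means) ** 2 / float((w**2 / ns).sum())
    allv = np.concatenate([np.asarray(groups[c], float) for c in conds])
    ss_total = ((allv - allv.mean()) ** 2).sum()
    ss_within = sum(
        ((np.asarray(groups[c], float) - np.mean(groups[c])) ** 2).sum()
        for c in conds
    )
    df_err = len(allv) - len(conds)
    f = ss_contrast / (ss_within / df_err)
    return f, ss_contrast / ss_total


def test_linear_contrast_constant_data_returns_zero():
    out = linear_contrast({1: [2.0, 2.0], 2: [2.0, 2.0], 3: [2.0, 2.0]})
    assert out["F"] == 0.0
    assert out["eta_squared"] == 0.0


def test_linear_contrast_pure_linear_signal_saturates_eta():
    out = linear_contrast({1: [1.0, 1.0], 2: [2.0, 2.0], 3: [3.0, 3.0]})
    assert out["eta_squared"] == pytest.approx(1.0)
    assert math.isinf(out["F"])


def test_linear_contrast_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        groups = {c: rng.normal(3 - 0.4 * c, 1.0, size=4) for c in (1, 2, 3)}
        out = linear_contrast(groups)
        f, eta = brute_force_contrast(groups)
        assert out["F"] == pytest.approx(f)
        assert out["eta_squared"] == pytest.approx(eta)
        assert out["df"] == (1, 9)


# -- group comparisons ------------------------------------------------------


def test_identical_samples_compare_as_equal():
    x = [0.2, 0.4, 0.6, 0.8]
    out = group_compare(x, list(x), paired=True)
    assert out["wilcoxon_p"] == 1.0
    out2 = group_compare(x, list(x), paired=False)
    assert out2["wilcoxon_p"] > 0.9


def test_separated_samples_match_exact_enumeration():
    x = np.arange(10) + 100.0
    y = np.arange(10)
    out = group_compare(x, y)
    # all 10 x's rank above all y's: two-sided exact p = 2 / C(20, 10)
    exact = 2 / math.comb(20, 10)
    assert out["wilcoxon_p"] == pytest.approx(exact)


def test_group_comparison_power_at_published_effect_size():
    """0.72 vs 0.36 mean AUC with sd 0.25 at n = 25/25: power > 0.8."""
    rng = np.random.default_rng(2)
    rejections = 0
    n_rep = 100
    for _ in range(n_rep):
        ya = np.clip(rng.normal(0.72, 0.25, 25), 0, 1)
        oa = np.clip(rng.normal(0.36, 0.25, 25), 0, 1)
        if group_compare(ya, oa)["wilcoxon_p"] < 0.05:
            rejections += 1
    assert rejections / n_rep > 0.8


# -- covariate regressions --------------------------------------------------


def participant_table(n=50, seed=0, age_effect=-0.3):
    rng = np.random.default_rng(seed)
    age = np.repeat([0, 1], n // 2)
    noise_cov = rng.normal(0, 1, n)
    auc_eff = np.clip(0.75 + age_effect * age + rng.normal(0, 0.15, n), 0, 1)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "age": age,
            "auc_effort": auc_eff,
            "auc_delay": np.clip(
                0.5 + 0.05 * rng.normal(size=n) + 0.04 * rng.normal(size=n), 0, 1
            ),
            "ncs": 40 + 25 * auc_eff + rng.normal(0, 8, n),
            "income_bin": rng.integers(1, 10, n),
            "ntlx_composite": rng.normal(11, 3, n),
            "noise_cov": noise_cov,
        }
    )


def test_duplicated_predictor_adds_zero_r2():
    tab = participant_table()
    tab["ncs_copy"] = tab["ncs"]
    out = hierarchical_delta_r2(tab, "auc_effort", ["ncs"], ["ncs_copy"])
    assert out["delta_r2"] == pytest.approx(0.0, abs=1e-10)


def test_age_effect_detected_controlling_for_noise_covariate():
    detections = 0
    for s in range(30):
        tab = participant_table(seed=s)
        out = hierarchical_delta_r2(tab, "auc_effort", ["noise_cov"], ["age"])
        detections += out["p"] < 0.05
    assert detections / 30 > 0.8


def test_covariate_battery_assembles_expected_models():
    tab = participant_table(seed=5)
    out = covariate_regressions(tab)
    assert {"ncs_from_auc", "ncs_hierarchical", "delay_income",
            "effort_income", "age_domain_income", "logistic_age"} <= set(out)
    assert out["ncs_hierarchical"]["delta_r2"] > 0.1
    assert out["effort_income"].pvalues["age"] < 0.05
    assert out["age_domain_income"]["with_income"].params["age_x_domain"] < 0


def test_logistic_separation_raises_warning():
    tab = participant_table(seed=1)
    tab["auc_effort"] = np.where(tab["age"] == 1, 0.1, 0.9)  # separable
    with pytest.warns(UserWarning, match="separation"):
        out = covariate_regressions(tab)
    assert out["logistic_age"]["separation"] is True
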