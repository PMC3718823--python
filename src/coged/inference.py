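"""Random-intercept multilevel models of subjective value and related tests.

The central model regresses relative subjective value on load-related
performance (d', mean RT) and centered load, with a normally distributed
participant-specific intercept:

    SV_ij = B0_j + B1 d'_ij + B2 mRT_ij + B3 N_c,ij (+ age terms) + e_ij
    B0_j ~ Normal(mu, tau^2),  e_ij ~ Normal(0, sigma^2_k)

Load is centered (N_2.5 = N - 2.5 for levels 1-4, so codes run -1.5..1.5).
The reference level N = 1 has no empirically titrated SV; its theoretical
anchor SV_1 = 1 can be included or excluded, and a ratio-predictor variant
(performance at each level divided by its N = 1 value, load centered at 3)
re-estimates the load effect without the anchor rows.

Estimation maximises the restricted log-likelihood (REML).  The residual
variance may be homogeneous or stratified by age group k; the stratified
fit reports a likelihood-ratio statistic against the nested homogeneous
fit.  Fixed-effect t-tests use a within/between degrees-of-freedom split:
within-participant terms get n_obs - n_participants - q_within df, and
between-participant terms get n_participants - q_between - 1.

Also provided: one-way linear-contrast ANOVA with eta^2, rank-based and
t group comparisons, and the covariate regression battery (hierarchical
delta-R^2, income/domain models, logistic age prediction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "SubjectiveValueModel",
    "SubjectiveValueResults",
    "RankDeficientError",
    "ConvergenceError",
    "fit_sv_mlm",
    "fit_sv_mlm_ratio",
    "linear_contrast",
    "group_compare",
    "covariate_regressions",
    "hierarchical_delta_r2",
]

_VAR_FLOOR = 1e-10


class RankDeficientError(np.linalg.LinAlgError):
    """The fixed-effects design matrix is singular."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimiser diagnostic."""


# ---------------------------------------------------------------------------
# REML machinery


def _reml_terms(y, X, groups, sigma2_by_obs, tau2):
    """Accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| over participants.

    Each participant block is V_j = sigma^2_j I + tau^2 11'; Woodbury gives
    V_j^-1 = (1/sigma^2_j)(I - c_j 11') with c_j = tau^2/(sigma^2_j + n_j tau^2).
    """
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdetV = 0.0
    for g in np.unique(groups):
        idx = groups == g
        Xg, yg = X[idx], y[idx]
        s2 = sigma2_by_obs[idx][0]
        n_g = idx.sum()
        c = tau2 / (s2 + n_g * tau2)
        x1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtVX += (Xg.T @ Xg - c * np.outer(x1, x1)) / s2
        XtVy += (Xg.T @ yg - c * x1 * y1) / s2
        ytVy += (yg @ yg - c * y1 * y1) / s2
        logdetV += (n_g - 1) * np.log(s2) + np.log(s2 + n_g * tau2)
    return XtVX, XtVy, ytVy, logdetV


def _restricted_loglik(theta, y, X, groups, group_sigma_idx, n_sigma):
    """theta = [log tau^2, log sigma^2_1, ..., log sigma^2_K]."""
    theta = np.clip(theta, -30.0, 30.0)  # keep the boundary walk finite
    tau2 = np.exp(theta[0])
    sig2 = np.exp(theta[1 : 1 + n_sigma])
    sigma2_by_obs = sig2[group_sigma_idx]
    XtVX, XtVy, ytVy, logdetV = _reml_terms(y, X, groups, sigma2_by_obs, tau2)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
    except np.linalg.LinAlgError:
        return -np.inf
    n, p = X.shape
    rss = ytVy - beta @ XtVy  # r'V^-1 r at the GLS solution
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdet_XtVX + rss)


@dataclass
class SubjectiveValueResults:
    """REML fit of the random-intercept subjective-value model.

    Coefficient tables follow the (B, SE, df, t, p) layout; ``df`` uses
    the within/between decomposition described in the module docstring.
    """

    model: "SubjectiveValueModel"
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    random_intercept_var: float
    residual_var: float | dict
    llf: float  # restricted log-likelihood
    converged: bool
    n_obs: int
    n_groups: int
    lr_heterogeneous: dict | None = None  # {"stat":, "p":, "llf_homogeneous":}

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df), index=self.params.index
        )

    @property
    def n_varparams(self) -> int:
        return 1 + (len(self.residual_var) if isinstance(self.residual_var, dict) else 1)

    @property
    def aic(self) -> float:
        k = len(self.params) + self.n_varparams
        return -2 * self.llf + 2 * k

    @property
    def bic(self) -> float:
        k = len(self.params) + self.n_varparams
        return -2 * self.llf + k * np.log(self.n_obs)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table with columns B, SE, df, t, p."""
        return pd.DataFrame(
            {
                "B": self.params,
                "SE": self.bse,
                "df": self.df,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Random-intercept model of subjective value (REML)",
            f"  observations: {self.n_obs}   participants: {self.n_groups}",
            f"  restricted log-likelihood: {self.llf:.3f}"
            f"   AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            f"  random-intercept variance: {self.random_intercept_var:.5f}",
        ]
        if isinstance(self.residual_var, dict):
            sv = "   ".join(f"group {k}: {v:.5f}" for k, v in self.residual_var.items())
            lines.append(f"  residual variance (heterogeneous): {sv}")
            if self.lr_heterogeneous is not None:
                lines.append(
                    "  LR vs homogeneous residual: "
                    f"{self.lr_heterogeneous['stat']:.3f} "
                    f"(p = {self.lr_heterogeneous['p']:.3f})"
                )
        else:
            lines.append(f"  residual variance: {self.residual_var:.5f}")
        lines.append("")
        lines.append(
            self.to_frame()
            .assign(df=lambda d: d["df"].astype(int))
            .to_string(float_format=lambda v: f"{v: .4f}")
        )
        return "\n".join(lines)


class SubjectiveValueModel:
    """Random-intercept model of SV on performance and centered load.

    Parameters
    ----------
    data : DataFrame
        Long format, one row per participant x level (x base amount):
        columns ``participant_id``, ``level``, ``sv``, ``d_prime``,
        ``mean_rt`` and (for age terms) ``age`` in {0, 1}.
    include_anchor : bool
        If True, rows at the reference level (N = 1) enter with the
        theoretical SV = 1.0 and their observed performance; if False,
        reference-level rows are dropped.
    age_terms : bool
        Add Age and Age x N_c fixed effects (dummy-coded, 1 = older).
    heterogeneous_by_age : bool
        Stratify the residual variance by age group and report the
        likelihood-ratio statistic against the homogeneous fit.
    center : float
        Load-centering constant; 2.5 for levels 1-4 (codes -1.5..1.5).
    performance : sequence of str
        Performance predictor columns (default d' and mean RT).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        include_anchor: bool = True,
        age_terms: bool = False,
        heterogeneous_by_age: bool = False,
        center: float = 2.5,
        performance: Sequence[str] = ("d_prime", "mean_rt"),
        sv_col: str = "sv",
        level_col: str = "level",
        reference_level: int = 1,
    ):
        df = data.copy()
        if include_anchor:
            ref = df[level_col] == reference_level
            df.loc[ref, sv_col] = df.loc[ref, sv_col].fillna(1.0)
        else:
            df = df[df[level_col] != reference_level]
        df = df.dropna(subset=[sv_col, *performance])
        if df.empty:
            raise ValueError("no usable rows after anchor handling")
        counts = df.groupby("participant_id")[level_col].nunique()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"participants with < 2 levels: {bad}")

        df = df.reset_index(drop=True)
        df["N_c"] = df[level_col] - center
        names = ["Intercept", *performance, "N_c"]
        cols = [np.ones(len(df))] + [df[c].to_numpy(float) for c in performance]
        cols.append(df["N_c"].to_numpy(float))
        if age_terms:
            if "age" not in df:
                raise ValueError("age_terms=True requires an 'age' column")
            cols.append(df["age"].to_numpy(float))
            cols.append((df["age"] * df["N_c"]).to_numpy(float))
            names += ["Age", "Age:N_c"]
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientError(
                f"fixed-effects design is rank deficient (terms: {names})"
            )

        self.frame = df
        self.exog_names = names
        self.exog = X
        self.endog = df[sv_col].to_numpy(float)
        codes, _ = pd.factorize(df["participant_id"])
        self.groups = codes
        self.heterogeneous_by_age = heterogeneous_by_age
        self.age_terms = age_terms
        if heterogeneous_by_age:
            if "age" not in df:
                raise ValueError("heterogeneous_by_age=True requires an 'age' column")
            # residual-variance stratum of each participant
            ages = df.groupby(codes)["age"].first().to_numpy(int)
            self.group_strata = ages
            self.n_sigma = len(np.unique(ages))
        else:
            self.group_strata = np.zeros(len(np.unique(codes)), dtype=int)
            self.n_sigma = 1

    # -- degrees of freedom -------------------------------------------------
    def _df_split(self) -> pd.Series:
        """Within/between df per coefficient.

        A term is *between* when it is constant within every participant
        (e.g. Age); all other slopes are *within* (performance, load, and
        the age-by-load interaction).  df_within = n - J - q_within;
        df_between = J - q_between - 1.
        """
        df = self.frame
        n, J = len(df), df["participant_id"].nunique()
        is_between = {}
        for j, name in enumerate(self.exog_names):
            if name == "Intercept":
                is_between[name] = True
                continue
            col = pd.Series(self.exog[:, j])
            is_between[name] = bool(
                (col.groupby(self.groups).nunique() == 1).all()
            )
        q_within = sum(
            1 for nm in self.exog_names if nm != "Intercept" and not is_between[nm]
        )
        q_between = sum(
            1 for nm in self.exog_names if nm != "Intercept" and is_between[nm]
        )
        df_w = n - J - q_within
        df_b = max(J - q_between - 1, 1)
        return pd.Series(
            {nm: (df_b if is_between[nm] else df_w) for nm in self.exog_names}
        )

    # -- estimation ---------------------------------------------------------
    def _fit_variances(self, n_sigma, group_strata):
        y, X, groups = self.endog, self.exog, self.groups
        strata_by_obs = group_strata[groups]

        # exact-fit shortcut: noiseless data make the REML surface singular
        ols_beta, ols_res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ ols_beta
        if float(resid @ resid) / len(y) < 1e-14:
            return ols_beta, 0.0, np.zeros(n_sigma), -np.inf, True

        # moment-based start values
        var_tot = float(np.var(resid))
        theta0 = np.log(np.full(1 + n_sigma, max(var_tot / 2, _VAR_FLOOR)))

        def neg(theta):
            return -_restricted_loglik(theta, y, X, groups, strata_by_obs, n_sigma)

        out = optimize.minimize(
            neg,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 10_000},
        )
        if not out.success or not np.isfinite(out.fun):
            raise ConvergenceError(
                f"REML optimisation failed: {out.message} "
                f"(iterations: {out.nit}, final objective: {out.fun})"
            )
        x = np.clip(out.x, -30.0, 30.0)
        tau2 = float(np.exp(x[0]))
        sig2 = np.exp(x[1 : 1 + n_sigma])
        XtVX, XtVy, _, _ = _reml_terms(y, X, groups, sig2[strata_by_obs], tau2)
        beta = np.linalg.solve(XtVX, XtVy)
        return beta, tau2, sig2, float(-out.fun), True

    def fit(self) -> SubjectiveValueResults:
        """Estimate by REML and return a results object."""
        beta, tau2, sig2, llf, conv = self._fit_variances(
            self.n_sigma, self.group_strata
        )
        strata_by_obs = self.group_strata[self.groups]
        sigma2_by_obs = np.maximum(sig2, _VAR_FLOOR)[strata_by_obs]
        XtVX, *_ = _reml_terms(
            self.endog, self.exog, self.groups, sigma2_by_obs, max(tau2, _VAR_FLOOR)
        )
        cov = np.linalg.inv(XtVX)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=self.exog_names)

        lr = None
        residual_var: float | dict
        if self.n_sigma > 1:
            residual_var = {int(k): float(sig2[k]) for k in range(self.n_sigma)}
            # nested homogeneous fit for the LR statistic
            _, _, _, llf_hom, _ = self._fit_variances(
                1, np.zeros_like(self.group_strata)
            )
            stat = max(0.0, 2 * (llf - llf_hom))
            lr = {
                "stat": stat,
                "p": float(stats.chi2.sf(stat, self.n_sigma - 1)),
                "llf_homogeneous": llf_hom,
            }
        else:
            residual_var = float(sig2[0])

        return SubjectiveValueResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=bse,
            df=self._df_split(),
            random_intercept_var=tau2,
            residual_var=residual_var,
            llf=llf,
            converged=conv,
            n_obs=len(self.endog),
            n_groups=len(np.unique(self.groups)),
            lr_heterogeneous=lr,
        )


def fit_sv_mlm(
    data: pd.DataFrame,
    include_anchor: bool = True,
    heterogeneous_by_age: bool = False,
    age_terms: bool = False,
    center: float = 2.5,
) -> SubjectiveValueResults:
    """Fit the subjective-value multilevel model (functional wrapper)."""
    return SubjectiveValueModel(
        data,
        include_anchor=include_anchor,
        age_terms=age_terms,
        heterogeneous_by_age=heterogeneous_by_age,
        center=center,
    ).fit()


def fit_sv_mlm_ratio(
    data: pd.DataFrame,
    levels: Sequence[int] = (2, 3, 4),
    center: float = 3.0,
    age_terms: bool = False,
    heterogeneous_by_age: bool = False,
) -> SubjectiveValueResults:
    """Anchor-free variant: performance ratios to N = 1, load centered at 3.

    Requires an N = 1 row per participant to form ratio predictors
    d'(N)/d'(1) and mRT(N)/mRT(1); only levels 2-4 enter the fit.  If a
    ratio predictor is constant (collinear with the intercept) it is
    dropped with a warning and the load slope is estimated without it.
    """
    base = data[data["level"] == 1].set_index("participant_id")
    if base.empty:
        raise ValueError("ratio model requires N = 1 performance rows")
    df = data[data["level"].isin(levels)].copy()
    missing = set(df["participant_id"]) - set(base.index)
    if missing:
        raise ValueError(f"participants missing N = 1 baseline: {sorted(missing)}")
    df["ratio_d_prime"] = (
        df["d_prime"].to_numpy()
        / base.loc[df["participant_id"], "d_prime"].to_numpy()
    )
    df["ratio_mean_rt"] = (
        df["mean_rt"].to_numpy()
        / base.loc[df["participant_id"], "mean_rt"].to_numpy()
    )
    performance = []
    for col in ("ratio_d_prime", "ratio_mean_rt"):
        if np.isclose(df[col].std(ddof=0), 0.0):
            warnings.warn(
                f"{col} is constant across rows; dropped (collinear with intercept)"
            )
        else:
            performance.append(col)
    return SubjectiveValueModel(
        df,
        include_anchor=False,
        age_terms=age_terms,
        heterogeneous_by_age=heterogeneous_by_age,
        center=center,
        performance=tuple(performance),
    ).fit()


# ---------------------------------------------------------------------------
# Contrasts and group comparisons


def linear_contrast(
    data: Mapping[float, Sequence[float]] | pd.DataFrame,
    condition_col: str = "condition",
    value_col: str = "value",
) -> dict:
    """One-way linear-contrast ANOVA over ordered conditions.

    Contrast weights are the centered condition coordinates; F has
    (1, N - k) degrees of freedom with the within-cell mean square as the
    error term, and eta^2 = SS_contrast / SS_total.  Constant data return
    F = 0 rather than raising.
    """
    if isinstance(data, pd.DataFrame):
        groups = {
            float(c): g[value_col].to_numpy(float)
            for c, g in data.groupby(condition_col)
        }
    else:
        groups = {float(c): np.asarray(v, float) for c, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions for a linear contrast")
    conds = np.array(sorted(groups))
    weights = conds - conds.mean()
    means = np.array([groups[c].mean() for c in conds])
    ns = np.array([len(groups[c]) for c in conds])
    n_total = int(ns.sum())
    grand = np.concatenate([groups[c] for c in conds])

    est = float(weights @ means)
    denom = float((weights**2 / ns).sum())
    ss_contrast = est**2 / denom if denom > 0 else 0.0
    ss_within = float(sum(((groups[c] - groups[c].mean()) ** 2).sum() for c in conds))
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    df_error = n_total - len(conds)
    if ss_total == 0:
        return {"F": 0.0, "df": (1, df_error), "p": 1.0, "eta_squared": 0.0}
    ms_error = ss_within / df_error if df_error > 0 else 0.0
    if ms_error == 0:
        f = np.inf if ss_contrast > 0 else 0.0
    else:
        f = ss_contrast / ms_error
    p = float(stats.f.sf(f, 1, df_error)) if np.isfinite(f) else 0.0
    return {
        "F": float(f),
        "df": (1, df_error),
        "p": p,
        "eta_squared": ss_contrast / ss_total,
    }


def group_compare(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
) -> dict:
    """Rank-based and t comparisons of two samples.

    Unpaired: Wilcoxon rank-sum (Mann-Whitney U, exact when feasible) and
    independent-samples t.  Paired: Wilcoxon signed-rank and paired t.
    Identical samples return p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired and len(x) != len(y):
        raise ValueError("paired comparison requires equal-length samples")
    out = {"mean_x": float(x.mean()), "mean_y": float(y.mean()), "paired": paired}
    if paired:
        if np.allclose(x, y):
            out["wilcoxon_p"] = 1.0
            out["t_p"] = 1.0
            return out
        out["wilcoxon_p"] = float(stats.wilcoxon(x, y).pvalue)
        out["t_p"] = float(stats.ttest_rel(x, y).pvalue)
    else:
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (not ties and max(len(x), len(y)) <= 25) else "auto"
        mw = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out["wilcoxon_p"] = float(mw.pvalue)
        out["t_p"] = float(stats.ttest_ind(x, y).pvalue)
    return out


# ---------------------------------------------------------------------------
# Covariate regressions


def hierarchical_delta_r2(
    table: pd.DataFrame,
    response: str,
    base_terms: Sequence[str],
    added_terms: Sequence[str],
) -> dict:
    """Increment in R^2 from adding terms to a base OLS model."""
    df = table.dropna(subset=[response, *base_terms, *added_terms])
    y = df[response]
    X0 = sm.add_constant(df[list(base_terms)])
    X1 = sm.add_constant(df[list(base_terms) + list(added_terms)])
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    ftest = fit1.compare_f_test(fit0)
    return {
        "r2_base": float(fit0.rsquared),
        "r2_full": float(fit1.rsquared),
        "delta_r2": float(fit1.rsquared - fit0.rsquared),
        "f": float(ftest[0]),
        "p": float(ftest[1]),
        "fit_base": fit0,
        "fit_full": fit1,
    }


def _logistic_age(table: pd.DataFrame, predictors: Sequence[str]) -> dict:
    df = table.dropna(subset=["age", *predictors])
    X = sm.add_constant(df[list(predictors)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(df["age"], X).fit(disp=0)
        return {"fit": fit, "separation": False, "pvalues": fit.pvalues.to_dict()}
    except Exception as err:  # separation surfaces as error or warning-as-error
        warnings.warn(
            f"logistic age model shows (quasi-)separation or non-convergence: {err}",
            stacklevel=2,
        )
        return {"fit": None, "separation": True, "pvalues": {}}


def covariate_regressions(table: pd.DataFrame) -> dict:
    """The covariate regression battery over a participant-level table.

    Expects columns (NaN-tolerant; each analysis uses what it needs):
    ``age`` (0/1), ``auc_effort``, ``auc_delay``, ``ncs``, ``income_bin``,
    ``ntlx_composite``, ``rating_amount_based``, ``rating_score_based``.

    Returns a dict of fitted models / summaries:

    * ``ncs_from_auc`` -- OLS of NCS on effort AUC (trait validity).
    * ``ncs_hierarchical`` -- delta-R^2 of age on effort AUC over NCS.
    * ``delay_income`` / ``effort_income`` -- AUC on age + income bin.
    * ``age_domain_income`` -- long-format AUC on age x domain with and
      without the income covariate.
    * ``logistic_age`` -- age from effort AUC (+ NTLX composite when
      available), with separation detection.
    """
    out: dict = {}
    cols = set(table.columns)

    if {"ncs", "auc_effort"} <= cols:
        df = table.dropna(subset=["ncs", "auc_effort"])
        out["ncs_from_auc"] = sm.OLS(
            df["ncs"], sm.add_constant(df[["auc_effort"]])
        ).fit()
    if {"ncs", "auc_effort", "age"} <= cols:
        out["ncs_hierarchical"] = hierarchical_delta_r2(
            table, "auc_effort", ["ncs"], ["age"]
        )
    if {"auc_delay", "age", "income_bin"} <= cols:
        df = table.dropna(subset=["auc_delay", "age", "income_bin"])
        out["delay_income"] = sm.OLS(
            df["auc_delay"], sm.add_constant(df[["age", "income_bin"]])
        ).fit()
    if {"auc_effort", "age", "income_bin"} <= cols:
        df = table.dropna(subset=["auc_effort", "age", "income_bin"])
        out["effort_income"] = sm.OLS(
            df["auc_effort"], sm.add_constant(df[["age", "income_bin"]])
        ).fit()
    if {"auc_effort", "auc_delay", "age", "income_bin"} <= cols:
        df = table.dropna(subset=["auc_effort", "auc_delay", "age", "income_bin"])
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "auc": df["auc_effort"],
                        "domain": 1,
                        "age": df["age"],
                        "income_bin": df["income_bin"],
                    }
                ),
                pd.DataFrame(
                    {
                        "auc": df["auc_delay"],
                        "domain": 0,
                        "age": df["age"],
                        "income_bin": df["income_bin"],
                    }
                ),
            ],
            ignore_index=True,
        )
        long["age_x_domain"] = long["age"] * long["domain"]
        with_income = sm.OLS(
            long["auc"],
            sm.add_constant(long[["age", "domain", "age_x_domain", "income_bin"]]),
        ).fit()
        without_income = sm.OLS(
            long["auc"], sm.add_constant(long[["age", "domain", "age_x_domain"]])
        ).fit()
        out["age_domain_income"] = {
            "with_income": with_income,
            "without_income": without_income,
        }
    if {"age", "auc_effort"} <= cols:
        predictors = ["auc_effort"]
        if "ntlx_composite" in cols:
            predictors.append("ntlx_composite")
        out["logistic_age"] = _logistic_age(table, predictors)
    return out
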