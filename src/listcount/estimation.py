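"""Prevalence estimators and Wald tests for list-experiment data.

The prevalence of the sensitive behaviour is the treatment effect in the
difference-in-means regression

    Y_i = lambda + beta^l T_i + eps_i                    (single list l)

and, pooling both lists of the double-list design with a list fixed effect,

    Y_i = lambda + beta T_i + delta 1(List = A) + eps_i  (pooled)

with standard errors clustered at the respondent level in the pooled fit,
since every respondent contributes one treated and one control observation.
Subgroup prevalences come from the fully interacted model
``Y ~ T * S`` (plus the list flag when pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import LongDataset, SurveyDataset

CLASSICAL = "classical"
ROBUST = "heterosked-robust"
CLUSTER = "cluster-robust"

_COV_TYPES = {CLASSICAL: "nonrobust", ROBUST: "HC1", "robust": "HC1"}


class DegenerateDesignError(ValueError):
    """Both treatment arms (or all S x T cells) are required for estimation."""


@dataclass
class PrevalenceEstimate:
    """A fitted prevalence with its uncertainty.

    ``beta`` is the estimated prevalence (treated-minus-control mean count),
    ``lam`` the control-arm intercept.
    """

    beta: float
    lam: float
    se: float
    ci95: tuple[float, float]
    n_obs: int
    scope: str
    se_flavor: str
    clustered: bool = False
    arm_means: tuple[float, float] | None = None  # (treated, control)
    influence: pd.Series | None = field(default=None, repr=False)


@dataclass
class SubgroupEstimate:
    """Interacted-model estimates: prevalence at S=0 and S=1."""

    beta: float          # prevalence among S = 0
    gamma: float         # level shift of the count for S = 1
    alpha: float         # interaction: prevalence difference S=1 minus S=0
    se_beta: float
    se_prevalence_s1: float
    n_obs: int
    scope: str
    subgroup: str

    @property
    def prevalence_s1(self) -> float:
        return self.beta + self.alpha

    def ci95_s0(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se_beta, self.beta + 1.96 * self.se_beta)

    def ci95_s1(self) -> tuple[float, float]:
        p = self.prevalence_s1
        return (p - 1.96 * self.se_prevalence_s1, p + 1.96 * self.se_prevalence_s1)


@dataclass
class WaldResult:
    """Normal-reference Wald test of a linear contrast."""

    difference: float
    se_diff: float
    statistic: float
    p_value: float
    method: str


def _wald(difference: float, se_diff: float, method: str) -> WaldResult:
    difference = float(difference)
    # numerical tie-break: contrasts identical to round-off are exact ties
    tied = abs(difference) < 1e-12
    if not np.isfinite(se_diff) or se_diff <= 0:
        # degenerate contrast with zero estimated variance
        se_diff = 0.0
        stat = 0.0 if tied else np.sign(difference) * np.inf
        p = 1.0 if tied else 0.0
        return WaldResult(difference, se_diff, float(stat), p, method)
    stat = 0.0 if tied else difference / se_diff
    p = 2.0 * stats.norm.sf(abs(stat))
    return WaldResult(difference, float(se_diff), float(stat), float(min(p, 1.0)), method)


def _cluster_fit(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    model = sm.OLS(y, x)
    return model.fit(cov_type="cluster", cov_kwds={"groups": groups, "use_correction": True})


def _influence(x: np.ndarray, resid: np.ndarray, coord: int) -> np.ndarray:
    """Per-row influence of each observation on the chosen OLS coefficient:
    psi_i = [(X'X)^{-1} x_i e_i]_coord, so that betahat - beta ~= sum psi_i."""
    xtx_inv = np.linalg.inv(x.T @ x)
    return (x @ xtx_inv)[:, coord] * resid


def estimate_single_list(data: LongDataset, se_flavor: str = "robust") -> PrevalenceEstimate:
    """Fit the single-list difference-in-means regression.

    ``beta`` equals mean(Y | T=1) - mean(Y | T=0) exactly; the default
    standard error is heteroskedasticity-robust (HC1) because the treated
    arm adds a Bernoulli term to the count and so has a different variance.
    """
    df = data.df
    lists = df["list"].unique()
    if len(lists) != 1:
        raise ValueError(f"expected a single list, got {sorted(lists)}")
    if df["T"].nunique() < 2:
        raise DegenerateDesignError("both treated and control observations are required")
    y = df["Y"].to_numpy(dtype=float)
    t = df["T"].to_numpy(dtype=float)
    x = sm.add_constant(t)
    fit = sm.OLS(y, x).fit(cov_type=_COV_TYPES.get(se_flavor, "HC1"))
    beta, lam = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    psi = _influence(x, fit.resid, 1)
    infl = pd.Series(psi, index=df["respondent_id"].to_numpy()).groupby(level=0).sum()
    return PrevalenceEstimate(
        beta=beta,
        lam=lam,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        n_obs=len(df),
        scope=f"list {lists[0]}",
        se_flavor=ROBUST if se_flavor in ("robust", ROBUST) else se_flavor,
        arm_means=(float(y[t == 1].mean()), float(y[t == 0].mean())),
        influence=infl,
    )


def estimate_pooled(data: LongDataset) -> PrevalenceEstimate:
    """Fit the pooled double-list regression with a list-A fixed effect and
    respondent-clustered standard errors."""
    df = data.df
    if df["list"].nunique() < 2:
        raise ValueError("pooled estimation needs observations from both lists")
    y = df["Y"].to_numpy(dtype=float)
    x = sm.add_constant(
        np.column_stack([df["T"].to_numpy(dtype=float), df["list_A_flag"].to_numpy(dtype=float)])
    )
    groups = df["respondent_id"].to_numpy()
    fit = _cluster_fit(y, x, groups)
    beta, lam = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    psi = _influence(x, fit.resid, 1)
    infl = pd.Series(psi, index=groups).groupby(level=0).sum()
    t = df["T"].to_numpy()
    return PrevalenceEstimate(
        beta=beta,
        lam=lam,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        n_obs=len(df),
        scope="pooled",
        se_flavor=CLUSTER,
        clustered=True,
        arm_means=(float(y[t == 1].mean()), float(y[t == 0].mean())),
        influence=infl,
    )


def estimate_subgroup(
    data: LongDataset, subgroup: str, pooled: bool = False, se_flavor: str = "robust"
) -> SubgroupEstimate:
    """Fit the interacted model ``Y ~ T * S`` (plus list flag if pooled).

    In the single-list case the fit is saturated, so ``beta`` equals the
    S=0 difference in arm means and ``beta + alpha`` the S=1 difference.
    """
    df = data.df
    if subgroup not in df.columns:
        raise KeyError(f"unknown subgroup column {subgroup!r}")
    s = df[subgroup].to_numpy(dtype=float)
    if set(np.unique(s)) - {0.0, 1.0}:
        raise ValueError(f"subgroup {subgroup!r} must be binary 0/1")
    t = df["T"].to_numpy(dtype=float)
    cells = pd.crosstab(t, s)
    if cells.shape != (2, 2) or (cells.values == 0).any():
        empty = [(int(ti), int(si)) for ti in (0, 1) for si in (0, 1)
                 if cells.reindex(index=[ti], columns=[si]).fillna(0).iloc[0, 0] == 0]
        raise DegenerateDesignError(f"empty T x {subgroup} cells: {empty}")
    cols = [t, s, t * s]
    if pooled:
        cols.append(df["list_A_flag"].to_numpy(dtype=float))
    x = sm.add_constant(np.column_stack(cols))
    y = df["Y"].to_numpy(dtype=float)
    if pooled:
        fit = _cluster_fit(y, x, df["respondent_id"].to_numpy())
    else:
        fit = sm.OLS(y, x).fit(cov_type=_COV_TYPES.get(se_flavor, "HC1"))
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    contrast[3] = 1.0
    s1 = fit.t_test(contrast)
    return SubgroupEstimate(
        beta=float(fit.params[1]),
        gamma=float(fit.params[2]),
        alpha=float(fit.params[3]),
        se_beta=float(fit.bse[1]),
        se_prevalence_s1=float(np.asarray(s1.sd).ravel()[0]),
        n_obs=len(df),
        scope="pooled" if pooled else f"list {df['list'].iloc[0]}",
        subgroup=subgroup,
    )


def wald_equal_lists(
    data: LongDataset, method: str = "stacked-clustered", subgroup: str | None = None
) -> WaldResult:
    """Internal-consistency test of equal prevalences from the two lists.

    The default stacks both lists with list-specific intercepts and
    treatment effects and clusters at the respondent level, so the
    covariance between the two betas (the same people serve in opposite
    roles) is accounted for. ``method="independent"`` treats the two
    single-list fits as independent. With ``subgroup`` given, the stacked
    model is fully interacted with the binary covariate and the contrast is
    the S=1 prevalence difference between lists.
    """
    df = data.df
    if df["list"].nunique() < 2:
        raise ValueError("internal-consistency test needs both lists")
    if method == "independent":
        if subgroup is None:
            est_a = estimate_single_list(LongDataset(df[df["list"] == "A"].copy()))
            est_b = estimate_single_list(LongDataset(df[df["list"] == "B"].copy()))
            diff = est_b.beta - est_a.beta
            se = float(np.hypot(est_a.se, est_b.se))
        else:
            sub_a = estimate_subgroup(LongDataset(df[df["list"] == "A"].copy()), subgroup)
            sub_b = estimate_subgroup(LongDataset(df[df["list"] == "B"].copy()), subgroup)
            diff = sub_b.prevalence_s1 - sub_a.prevalence_s1
            se = float(np.hypot(sub_a.se_prevalence_s1, sub_b.se_prevalence_s1))
        return _wald(diff, se, "independent")
    a_flag = df["list_A_flag"].to_numpy(dtype=float)
    b_flag = 1.0 - a_flag
    t = df["T"].to_numpy(dtype=float)
    if subgroup is None:
        x = np.column_stack([a_flag, b_flag, t * a_flag, t * b_flag])
        contrast = np.array([0.0, 0.0, -1.0, 1.0])    # beta_B - beta_A
    else:
        s = df[subgroup].to_numpy(dtype=float)
        x = np.column_stack(
            [a_flag, b_flag, s * a_flag, s * b_flag, t * a_flag, t * b_flag,
             t * s * a_flag, t * s * b_flag]
        )
        # (beta_B + alpha_B) - (beta_A + alpha_A)
        contrast = np.array([0.0, 0.0, 0.0, 0.0, -1.0, 1.0, -1.0, 1.0])
    fit = _cluster_fit(df["Y"].to_numpy(dtype=float), x, df["respondent_id"].to_numpy())
    test = fit.t_test(contrast)
    diff = float(np.asarray(test.effect).ravel()[0])
    se = float(np.asarray(test.sd).ravel()[0])
    return _wald(diff, se, "stacked-clustered")


def wald_vs_direct(
    est: PrevalenceEstimate,
    data: SurveyDataset | None = None,
    *,
    direct_mean: float | None = None,
    n_direct: int | None = None,
    method: str = "independent",
) -> WaldResult:
    """Test the list-experiment prevalence against the direct-question rate.

    The difference ``mean(direct) - beta`` measures over-reporting (positive)
    or under-reporting (negative) in the direct question. The default
    variance treats the two estimates as independent,
    ``se^2 = se_beta^2 + p(1-p)/n``; ``method="stacked"`` uses the
    respondent-level influence covariance, since the same people answer
    both instruments.
    """
    if data is not None:
        direct = data.df["direct_report"].to_numpy(dtype=float)
        direct_mean = float(direct.mean())
        n_direct = len(direct)
    if direct_mean is None or n_direct is None:
        raise ValueError("supply either a SurveyDataset or direct_mean and n_direct")
    if not -0.2 <= est.beta <= 1.2:
        import logging

        logging.getLogger(__name__).warning(
            "prevalence estimate %.3f is far outside [0, 1]; interpret with care", est.beta
        )
    diff = direct_mean - est.beta
    if method == "stacked":
        if data is None or est.influence is None:
            raise ValueError("stacked method needs the survey data and estimator influence")
        wide = data.df.set_index("respondent_id")
        ids = est.influence.index
        psi_beta = est.influence.to_numpy()
        d = wide.loc[ids, "direct_report"].to_numpy(dtype=float)
        psi_d = (d - direct_mean) / len(d)
        se = float(np.sqrt(np.sum((psi_d - psi_beta) ** 2)))
        return _wald(diff, se, "stacked")
    var_direct = direct_mean * (1.0 - direct_mean) / n_direct
    se = float(np.sqrt(est.se**2 + var_direct))
    return _wald(diff, se, "independent")
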