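"""Assumption checks for the list experiment.

Identification of the prevalence as a difference in mean counts rests on
three assumptions:

(i)  randomisation balance — treated and control respondents are comparable;
(ii) no design effect — adding the sensitive item does not change answers
     to the non-sensitive items, which implies two families of stochastic-
     dominance inequalities between the treated and control count CDFs:

         F0(y) >= F1(y)          for y = 0..J
         F1(y) >= F0(y - 1)      for y = 1..J+1

     where Fg is the CDF of the count in arm g (control counts live on
     0..J, treated on 0..J+1);
(iii) no ceiling/floor pressure — few control respondents agree with all
     (ceiling) or none (floor) of the non-sensitive items, since such
     respondents would lose answer privacy when treated.

Each inequality in (ii) is checked with a one-sided z statistic on the
difference of the two empirical CDF values, using unpooled binomial
variances, and the family is summarised by a Bonferroni-corrected minimum
p-value over the 2(J+1) inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import LongDataset, SurveyDataset

FLOOR_THRESHOLD = 0.05
CEILING_THRESHOLD = 0.10


@dataclass
class BalanceRow:
    covariate: str
    mean_group1: float
    mean_group2: float
    difference: float
    p_value: float


@dataclass
class DesignEffectResult:
    """Per-inequality one-sided p-values and the Bonferroni summary."""

    inequality: pd.DataFrame      # columns: family, y, cdf_control, cdf_treated, z, p
    n_tested: int                 # Bonferroni multiplicity m = 2(J+1)
    min_p: float
    bonferroni_p: float           # min(1, m * min_p)


@dataclass
class DiagnosticsReport:
    balance: list[BalanceRow]
    balance_joint_p: float | None
    design_effect: dict[str, DesignEffectResult]
    floor_prop: dict[str, float]
    ceiling_prop: dict[str, float]
    flags: list[str] = field(default_factory=list)


def balance_test(data: SurveyDataset, covariates: list[str] | None = None):
    """Randomisation balance between groups 1 and 2.

    Per covariate: a two-sample mean-difference z test. Jointly: the F test
    of all covariates in a linear regression of the group indicator on them.
    Constant covariates are skipped with a warning flag.
    """
    covariates = covariates if covariates is not None else data.covariates
    if not covariates:
        raise ValueError("at least one covariate is required")
    df = data.df
    g1 = df["group"] == 1
    rows: list[BalanceRow] = []
    usable: list[str] = []
    flags: list[str] = []
    for cov in covariates:
        x = pd.to_numeric(df[cov], errors="coerce").to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            flags.append(f"covariate {cov!r} is constant; skipped in balance test")
            continue
        usable.append(cov)
        a, b = x[g1.to_numpy()], x[~g1.to_numpy()]
        diff = float(np.nanmean(a) - np.nanmean(b))
        se = float(np.sqrt(np.nanvar(a, ddof=1) / len(a) + np.nanvar(b, ddof=1) / len(b)))
        z = 0.0 if se == 0 else diff / se
        p = 1.0 if diff == 0 else float(2 * stats.norm.sf(abs(z)))
        rows.append(BalanceRow(cov, float(np.nanmean(a)), float(np.nanmean(b)), diff, p))
    joint_p = None
    if usable:
        y = g1.astype(float).to_numpy()
        x = sm.add_constant(df[usable].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        joint_p = float(fit.f_pvalue)
    return rows, joint_p, flags


def _ecdf(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    return np.array([(values <= y).mean() for y in support])


def design_effect_test(data: LongDataset, j: int = 3) -> DesignEffectResult:
    """One-sided z tests of the no-design-effect CDF inequalities on one list.

    A small p indicates the inequality is *violated* in the sample beyond
    binomial noise. The top inequality of the second family (y = J+1) is
    vacuous — both CDFs are 1 — and reported with p = 1. Bonferroni
    multiplicity is 2(J+1), counting every inequality in both families.
    """
    df = data.df
    if df["list"].nunique() != 1:
        raise ValueError("design-effect test runs on a single list at a time")
    y0 = df.loc[df["T"] == 0, "Y"].to_numpy(dtype=float)
    y1 = df.loc[df["T"] == 1, "Y"].to_numpy(dtype=float)
    if len(y0) < 2 or len(y1) < 2:
        raise ValueError("each arm needs at least 2 observations")
    n0, n1 = len(y0), len(y1)
    support0 = np.arange(0, j + 1)
    support1 = np.arange(0, j + 2)
    f0 = _ecdf(y0, support0)
    f1 = _ecdf(y1, support1)

    def one_sided(violation: float, p_a: float, n_a: int, p_b: float, n_b: int) -> tuple[float, float]:
        # violation = estimated amount by which the inequality fails (>0 bad)
        var = p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b
        if var == 0:
            return (np.inf if violation > 0 else -np.inf, 0.0 if violation > 0 else 1.0)
        z = violation / np.sqrt(var)
        return float(z), float(stats.norm.sf(z))

    records = []
    # family 1: F0(y) >= F1(y), y = 0..J; violated when F1(y) > F0(y)
    for y in range(j + 1):
        z, p = one_sided(f1[y] - f0[y], f0[y], n0, f1[y], n1)
        records.append(("F0>=F1", y, f0[y], f1[y], z, p))
    # family 2: F1(y) >= F0(y-1), y = 1..J+1; violated when F0(y-1) > F1(y)
    for y in range(1, j + 2):
        if y == j + 1:      # both CDFs are exactly 1: vacuous
            records.append(("F1>=F0(y-1)", y, 1.0, 1.0, 0.0, 1.0))
            continue
        z, p = one_sided(f0[y - 1] - f1[y], f0[y - 1], n0, f1[y], n1)
        records.append(("F1>=F0(y-1)", y, f0[y - 1], f1[y], z, p))
    table = pd.DataFrame(
        records, columns=["family", "y", "cdf_control", "cdf_treated", "z", "p"]
    )
    m = 2 * (j + 1)
    min_p = float(table["p"].min())
    return DesignEffectResult(table, m, min_p, float(min(1.0, m * min_p)))


def ceiling_floor(
    data: LongDataset,
    j: int = 3,
    floor_threshold: float = FLOOR_THRESHOLD,
    ceiling_threshold: float = CEILING_THRESHOLD,
) -> tuple[float, float, list[str]]:
    """Control-arm floor (Y=0) and ceiling (Y=J) proportions on one list.

    Flags are raised when the floor proportion exceeds ``floor_threshold``
    (default 5%) or the ceiling proportion exceeds ``ceiling_threshold``
    (default 10%).
    """
    df = data.df
    control = df.loc[df["T"] == 0, "Y"].to_numpy(dtype=float)
    if len(control) == 0:
        raise ValueError("control arm is empty")
    floor_prop = float((control == 0).mean())
    ceiling_prop = float((control == j).mean())
    flags = []
    list_id = df["list"].iloc[0]
    if floor_prop > floor_threshold:
        flags.append(
            f"floor effect risk on list {list_id}: Pr(Y=0|control)={floor_prop:.3f} "
            f"> {floor_threshold:.2f}"
        )
    if ceiling_prop > ceiling_threshold:
        flags.append(
            f"ceiling effect risk on list {list_id}: Pr(Y={j}|control)={ceiling_prop:.3f} "
            f"> {ceiling_threshold:.2f}"
        )
    return floor_prop, ceiling_prop, flags


def run_diagnostics(
    survey: SurveyDataset,
    long: LongDataset,
    covariates: list[str] | None = None,
    j: int = 3,
) -> DiagnosticsReport:
    """Full assumption report: balance, design-effect tests and floor/ceiling
    proportions for both lists."""
    covs = covariates if covariates is not None else survey.covariates
    if covs:
        balance, joint_p, flags = balance_test(survey, covs)
    else:
        balance, joint_p, flags = [], None, []
    design_effect: dict[str, DesignEffectResult] = {}
    floor_prop: dict[str, float] = {}
    ceiling_prop: dict[str, float] = {}
    for list_id in ("A", "B"):
        sub = long.restrict(list_id)
        design_effect[list_id] = design_effect_test(sub, j=j)
        fl, ce, fc_flags = ceiling_floor(sub, j=j)
        floor_prop[list_id] = fl
        ceiling_prop[list_id] = ce
        flags.extend(fc_flags)
        if design_effect[list_id].bonferroni_p < 0.05:
            flags.append(
                f"design-effect inequalities rejected on list {list_id} "
                f"(Bonferroni p={design_effect[list_id].bonferroni_p:.2g})"
            )
    return DiagnosticsReport(balance, joint_p, design_effect, floor_prop, ceiling_prop, flags)
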