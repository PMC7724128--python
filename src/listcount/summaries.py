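"""Desk calculations on published summary statistics.

Every estimator in :mod:`listcount.estimation` reduces, for balanced
designs, to simple arithmetic on arm means and standard errors. These
helpers perform exactly that arithmetic, so results reported only as table
entries (arm means, prevalences, SEs, direct-report rates) can be checked
or extended without the respondent-level data.
"""

from __future__ import annotations

import numpy as np

from .estimation import WaldResult, _wald


def prevalence_from_arm_means(treated_mean: float, control_mean: float) -> float:
    """Difference-in-means prevalence: the single-binary-regressor OLS slope."""
    return treated_mean - control_mean


def misreport_gap(direct_mean: float, beta: float) -> float:
    """Absolute over-/under-reporting of the direct question relative to the
    list-experiment prevalence."""
    return abs(direct_mean - beta)


def pooled_prevalence_balanced(beta_a: float, beta_b: float) -> float:
    """Pooled double-list prevalence under the balanced-design identity:
    with equal group sizes the pooled OLS slope is the mean of the two
    single-list slopes."""
    return 0.5 * (beta_a + beta_b)


def wald_vs_direct_summary(
    beta: float, se_beta: float, direct_mean: float, n_direct: int
) -> WaldResult:
    """Wald test of list prevalence against the direct-question proportion,
    treating the two as independent: se^2 = se_beta^2 + p(1-p)/n."""
    if n_direct <= 0:
        raise ValueError("n_direct must be positive")
    se = float(np.sqrt(se_beta**2 + direct_mean * (1.0 - direct_mean) / n_direct))
    return _wald(direct_mean - beta, se, "independent")


def wald_equal_summary(beta_a: float, se_a: float, beta_b: float, se_b: float) -> WaldResult:
    """Wald test of equal per-list prevalences from summary estimates,
    independence variance (no respondent-level covariance available)."""
    return _wald(beta_b - beta_a, float(np.hypot(se_a, se_b)), "independent")
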