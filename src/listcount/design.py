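"""Survey-design tools: double-list efficiency and minimum sample size.

The direct question estimates prevalence with a bias B but small variance
p(1-p)/N; the single-list experiment is (under its assumptions) unbiased
but noisy, with variance approximately C/(N-1) where

    C = pi*(1 - pi*) + 4 Var[Y_i(0)]

and Var[Y_i(0)] is the variance of the control-arm item count. Equating the
two mean-squared errors in x = N - 1 and y = B gives the quadratic

    y^2 x^2 + ((2 pi* - 1) y - 4 Var[Y_i(0)]) x - C = 0

whose positive root is the break-even x; the minimum sample size for the
list experiment to beat the direct question in MSE is
N_min = round(x) + 1 (nearest integer, no intermediate rounding). The
direct-question variance term uses p = pi* - B in this convention,
regardless of the direction of misreporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import LongDataset
from .estimation import PrevalenceEstimate

logger = logging.getLogger(__name__)


class NoFiniteSolutionError(ValueError):
    """With zero bias the direct question wins at every sample size."""


@dataclass(frozen=True)
class SampleSizeProblem:
    """Inputs of the bias-variance break-even computation."""

    pi_star: float                 # assumed true prevalence (list estimate)
    var_y0: float                  # Var of control-arm item count
    direct_mean: float | None = None   # self-declared prevalence E(p_i)
    bias: float | None = None          # B = |E(p_i) - pi*|; derived if absent

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_star < 1.0:
            raise ValueError(f"pi_star must lie in (0, 1), got {self.pi_star}")
        if self.var_y0 < 0:
            raise ValueError(f"var_y0 must be nonnegative, got {self.var_y0}")
        if self.bias is None:
            if self.direct_mean is None:
                raise ValueError("supply bias or direct_mean")
            object.__setattr__(self, "bias", abs(self.direct_mean - self.pi_star))
        elif self.direct_mean is not None:
            expected = abs(self.direct_mean - self.pi_star)
            if not np.isclose(self.bias, expected, atol=5e-4):
                raise ValueError(
                    f"bias {self.bias} inconsistent with |direct - pi*| = {expected:.4f}"
                )


@dataclass(frozen=True)
class SampleSizeResult:
    quad_a: float
    quad_b: float
    quad_c: float
    C: float
    root_x: float          # break-even N - 1
    n_min: int


def nmin_solve(problem: SampleSizeProblem) -> SampleSizeResult:
    """Solve the break-even quadratic in closed form.

    Coefficients are formed at full precision from (pi*, Var[Y(0)], B); the
    negative root is discarded and N_min is the nearest integer to
    root + 1. With 3-decimal published inputs the result can differ by
    about one respondent from a computation on unrounded values.
    """
    y = float(problem.bias)
    if y == 0.0:
        raise NoFiniteSolutionError(
            "bias is zero: the direct question has lower MSE at every sample size"
        )
    pi = problem.pi_star
    var0 = problem.var_y0
    c_const = pi * (1.0 - pi) + 4.0 * var0
    a = y * y
    b = (2.0 * pi - 1.0) * y - 4.0 * var0
    c = -c_const
    disc = b * b - 4.0 * a * c
    root = (-b + np.sqrt(disc)) / (2.0 * a)
    if root <= 0:
        raise NoFiniteSolutionError(f"no positive root (root={root:.3f})")
    return SampleSizeResult(a, b, c, c_const, float(root), int(round(root + 1.0)))


def se_reduction(se_double: float, se_single: float) -> float:
    """Relative change in SE from pooling the two lists:
    (SE_double - SE_single) / SE_single, negative when pooling helps.
    Multiply by 100 for percent display."""
    if se_single <= 0:
        raise ValueError(f"se_single must be positive, got {se_single}")
    return (se_double - se_single) / se_single


def bias_from_estimates(
    list_estimate: PrevalenceEstimate,
    direct_mean: float,
    control_data: LongDataset | None = None,
    var_y0: float | None = None,
) -> SampleSizeProblem:
    """Build a sample-size problem from a fitted list estimate.

    The true prevalence is taken to be the list-experiment estimate; the
    bias is its gap to the direct-question rate; Var[Y(0)] comes from the
    control arm of the same list (or is supplied directly).
    """
    pi = list_estimate.beta
    if not 0.0 <= pi <= 1.0:
        logger.warning("list estimate %.3f outside [0, 1]; clamping for the design problem", pi)
        pi = float(np.clip(pi, 1e-6, 1.0 - 1e-6))
    if var_y0 is None:
        if control_data is None:
            raise ValueError("supply control_data or var_y0")
        y0 = control_data.df.loc[control_data.df["T"] == 0, "Y"].to_numpy(dtype=float)
        var_y0 = float(np.var(y0, ddof=1))
    return SampleSizeProblem(pi_star=pi, var_y0=var_y0, direct_mean=direct_mean)


def mse_crossover_bruteforce(problem: SampleSizeProblem, n_max: int = 2_000_000) -> int:
    """Brute-force break-even sample size by scanning N.

    Compares MSE_direct(N) = B^2 + p(1-p)/N with p = pi* - B against
    MSE_list(N) = C/(N-1) and returns the smallest integer N >= 2 at which
    the list experiment's MSE is no larger. Independent of the quadratic
    solution; used as a cross-check.
    """
    y = float(problem.bias)
    if y == 0.0:
        raise NoFiniteSolutionError("bias is zero")
    pi = problem.pi_star
    c_const = pi * (1.0 - pi) + 4.0 * problem.var_y0
    p = pi - y
    n = np.arange(2, n_max + 1, dtype=float)
    mse_direct = y * y + p * (1.0 - p) / n
    mse_list = c_const / (n - 1.0)
    ok = mse_list <= mse_direct
    if not ok.any():
        raise NoFiniteSolutionError(f"no crossover below N={n_max}")
    return int(n[np.argmax(ok)])
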