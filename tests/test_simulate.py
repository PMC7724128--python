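"""Generator contract: arrival-parity assignment, closed-form moments,
reproducibility, and the controllable assumption violations."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from listcount import (
    BehaviorModel,
    ListDesign,
    MisreportModel,
    SimulationConfig,
    ViolationConfig,
    assign_groups,
    burkina_config,
    senegal_config,
    simulate_survey,
    to_long,
)


class TestAssignGroups:
    def test_alternates_starting_with_group_one(self):
        assert assign_groups(4).tolist() == [1, 2, 1, 2]
        assert assign_groups(1).tolist() == [1]

    def test_even_cohort_splits_in_half(self):
        groups = assign_groups(1706)
        assert (groups == 1).sum() == 853
        assert (groups == 2).sum() == 853

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            assign_groups(0)

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=50, derandomize=True)
    def test_parity_rule(self, n):
        groups = assign_groups(n)
        k = np.arange(1, n + 1)
        assert np.array_equal(groups, np.where(k % 2 == 1, 1, 2))


def _degenerate_config(n=50, pi=1.0):
    designs = (ListDesign("A", (0.0, 0.0, 0.0)), ListDesign("B", (0.0, 0.0, 0.0)))
    return SimulationConfig(
        n=n, designs=designs, behavior=BehaviorModel(pi=pi),
        misreport=MisreportModel("under_report", 0.0), seed=7,
    )


def test_degenerate_probabilities_pin_all_counts():
    survey = simulate_survey(_degenerate_config()).df
    treated_a = survey["group"] == 1
    assert (survey.loc[treated_a, "y_listA"] == 1).all()
    assert (survey.loc[~treated_a, "y_listA"] == 0).all()
    assert (survey.loc[~treated_a, "y_listB"] == 1).all()
    assert (survey.loc[treated_a, "y_listB"] == 0).all()
    assert (survey["direct_report"] == 1).all()


def test_same_seed_reproduces_identical_dataset():
    a = simulate_survey(burkina_config(seed=3)).df
    b = simulate_survey(burkina_config(seed=3)).df
    assert a.equals(b)
    c = simulate_survey(burkina_config(seed=4)).df
    assert not a.equals(c)


def test_burkina_closed_form_moments(burkina_cohort, burkina_long):
    """E[direct] = pi(1-q) = 0.054 and treated-minus-control difference = pi,
    each within a 3-standard-error Monte-Carlo band at n=1706."""
    df = burkina_cohort.df
    direct_mean = df["direct_report"].mean()
    se_direct = np.sqrt(0.054 * (1 - 0.054) / len(df))
    assert abs(direct_mean - 0.054) < 3 * se_direct

    long_df = burkina_long.df
    for list_id in ("A", "B"):
        sub = long_df[long_df["list"] == list_id]
        diff = sub.loc[sub["T"] == 1, "Y"].mean() - sub.loc[sub["T"] == 0, "Y"].mean()
        # Var(diff) ~ (2 Var(S) + pi(1-pi)) / (n/2); generous band
        assert abs(diff - 0.24) < 3 * 0.05


def test_senegal_closed_form_direct_mean(senegal_cohort):
    """Over-reporting model: E[direct] = pi + q(1-pi) = 0.968."""
    direct_mean = senegal_cohort.df["direct_report"].mean()
    se = np.sqrt(0.968 * 0.032 / 495)
    assert abs(direct_mean - 0.968) < 3 * se


def test_no_violation_difference_is_prevalence_at_large_n():
    config = replace(burkina_config(seed=11), n=100_000)
    long = to_long(simulate_survey(config))
    df = long.df[long.df["list"] == "A"]
    diff = df.loc[df["T"] == 1, "Y"].mean() - df.loc[df["T"] == 0, "Y"].mean()
    se = np.sqrt((2 * 0.55 + 0.24 * 0.76) / 50_000)
    assert abs(diff - 0.24) < 3 * se


def test_control_count_marginal_is_poisson_binomial():
    """With independent items the control count follows the Poisson-binomial
    law of the item profile; checked against exhaustive enumeration."""
    probs = (0.9, 0.5, 0.1)
    config = SimulationConfig(
        n=100_000, behavior=BehaviorModel(pi=0.5), seed=5,
        designs=(ListDesign("A", probs), ListDesign("B", probs)),
    )
    survey = simulate_survey(config).df
    control_a = survey.loc[survey["group"] == 2, "y_listA"].to_numpy()

    pmf = np.zeros(4)
    for pattern in itertools.product([0, 1], repeat=3):
        weight = np.prod([p if x else 1 - p for p, x in zip(probs, pattern)])
        pmf[sum(pattern)] += weight
    for k in range(4):
        freq = (control_a == k).mean()
        se = np.sqrt(pmf[k] * (1 - pmf[k]) / len(control_a))
        assert abs(freq - pmf[k]) < 4 * se


def test_ceiling_liar_mode_deflates_treated_mean():
    """With trait holders hiding at the ceiling, the treated-minus-control
    difference drops below pi; expectation via enumeration over the 2^3
    agreement patterns: E[diff] = pi - pi * Pr(all items agreed)."""
    probs = (0.9, 0.9, 0.9)
    pi = 0.3
    expected_diff = pi - pi * (0.9 ** 3)
    config = SimulationConfig(
        n=100_000, behavior=BehaviorModel(pi=pi), seed=9,
        designs=(ListDesign("A", probs), ListDesign("B", probs)),
        violations=ViolationConfig(liar_mode="deflate_at_ceiling"),
    )
    survey = simulate_survey(config).df
    treated = survey["group"] == 1
    diff = survey.loc[treated, "y_listA"].mean() - survey.loc[~treated, "y_listA"].mean()
    assert diff < pi
    assert abs(diff - expected_diff) < 0.02


def test_design_effect_shift_moves_treated_mean():
    config = SimulationConfig(
        n=100_000, behavior=BehaviorModel(pi=0.2), seed=13,
        violations=ViolationConfig(design_effect_shift=-0.1),
    )
    survey = simulate_survey(config).df
    treated = survey["group"] == 1
    diff = survey.loc[treated, "y_listA"].mean() - survey.loc[~treated, "y_listA"].mean()
    # three items each deflated by 0.1 => difference = pi - 0.3
    assert abs(diff - (0.2 - 0.3)) < 0.02


def test_shift_clamping_logs_warning(caplog):
    config = SimulationConfig(
        n=100, behavior=BehaviorModel(pi=0.5), seed=1,
        violations=ViolationConfig(design_effect_shift=0.5),
    )
    with caplog.at_level("WARNING"):
        simulate_survey(config)
    assert any("clamping" in rec.message for rec in caplog.records)


def test_subgroup_effect_shifts_local_prevalence():
    from listcount import with_subgroup

    config = with_subgroup(replace(burkina_config(seed=21), n=60_000), "exposed", prob=0.5, shift=0.2)
    survey = simulate_survey(config)
    long = to_long(survey)
    df = long.df[long.df["list"] == "A"]
    for level, target in ((0, 0.24), (1, 0.44)):
        sub = df[df["exposed"] == level]
        diff = sub.loc[sub["T"] == 1, "Y"].mean() - sub.loc[sub["T"] == 0, "Y"].mean()
        assert abs(diff - target) < 0.05


def test_guideline_compliance_flag():
    assert ListDesign("A", (0.9, 0.5, 0.1)).guideline_compliant
    assert not ListDesign("A", (0.7, 0.5, 0.3)).guideline_compliant


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        BehaviorModel(pi=1.2)
    with pytest.raises(ValueError):
        MisreportModel("sideways", 0.1)
    with pytest.raises(ValueError):
        SimulationConfig(n=3, behavior=BehaviorModel(pi=0.5))
    with pytest.raises(ValueError):
        ListDesign("A", (0.5, 1.3))
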