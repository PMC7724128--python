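import numpy as np
import pandas as pd
import pytest

from listcount import SurveyDataset, burkina_config, senegal_config, simulate_survey, to_long


@pytest.fixture
def tiny_survey() -> SurveyDataset:
    """Four respondents, hand-written counts, no covariates."""
    df = pd.DataFrame(
        {
            "respondent_id": [1, 2, 3, 4],
            "group": [1, 2, 1, 2],
            "y_listA": [3, 2, 4, 1],
            "y_listB": [2, 3, 1, 4],
            "treated_list": ["A", "B", "A", "B"],
            "direct_report": [1, 0, 1, 1],
        }
    )
    return SurveyDataset(df)


@pytest.fixture(scope="session")
def burkina_cohort():
    """One simulated Burkina-style cohort (n=1706), shared across tests."""
    return simulate_survey(burkina_config(seed=20260928))


@pytest.fixture(scope="session")
def burkina_long(burkina_cohort):
    return to_long(burkina_cohort)


@pytest.fixture(scope="session")
def senegal_cohort():
    return simulate_survey(senegal_config(seed=20260928))


def make_long(y0: list[int], y1: list[int], list_id: str = "A") -> "pd.DataFrame":
    """Single-list long table from explicit control and treated counts."""
    n0, n1 = len(y0), len(y1)
    return pd.DataFrame(
        {
            "respondent_id": np.arange(n0 + n1),
            "list": list_id,
            "Y": list(y0) + list(y1),
            "T": [0] * n0 + [1] * n1,
            "list_A_flag": int(list_id == "A"),
        }
    )
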