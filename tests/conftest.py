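import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (83 rows, three concerts) plus ground truth."""
    from latentconn.synthetic_data import simulate_study
    return simulate_study(seed=20210721)


@pytest.fixture(scope="session")
def study_table(study):
    return study[0]


@pytest.fixture()
def tiny_df():
    """Minimal 3-row frame satisfying the required schema."""
    rows = []
    for i, cond in enumerate(["voted", "voted", "not_voted"]):
        rows.append({
            "participant_id": f"P{i}", "concert": 1, "condition": cond,
            "age_years": 30 + i, "gender": ["woman", "man", "not_reported"][i],
            "empathic_concern": 3.0,
            "covid_loneliness": 2, "covid_lack_companionship": 3,
            "covid_isolation": 2, "covid_anxiety": 4,
            "covid_worry_self": 1, "covid_worry_others": 5,
            "conn_artist": 3, "conn_audience": 2,
            "ios_artist": 5, "ios_audience": np.nan,
        })
    return pd.DataFrame(rows)
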