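import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import longimpute as li

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> li.SimulationConfig:
    return li.SimulationConfig(n_subjects=200)


@pytest.fixture(scope="session")
def complete_panel(small_config) -> pd.DataFrame:
    return li.generate_complete(small_config, seed=11)


@pytest.fixture(scope="session")
def amputed_panel(small_config, complete_panel) -> pd.DataFrame:
    return li.ampute_mar(complete_panel, small_config, seed=11)


def make_panel(bmi_rows, dbp_rows=None, age1=None, sex=None) -> pd.DataFrame:
    """Build a 6-wave panel from per-subject value lists (NaN = missing)."""
    bmi_rows = [list(r) for r in bmi_rows]
    n = len(bmi_rows)
    if dbp_rows is None:
        dbp_rows = [[70.0] * 6 for _ in range(n)]
    if age1 is None:
        age1 = [40.0 + i for i in range(n)]
    if sex is None:
        sex = [i % 2 for i in range(n)]
    rows = []
    for i in range(n):
        for w in range(1, 7):
            rows.append({
                "subject_id": i + 1, "wave": w, "time": float(w),
                "age": age1[i] + 3.0 * (w - 1), "sex": float(sex[i]),
                "bmi": bmi_rows[i][w - 1], "dbp": dbp_rows[i][w - 1]})
    return pd.DataFrame(rows)
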