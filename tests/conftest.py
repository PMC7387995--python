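import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import scolioscreen as sc
from scolioscreen.variables import TABLE1_COUNTS

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def expand_counts(variable: str) -> pd.DataFrame:
    """Individual-level records for one variable from the published counts."""
    from scolioscreen.variables import VARIABLES

    levels = VARIABLES[variable].levels
    rows = []
    for i, level in enumerate(levels):
        for j, n in enumerate(TABLE1_COUNTS[variable][i]):
            rows.extend({variable: level, "ais": j} for _ in range(n))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One synthetic cohort at the study's size (n=1779), fixed seed."""
    return sc.generate_cohort(sc.default_spec(seed=11))


@pytest.fixture(scope="session")
def gender_table() -> sc.ContingencyTable:
    return sc.table1_contingency("gender")
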