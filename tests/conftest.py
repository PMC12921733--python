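import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from bchicea import (
    LifeTable,
    bundled_defaults,
    bundled_life_table,
    default_settings,
)

hyp_settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def sentio():
    return bundled_defaults("sentio")


@pytest.fixture(scope="session")
def osia():
    return bundled_defaults("osia")


@pytest.fixture(scope="session")
def settings():
    return default_settings()


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture(scope="session")
def zero_mortality_table():
    """Nobody dies before the terminal age (well beyond a 15-year run at 40)."""
    rows = []
    for sex in ("female", "male"):
        q = np.zeros(101)
        q[-1] = 1.0
        rows.append(pd.DataFrame({"age": np.arange(101), "sex": sex, "q_annual": q}))
    return LifeTable(pd.concat(rows, ignore_index=True))
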