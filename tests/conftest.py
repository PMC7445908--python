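import numpy as np
import pytest

from apcie import RateTable, simulate, study_config, subsample_periods


def make_table(deaths, population, age_start=20, first_period=1990, step=5):
    """Small Lexis table with 5-year age groups starting at ``age_start``."""
    deaths = np.atleast_2d(np.asarray(deaths, dtype=float))
    A, P = deaths.shape
    pop = np.broadcast_to(np.asarray(population, dtype=float), (A, P)).copy()
    ages = tuple((age_start + 5 * u, age_start + 5 * u + 4) for u in range(A))
    periods = tuple(first_period + step * j for j in range(P))
    return RateTable(ages, periods, deaths, pop)


@pytest.fixture(scope="session")
def study_sim():
    """Study-like synthetic table (13 age groups x 26 annual years) plus its truth."""
    return simulate(study_config(seed=42))


@pytest.fixture(scope="session")
def study_table_modeled(study_sim):
    """The study-like table subsampled to the six modelled years 1990...2015."""
    table, _ = study_sim
    return subsample_periods(table, 1990, 5)
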