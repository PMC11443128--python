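import numpy as np
import pandas as pd
import pytest

from surgrisk import CohortSpec, simulate_registry
from surgrisk.registry_io import AgeBand, AgeBandSchema


@pytest.fixture(scope="session")
def default_schema():
    return AgeBandSchema.default()


@pytest.fixture(scope="session")
def two_band_schema():
    return AgeBandSchema((AgeBand("0-4", 0, 5), AgeBand("5+", 5, None)))


@pytest.fixture(scope="session")
def small_registry():
    """A small but complete synthetic registry (both sexes, 5 years)."""
    spec = CohortSpec(cohort_size=20_000, seed=11)
    return spec, simulate_registry(spec)


def make_rate_table(schema, lam, mu, sex="F", period="p", event_definition="first"):
    """RateTable directly from hazard arrays (person-years set to 1)."""
    from surgrisk.rates import RateTable

    df = pd.DataFrame(
        {
            "period": period,
            "sex": sex,
            "band": schema.labels,
            "event_definition": event_definition,
            "person_years": 1.0,
            "incidence_rate": np.asarray(lam, dtype=float),
            "mortality_rate": np.asarray(mu, dtype=float),
        }
    )
    return RateTable(df, schema)


@pytest.fixture(scope="session")
def rate_table_factory():
    return make_rate_table
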