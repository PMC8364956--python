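import numpy as np
import pytest

from yieldens import (
    GenerativeTruth,
    PanelSchema,
    generate_panel,
    preprocess_train_test,
    year_forward_split,
)


@pytest.fixture(scope="session")
def small_schema():
    return PanelSchema(n_states=2, counties_per_state=4, years=(2000, 2011))


@pytest.fixture(scope="session")
def small_truth(small_schema):
    return GenerativeTruth.default(small_schema, seed=0)


@pytest.fixture(scope="session")
def small_panel(small_schema, small_truth):
    return generate_panel(small_schema, small_truth, seed=1)


@pytest.fixture(scope="session")
def processed_split(small_panel):
    """(train, test, fitted) for test year 2011 with default preprocessing."""
    train_raw, test_raw = year_forward_split(small_panel, 2011)
    return preprocess_train_test(train_raw, test_raw)


@pytest.fixture(scope="session")
def noise_free_truth(small_schema):
    """Truth with zero noise and zero weather/soil effects: yield is exactly
    the per-county trend line."""
    n = small_schema.n_counties
    return GenerativeTruth(
        intercepts=np.linspace(100.0, 160.0, n),
        slopes=np.full(n, 2.0),
        weather_coefs=np.zeros(5),
        soil_coefs=np.zeros(10),
        soil_quad=0.0,
        noise_sd=0.0,
        schema=small_schema,
    )
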