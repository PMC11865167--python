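import pandas as pd
import pytest

from eqvalue import (
    DEFAULT_TRUTH,
    NORWAY_COEFFICIENTS,
    FitOptions,
    simulate_study,
)


@pytest.fixture(scope="session")
def norway():
    return NORWAY_COEFFICIENTS


@pytest.fixture(scope="session")
def small_study():
    """A 150-respondent simulated study under the standard synthetic truth."""
    return simulate_study(DEFAULT_TRUTH, n_respondents=150, seed=42)


@pytest.fixture(scope="session")
def fast_options():
    """Reduced quadrature / single start for cheap estimation tests."""
    return FitOptions(n_starts=1, n_quad=9)


@pytest.fixture()
def toy_ctto():
    """Hand-sized cTTO table with interior, floor (-1) and ceiling (1) rows."""
    return pd.DataFrame(
        {
            "respondent_id": [0, 0, 0, 1, 1, 2, 2, 3, 3, 4, 4],
            "block": 0,
            "state_code": [
                "21111", "33333", "55555",
                "21111", "55555",
                "33333", "44444",
                "21111", "33333",
                "55555", "44444",
            ],
            "value": [0.95, 0.30, -1.0, 1.0, -0.55, 0.10, -1.0, 0.80, 0.45, -0.90, -0.25],
            "flagged": False,
        }
    )
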