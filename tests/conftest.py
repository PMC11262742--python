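import datetime as dt

import pandas as pd
import pytest

from claimscreen import SimulationConfig, simulate_dataset, validate_claims
from claimscreen.simulate import BEHAVIOURS


@pytest.fixture
def tiny_claims() -> pd.DataFrame:
    """Hand-built four-centre claims table spanning three weeks."""
    rows = [
        ("A", "private", "2021-04-08", 115, 2),
        ("A", "private", "2021-04-09", 98, 3),
        ("A", "private", "2021-04-15", 210, 4),
        ("B", "pharmacy", "2021-04-08", 64, 1),
        ("B", "pharmacy", "2021-04-16", 70, 2),
        ("C", "practice", "2021-04-10", 5, 0),
        ("C", "practice", "2021-04-22", 3, 1),
        ("D", "private", "2021-04-08", 3620, 70),
    ]
    df = pd.DataFrame(rows, columns=["centre_id", "category", "date", "n_tests", "n_positive"])
    return validate_claims(df)


def small_sim_config(**overrides) -> SimulationConfig:
    """Sixty-centre, 15-week honest configuration for fast end-to-end tests."""
    base = dict(
        seed=123,
        n_centres={"pharmacy": 10, "practice": 20, "private": 30},
        window_start=dt.date(2021, 4, 8),
        window_end=dt.date(2021, 7, 21),
        fraud_prevalence={b: 0.0 for b in BEHAVIOURS},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_honest_dataset():
    cfg = small_sim_config()
    claims, truth = simulate_dataset(cfg)
    return cfg, claims, truth
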