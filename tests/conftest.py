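import numpy as np
import pandas as pd
import pytest

from vaxlens import CovidStatsPanel, SimulationConfig
from vaxlens.lagreg import STAT_VARIABLES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A compact synthetic world for fast end-to-end tests."""
    return SimulationConfig(
        n_days=120,
        seed=5,
        tweets_per_day=300,
        events=((30, 8, 6.0), (75, 10, 7.0)),
    )


def toy_panel(n_days: int = 60, seed: int = 0, start: str = "2020-06-09") -> CovidStatsPanel:
    """A small hand-scaled panel (values O(1..100)) with valid invariants."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    dates = pd.date_range(start, periods=n_days, freq="D")
    new_cases = 10 + 5 * np.sin(2 * np.pi * t / 23) + rng.random(n_days)
    new_deaths = 2 + np.cos(2 * np.pi * t / 17) + rng.random(n_days)
    new_vacc = np.where(t > 20, t - 20 + rng.random(n_days), 0.0)
    rep = 1 + 0.2 * np.sin(2 * np.pi * t / 31) + 0.05 * rng.standard_normal(n_days)
    frame = pd.DataFrame(
        {
            "new_cases": new_cases,
            "new_deaths": new_deaths,
            "new_vaccinations": new_vacc,
            "total_cases": np.cumsum(new_cases),
            "total_deaths": np.cumsum(new_deaths),
            "total_vaccinations": np.cumsum(new_vacc),
            "people_vaccinated": np.cumsum(new_vacc * np.clip(1 - t / n_days, 0.1, 1)),
            "reproduction_rate": rep,
        },
        index=dates,
    )
    assert list(frame.columns) == list(STAT_VARIABLES)
    return CovidStatsPanel(frame)


@pytest.fixture
def panel60():
    return toy_panel()
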