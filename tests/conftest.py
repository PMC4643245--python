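import numpy as np
import pandas as pd
import pytest

from climcox.climate import DailyClimate
from climcox.cox import CohortIntervals
from climcox.lagweights import WeibullWindow
from climcox.synthetic import (
    ClimateSimConfig,
    CohortSimConfig,
    TrueHazardModel,
    simulate_climate,
    simulate_cohort,
    simulate_survival,
)


@pytest.fixture(scope="session")
def toy_climate():
    """Deterministic 400-day climate series."""
    rng = np.random.default_rng(42)
    n = 400
    d = np.arange(n)
    mint = 6 + 6 * np.sin(2 * np.pi * d / 365.25) + rng.normal(0, 2, n)
    dtr = np.abs(5 + 2 * np.sin(2 * np.pi * d / 365.25) + rng.normal(0, 1.5, n))
    return DailyClimate(mint=mint, dtr=dtr)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort with known short/long windows and modest
    effects; shared by several modules' tests."""
    T = 30
    n_days = T + 500
    climate = simulate_climate(ClimateSimConfig(n_days=n_days, seed=7))
    roster = simulate_cohort(
        CohortSimConfig(entry_schedule=[(T, 120), (T + 150, 80)], seed=8), n_days
    )
    truth = TrueHazardModel(
        baseline_daily_hazard=1.2e-3,
        log_hazard_ratios={"MinT": -0.2, "DTR": 0.3},
        mint_window=WeibullWindow(shape=1.2, scale=2.0, max_lag=T),
        dtr_window=WeibullWindow(shape=1.8, scale=18.0, max_lag=T),
    )
    events = simulate_survival(climate, roster, truth, max_follow_up=n_days, seed=9)
    return {"climate": climate, "roster": roster, "truth": truth, "events": events, "T": T}


def make_intervals(df: pd.DataFrame, terms, cluster_col="cl") -> CohortIntervals:
    """Build CohortIntervals straight from a row-level data frame."""
    return CohortIntervals(
        ids=df["id"].to_numpy(),
        start=df["start"].to_numpy(float),
        stop=df["stop"].to_numpy(float),
        event=df["event"].to_numpy(),
        X=df[list(terms)].to_numpy(float),
        terms=tuple(terms),
        cluster=df[cluster_col].to_numpy() if cluster_col in df else df["id"].to_numpy(),
    )


@pytest.fixture(scope="session")
def toy_cox_frame():
    """40 individuals x <=30 daily rows with two covariates; heavy ties."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        x1, x2 = rng.normal(), float(rng.binomial(1, 0.5))
        lin = 0.7 * x1 - 0.5 * x2
        for d in range(1, 31):
            p = 1 - np.exp(-0.05 * np.exp(lin))
            ev = rng.uniform() < p
            rows.append((i, d - 1.0, float(d), int(ev), x1, x2, f"a{i % 4}"))
            if ev:
                break
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x1", "x2", "cl"])
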