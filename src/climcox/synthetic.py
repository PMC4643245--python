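"""Synthetic climate, cohort and mortality generators with known truth.

Every downstream stage (weighting, Cox fitting, window search, model
selection) is validated against cohorts produced here, where the lagged
hazard structure is known exactly.

Daily mortality follows a complementary-log-log discrete hazard,
``p(d) = 1 - exp(-h0 * exp(eta(d)))``, so the discrete-time simulation is
the exact daily-increment version of a proportional-hazards process and
Cox fits on the simulated data are consistent for the generating
log-hazard ratios.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import DailyClimate
from .errors import BurnInError, ConfigurationError
from .lagweights import WeibullWindow, weighted_values

DAYS_PER_YEAR = 365.25

#: hazard-model terms understood by the generator (a subset of the Cox
#: engine's term vocabulary)
TRUE_MODEL_TERMS = (
    "DTR",
    "MinT",
    "DTR:MinT",
    "AgeStart",
    "AgeStart:age",
    "DTR:age",
    "MinT:age",
    "Brood",
    "Brood:DTR",
    "Brood:age",
)


# ---------------------------------------------------------------------------
# climate

@dataclass
class ClimateSimConfig:
    """Seasonal-plus-AR(1) daily climate generator settings.

    ``noise_sd_*`` are the stationary (marginal) standard deviations of the
    AR(1) noise; innovations use sd*sqrt(1-ar^2) so the lag-1
    autocorrelation of the de-seasonalized residuals equals
    ``ar_coefficient``.
    """

    n_days: int
    mean_mint: float = 6.0
    seasonal_amplitude_mint: float = 6.5
    mean_dtr: float = 7.0
    seasonal_amplitude_dtr: float = 2.5
    ar_coefficient: float = 0.6
    noise_sd_mint: float = 3.0
    noise_sd_dtr: float = 2.0
    mint_dtr_noise_correlation: float = 0.0
    phase_day: float = 105.0  # MinT peaks ~mid-July for a Jan-1 start
    start_date: _dt.date = field(default_factory=lambda: _dt.date(2008, 1, 1))
    seed: int = 0

    def validate(self) -> None:
        if int(self.n_days) != self.n_days or self.n_days < 1:
            raise ConfigurationError(f"n_days must be an integer >= 1, got {self.n_days}")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ConfigurationError(
                f"ar_coefficient must lie in [0, 1), got {self.ar_coefficient}"
            )
        for name in ("noise_sd_mint", "noise_sd_dtr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (-1.0 < self.mint_dtr_noise_correlation < 1.0):
            raise ConfigurationError(
                "mint_dtr_noise_correlation must lie in (-1, 1), "
                f"got {self.mint_dtr_noise_correlation}"
            )


def _seasonal(n_days: int, mean: float, amplitude: float, phase: float) -> np.ndarray:
    d = np.arange(n_days, dtype=float)
    return mean + amplitude * np.sin(2.0 * np.pi * (d - phase) / DAYS_PER_YEAR)


def simulate_climate(config: ClimateSimConfig) -> DailyClimate:
    """Simulate a daily MinT/DTR series.

    MinT(d) = mean + amplitude*sin(2*pi*(d - phase)/365.25) + AR(1) noise;
    DTR likewise but kept non-negative by redrawing the day's innovation
    (truncation by resampling, not clipping, so no point mass at 0).
    """
    config.validate()
    n = int(config.n_days)
    rho = config.ar_coefficient
    ss = np.random.SeedSequence(config.seed)
    rng_mint, rng_dtr = [np.random.default_rng(s) for s in ss.spawn(2)]

    season_mint = _seasonal(n, config.mean_mint, config.seasonal_amplitude_mint, config.phase_day)
    season_dtr = _seasonal(n, config.mean_dtr, config.seasonal_amplitude_dtr, config.phase_day)

    innov_sd_mint = config.noise_sd_mint * np.sqrt(1.0 - rho**2)
    innov_sd_dtr = config.noise_sd_dtr * np.sqrt(1.0 - rho**2)
    r = config.mint_dtr_noise_correlation

    # MinT noise: plain Gaussian AR(1), vectorizable
    eps_m = rng_mint.normal(0.0, 1.0, size=n)
    noise_m = np.empty(n)
    noise_m[0] = config.noise_sd_mint * eps_m[0]
    for d in range(1, n):
        noise_m[d] = rho * noise_m[d - 1] + innov_sd_mint * eps_m[d]

    # DTR noise: innovations correlated with the MinT innovations; redraw
    # (only the independent component) whenever DTR would go negative
    noise_d = np.empty(n)
    dtr = np.empty(n)
    indep_scale = np.sqrt(max(1.0 - r**2, 0.0))
    for d in range(n):
        base = rho * noise_d[d - 1] if d > 0 else 0.0
        sd = innov_sd_dtr if d > 0 else config.noise_sd_dtr
        for attempt in range(1000):
            if attempt == 0:
                eps = r * eps_m[d] + indep_scale * rng_dtr.normal()
            else:
                # redraw the whole innovation (truncation by resampling);
                # retries drop the cross-correlation for this day only
                eps = rng_dtr.normal()
            cand = base + sd * eps
            if season_dtr[d] + cand >= 0.0:
                noise_d[d] = cand
                dtr[d] = season_dtr[d] + cand
                break
        else:
            raise ConfigurationError(
                "could not draw a non-negative DTR after 1000 attempts on day "
                f"{d}; check mean_dtr / seasonal_amplitude_dtr / noise_sd_dtr"
            )

    mint = season_mint + noise_m
    return DailyClimate(mint=mint, dtr=dtr, start_date=config.start_date)


# ---------------------------------------------------------------------------
# cohort roster

@dataclass
class CohortSimConfig:
    """Staggered-entry cohort with two crossed two-level treatments.

    ``entry_schedule`` is a list of (entry day, count) pairs; foraging
    environment is determined by aviary (aviaries nest within foraging
    level), brood size and sex are assigned at the individual level.
    """

    entry_schedule: list
    age_at_entry_range: tuple = (0.25, 2.0)  # years
    n_aviaries_per_foraging: int = 4
    assign_sex: bool = True
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return int(sum(c for _, c in self.entry_schedule))

    def validate(self, n_days: int | None = None) -> None:
        if not self.entry_schedule:
            raise ConfigurationError("entry_schedule must be non-empty")
        for day, count in self.entry_schedule:
            if count < 1:
                raise ConfigurationError(f"entry count must be >= 1, got {count}")
            if day < 0:
                raise ConfigurationError(f"entry day must be >= 0, got {day}")
            if n_days is not None and day >= n_days:
                raise ConfigurationError(
                    f"entry day {day} is beyond the climate span of {n_days} days"
                )
        lo, hi = self.age_at_entry_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid age_at_entry_range {self.age_at_entry_range}")
        if self.n_aviaries_per_foraging < 1:
            raise ConfigurationError("need at least one aviary per foraging level")


def simulate_cohort(config: CohortSimConfig, n_days: int | None = None) -> pd.DataFrame:
    """Generate a roster: one row per individual with entry day, entry age
    and treatment factors.  Deterministic given ``config.seed``."""
    config.validate(n_days)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rows = []
    aviaries = {
        "easy": [f"E{i+1}" for i in range(config.n_aviaries_per_foraging)],
        "hard": [f"H{i+1}" for i in range(config.n_aviaries_per_foraging)],
    }
    idx = 0
    for day, count in config.entry_schedule:
        for _ in range(int(count)):
            foraging = ("easy", "hard")[idx % 2]
            brood = ("small", "large")[(idx // 2) % 2]
            aviary_pool = aviaries[foraging]
            aviary = aviary_pool[(idx // 4) % len(aviary_pool)]
            lo, hi = config.age_at_entry_range
            age = float(rng.uniform(lo, hi))
            sex = ("m", "f")[(idx // 4) % 2] if config.assign_sex else ""
            rows.append(
                {
                    "id": idx,
                    "entry_day": int(day),
                    "age_entry_years": age,
                    "foraging": foraging,
                    "brood": brood,
                    "aviary": aviary,
                    "sex": sex,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mortality

@dataclass
class TrueHazardModel:
    """Generating hazard: baseline daily cumulative-hazard increment plus
    log hazard ratios on weighted, centered covariates.

    ``treatment_overrides`` maps a foraging level ('easy'/'hard') to a
    partial coefficient dict merged over ``log_hazard_ratios``, enabling
    opposite-signed interactions across treatments.
    """

    baseline_daily_hazard: float
    log_hazard_ratios: dict
    mint_window: WeibullWindow
    dtr_window: WeibullWindow
    treatment_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.baseline_daily_hazard < 1.0):
            raise ConfigurationError(
                f"baseline_daily_hazard must lie in [0, 1), got {self.baseline_daily_hazard}"
            )
        all_terms = dict(self.log_hazard_ratios)
        for override in self.treatment_overrides.values():
            all_terms.update(override)
        unknown = set(all_terms) - set(TRUE_MODEL_TERMS)
        if unknown:
            raise ConfigurationError(f"unknown hazard terms: {sorted(unknown)}")

    def coefficients_for(self, foraging: str) -> dict:
        coefs = {t: 0.0 for t in TRUE_MODEL_TERMS}
        coefs.update(self.log_hazard_ratios)
        coefs.update(self.treatment_overrides.get(foraging, {}))
        return coefs


def simulate_survival(
    climate: DailyClimate,
    roster: pd.DataFrame,
    truth: TrueHazardModel,
    max_follow_up: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate death/censoring for every roster individual.

    Individuals are at risk from the day after entry; each at-risk day d
    has death probability ``1 - exp(-h0 * exp(eta(d)))``.  The first
    Bernoulli success is the death day; survivors at ``max_follow_up``
    days (or the end of the climate record) are censored.

    Returns the roster augmented with ``exit_day`` (last day at risk,
    inclusive) and ``event`` (1 = died on exit_day).
    """
    truth.validate()
    n_days = climate.n_days
    T = max(truth.mint_window.max_lag, truth.dtr_window.max_lag)
    entry = roster["entry_day"].to_numpy(int)
    if np.any(entry < T):
        bad = roster.loc[entry < T, "id"].tolist()[:5]
        raise BurnInError(
            f"individuals {bad} enter before day {T}; the lag windows need "
            f"{T} days of climate history before entry (burn-in)"
        )

    wmint = weighted_values(climate.mint, truth.mint_window)
    wdtr = weighted_values(climate.dtr, truth.dtr_window)
    # truth centers on calendar-day means over the valid span (documented
    # convention; analysis-side centering is recomputed over bird-days)
    wmint = wmint - np.nanmean(wmint)
    wdtr = wdtr - np.nanmean(wdtr)
    wmint = np.nan_to_num(wmint)
    wdtr = np.nan_to_num(wdtr)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(roster)
    H = int(max_follow_up)
    offsets = np.arange(1, H + 1)
    day_idx = entry[:, None] + offsets[None, :]  # (n, H)
    alive_mask = day_idx < n_days
    day_clip = np.minimum(day_idx, n_days - 1)

    age0 = roster["age_entry_years"].to_numpy(float)
    brood = (roster["brood"].to_numpy() == "large").astype(float)
    sqrt_age = np.sqrt(age0[:, None] + offsets[None, :] / DAYS_PER_YEAR)

    wd = wdtr[day_clip]
    wm = wmint[day_clip]

    eta = np.zeros((n, H))
    for level in ("easy", "hard"):
        sel = roster["foraging"].to_numpy() == level
        if not sel.any():
            continue
        c = truth.coefficients_for(level)
        eta_l = (
            c["DTR"] * wd[sel]
            + c["MinT"] * wm[sel]
            + c["DTR:MinT"] * wd[sel] * wm[sel]
            + c["AgeStart"] * age0[sel, None]
            + c["AgeStart:age"] * age0[sel, None] * sqrt_age[sel]
            + c["DTR:age"] * wd[sel] * sqrt_age[sel]
            + c["MinT:age"] * wm[sel] * sqrt_age[sel]
            + c["Brood"] * brood[sel, None]
            + c["Brood:DTR"] * brood[sel, None] * wd[sel]
            + c["Brood:age"] * brood[sel, None] * sqrt_age[sel]
        )
        eta[sel] = eta_l

    p = 1.0 - np.exp(-truth.baseline_daily_hazard * np.exp(eta))
    u = rng.uniform(size=(n, H))
    death = (u < p) & alive_mask

    any_death = death.any(axis=1)
    first = np.where(any_death, death.argmax(axis=1), H - 1)
    last_alive = np.clip(alive_mask.sum(axis=1) - 1, 0, None)
    exit_offset = np.where(any_death, first, last_alive)
    out = roster.copy()
    out["exit_day"] = entry + 1 + exit_offset
    out["event"] = any_death.astype(int)
    return out


# ---------------------------------------------------------------------------
# CSV export in the pipeline's cohort dialect

def cohort_to_csv(events: pd.DataFrame, climate: DailyClimate, path) -> None:
    """Write an event table in the cohort CSV dialect the pipeline reads."""
    dates = climate.dates()
    df = pd.DataFrame(
        {
            "id": events["id"],
            "entry_date": dates[events["entry_day"]].strftime("%Y-%m-%d"),
            "exit_date": dates[np.minimum(events["exit_day"], climate.n_days - 1)].strftime(
                "%Y-%m-%d"
            ),
            "event": events["event"],
            "age_entry_years": events["age_entry_years"],
            "foraging": events["foraging"],
            "brood": events["brood"],
            "aviary": events["aviary"],
            "sex": events.get("sex", ""),
        }
    )
    df.to_csv(path, index=False)


def cohort_from_csv(path, climate: DailyClimate) -> pd.DataFrame:
    """Read a cohort CSV back into the internal day-indexed event table."""
    from .errors import SchemaError

    df = pd.read_csv(path)
    required = {
        "id",
        "entry_date",
        "exit_date",
        "event",
        "age_entry_years",
        "foraging",
        "brood",
        "aviary",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cohort CSV missing columns: {sorted(missing)}")
    out = df.copy()
    out["entry_day"] = [climate.day_index(d) for d in df["entry_date"]]
    out["exit_day"] = [climate.day_index(d) for d in df["exit_date"]]
    if "sex" not in out.columns:
        out["sex"] = ""
    return out
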