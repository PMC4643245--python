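"""Three-parameter Weibull lag-weight windows and weighted climate covariates.

A window assigns a normalized weight to each integer lag 1..T before a
focal day; collapsing the lagged daily series through those weights yields
a single time-dependent covariate per day.  Lag 1 is the day preceding the
focal day (same-day climate is never used).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .climate import DailyClimate
from .errors import BurnInError, DegenerateWindowError, WindowParameterError

#: default window length in days; long enough for multi-month lags
DEFAULT_MAX_LAG = 120


@dataclass(frozen=True)
class WeibullWindow:
    """Weibull(shape, scale, location) lag-weight window over lags 1..max_lag.

    Weights are the three-parameter Weibull density evaluated at integer
    lags and renormalized to sum to one over the window.
    """

    shape: float
    scale: float
    location: float = 0.0
    max_lag: int = DEFAULT_MAX_LAG

    def __post_init__(self):
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise WindowParameterError(f"shape must be positive, got {self.shape}")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise WindowParameterError(f"scale must be positive, got {self.scale}")
        if not (self.location >= 0 and np.isfinite(self.location)):
            raise WindowParameterError(f"location must be >= 0, got {self.location}")
        if int(self.max_lag) != self.max_lag or self.max_lag < 1:
            raise WindowParameterError(f"max_lag must be an integer >= 1, got {self.max_lag}")

    @property
    def params(self) -> tuple:
        return (self.shape, self.scale, self.location)


def uniform_window(max_lag: int = DEFAULT_MAX_LAG) -> WeibullWindow:
    """A near-flat window (exponential with huge scale), used as a null
    reference and as a neutral starting window."""
    return WeibullWindow(shape=1.0, scale=1e9, location=0.0, max_lag=max_lag)


def weibull_weight(lag, window: WeibullWindow):
    """Raw (unnormalized) weight at integer lag(s): the three-parameter
    Weibull density (k/lam)*((t-loc)/lam)^(k-1)*exp(-((t-loc)/lam)^k),
    zero at and below the location."""
    t = np.asarray(lag, dtype=float)
    if np.any(t < 1):
        raise WindowParameterError("lag must be >= 1")
    w = _stats.weibull_min.pdf(t, c=window.shape, loc=window.location, scale=window.scale)
    # density is infinite at t == location when shape < 1; the window puts
    # no mass at or before its onset
    w = np.where(t - window.location <= 0.0, 0.0, w)
    return w if w.ndim else float(w)


def normalized_weights(window: WeibullWindow) -> np.ndarray:
    """Normalized weight vector over lags 1..max_lag (sums to 1)."""
    lags = np.arange(1, window.max_lag + 1, dtype=float)
    raw = np.asarray(weibull_weight(lags, window), dtype=float)
    total = raw.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise DegenerateWindowError(
            f"window {window.params} has no mass on lags 1..{window.max_lag}"
        )
    return raw / total


def cumulative_weight(window: WeibullWindow) -> np.ndarray:
    """Cumulative normalized weight at lags 1..max_lag (non-decreasing,
    ends at 1)."""
    return np.cumsum(normalized_weights(window))


def days_to_fraction(window: WeibullWindow, q: float) -> int:
    """Smallest lag whose cumulative weight reaches fraction ``q``.

    ``q`` must lie in (0, 1]; a tiny tolerance absorbs float round-off so
    that q=1 always returns a lag <= max_lag.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must be in (0, 1], got {q}")
    cum = cumulative_weight(window)
    idx = np.searchsorted(cum, q - 1e-12)
    idx = min(idx, window.max_lag - 1)
    return int(idx + 1)


@dataclass
class WeightedSeries:
    """Weighted covariate series for one climate variable.

    ``values`` is aligned to climate day indices; days with fewer than
    ``max_lag`` days of history are NaN.  Raw (uncentered) values are kept;
    ``center_constant`` records what has been subtracted (0 if uncentered).
    """

    values: np.ndarray
    variable: str
    window: WeibullWindow
    center_constant: float = 0.0
    first_valid_day: int = 0

    @property
    def raw(self) -> np.ndarray:
        return self.values + self.center_constant

    def centered_at(self, constant: float) -> "WeightedSeries":
        return replace(
            self, values=self.raw - constant, center_constant=float(constant)
        )

    def to_csv(self, path, start_date=None) -> None:
        w = self.window
        header = (
            f"# variable: {self.variable}\n"
            f"# window: shape={w.shape} scale={w.scale} location={w.location} max_lag={w.max_lag}\n"
            f"# center_constant: {self.center_constant}\n"
        )
        days = np.arange(self.values.size)
        cols = {"day": days, "value": self.values}
        if start_date is not None:
            cols = {
                "date": pd.date_range(start_date, periods=self.values.size).strftime("%Y-%m-%d"),
                **cols,
            }
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(cols).to_csv(fh, index=False)


def weighted_values(series: np.ndarray, window: WeibullWindow) -> np.ndarray:
    """Collapse a daily series through window weights.

    value(d) = sum_{t=1..T} w(t) * x(d - t); NaN for d < T.
    """
    x = np.asarray(series, dtype=float)
    w = normalized_weights(window)
    T = window.max_lag
    if x.size < T + 1:
        raise BurnInError(
            f"series of length {x.size} cannot support a {T}-day window; "
            f"first valid day would be {T}"
        )
    conv = np.convolve(x, w)  # conv[n] = sum_k x[k] w[n-k], w index = lag-1
    out = np.full(x.size, np.nan)
    out[T:] = conv[T - 1 : x.size - 1]
    return out


def build_weighted_covariate(
    climate: DailyClimate,
    variable: str,
    window: WeibullWindow,
    center: bool = False,
    bird_day_counts: np.ndarray | None = None,
) -> WeightedSeries:
    """Build the weighted covariate for one climate variable.

    If ``center`` is set the series is mean-centered; ``bird_day_counts``
    (number of individuals at risk per calendar day) weights the mean so
    the constant is the mean over bird-days rather than calendar days.
    Downstream interval expansion recomputes centering over the exact
    bird-days entering an analysis; calendar centering here is a
    convenience for standalone exports.
    """
    x = climate.variable(variable)
    vals = weighted_values(x, window)
    T = window.max_lag
    constant = 0.0
    if center:
        valid = ~np.isnan(vals)
        if bird_day_counts is not None:
            counts = np.asarray(bird_day_counts, dtype=float)
            if counts.shape != vals.shape:
                raise BurnInError("bird_day_counts must align with the climate series")
            wts = counts[valid]
            if wts.sum() <= 0:
                raise BurnInError("bird_day_counts has no mass on valid days")
            constant = float(np.average(vals[valid], weights=wts))
        else:
            constant = float(np.mean(vals[valid]))
        vals = vals - constant
    return WeightedSeries(
        values=vals,
        variable=variable,
        window=window,
        center_constant=constant,
        first_valid_day=T,
    )
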