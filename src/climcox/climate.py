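"""Daily climate series container and CSV I/O.

A :class:`DailyClimate` holds per-calendar-day minimum temperature (MinT)
and diurnal temperature range (DTR).  Maximum temperature is derived as
``MaxT = MinT + DTR`` so the identity holds exactly on every day.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

VARIABLES = ("MinT", "DTR", "MaxT")


@dataclass
class DailyClimate:
    """Per-day MinT/DTR series indexed by integer day 0..n_days-1.

    Parameters
    ----------
    mint : ndarray of float
        Daily minimum temperature in deg C.
    dtr : ndarray of float
        Daily diurnal temperature range in deg C; must be >= 0.
    start_date : datetime.date
        Calendar date of day index 0.
    """

    mint: np.ndarray
    dtr: np.ndarray
    start_date: _dt.date = field(default_factory=lambda: _dt.date(2008, 1, 1))

    def __post_init__(self):
        self.mint = np.asarray(self.mint, dtype=float)
        self.dtr = np.asarray(self.dtr, dtype=float)
        if self.mint.shape != self.dtr.shape or self.mint.ndim != 1:
            raise SchemaError("mint and dtr must be 1-D arrays of equal length")
        if self.mint.size == 0:
            raise SchemaError("climate series must cover at least one day")
        if not np.all(np.isfinite(self.mint)) or not np.all(np.isfinite(self.dtr)):
            raise SchemaError("climate series contains non-finite values")
        if np.any(self.dtr < 0):
            raise SchemaError("DTR must be non-negative on every day")

    @property
    def maxt(self) -> np.ndarray:
        return self.mint + self.dtr

    @property
    def n_days(self) -> int:
        return self.mint.size

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def day_of_year(self) -> np.ndarray:
        return self.dates().dayofyear.to_numpy()

    def variable(self, name: str) -> np.ndarray:
        """Return the daily series for ``name`` in {MinT, DTR, MaxT}."""
        if name == "MinT":
            return self.mint
        if name == "DTR":
            return self.dtr
        if name == "MaxT":
            return self.maxt
        raise SchemaError(f"unknown climate variable {name!r}; expected one of {VARIABLES}")

    def day_index(self, date) -> int:
        """Integer day index of a calendar date (may be out of range)."""
        d = pd.Timestamp(date).date()
        return (d - self.start_date).days

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates().strftime("%Y-%m-%d"),
                "mint_c": self.mint,
                "maxt_c": self.maxt,
                "dtr_c": self.dtr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DailyClimate":
        df = pd.read_csv(path)
        required = {"date", "mint_c", "maxt_c", "dtr_c"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"climate CSV missing columns: {sorted(missing)}")
        dates = pd.to_datetime(df["date"])
        if len(dates) > 1:
            deltas = dates.diff().dropna().dt.days.unique()
            if not np.array_equal(deltas, [1]):
                raise SchemaError("climate CSV dates must be consecutive calendar days")
        mint = df["mint_c"].to_numpy(float)
        dtr = df["dtr_c"].to_numpy(float)
        if not np.allclose(df["maxt_c"].to_numpy(float), mint + dtr, atol=1e-6):
            raise SchemaError("climate CSV violates maxt_c = mint_c + dtr_c")
        return cls(mint=mint, dtr=dtr, start_date=dates.iloc[0].date())
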