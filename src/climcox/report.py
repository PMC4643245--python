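"""Effect-size reporting: percent transforms, conditional climate effects,
hazard surfaces, and the photoperiod-confound check."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import CohortIntervals, CoxFit, fit_cox, lr_test
from .errors import DataError, UnsupportedLatitudeError


def hazard_ratio_percent(hr: float) -> float:
    """Percent change in hazard implied by a hazard ratio: (hr - 1) * 100.

    A hazard ratio of 1.25 per year of age at entry, for example, means
    the hazard rate increases 25% per year.
    """
    hr = float(hr)
    if not (hr > 0 and np.isfinite(hr)):
        raise ValueError(f"hazard ratio must be positive and finite, got {hr}")
    return (hr - 1.0) * 100.0


def conditional_dtr_effect(fit: CoxFit, mint_value: float) -> float:
    """Hazard ratio per degree C of weighted DTR at a given raw weighted
    MinT value: exp(b_DTR + b_DTRxMinT * (mint_value - centering constant)).

    At the centering constant (the cohort-mean weighted MinT) this equals
    exp(b_DTR) exactly.
    """
    for needed in ("DTR", "DTR:MinT"):
        if needed not in fit.terms:
            raise DataError(f"fit lacks required term {needed!r}")
    center = fit.centering.get("MinT", 0.0)
    b_dtr = fit.coef("DTR")
    b_int = fit.coef("DTR:MinT")
    return float(np.exp(b_dtr + b_int * (mint_value - center)))


@dataclass
class HazardSurface:
    """Relative hazard over a (weighted DTR, weighted MinT) grid for a
    fixed non-climate covariate context; reference (all centered
    covariates zero) has relative hazard 1."""

    dtr_values: np.ndarray  # raw (uncentered) weighted DTR axis
    mint_values: np.ndarray
    relative_hazard: np.ndarray  # shape (len(dtr), len(mint))
    coverage_mask: np.ndarray  # True where inside 95% of observed range
    context: dict

    def to_frame(self):
        import pandas as pd

        d, m = np.meshgrid(self.dtr_values, self.mint_values, indexing="ij")
        return pd.DataFrame(
            {
                "weighted_dtr": d.ravel(),
                "weighted_mint": m.ravel(),
                "relative_hazard": self.relative_hazard.ravel(),
                "in_coverage": self.coverage_mask.ravel(),
            }
        )


def _coverage_interval(values: np.ndarray, coverage: float = 0.95) -> tuple:
    lo = np.quantile(values, (1 - coverage) / 2)
    hi = np.quantile(values, 1 - (1 - coverage) / 2)
    return float(lo), float(hi)


def hazard_surface(
    fit: CoxFit,
    dtr_values: np.ndarray,
    mint_values: np.ndarray,
    context: dict,
    observed_dtr: np.ndarray | None = None,
    observed_mint: np.ndarray | None = None,
    coverage: float = 0.95,
) -> HazardSurface:
    """Relative hazard exp(eta) on a grid of raw weighted DTR x MinT.

    ``context`` must supply a value for every non-climate covariate in the
    fit (keyed by term parent, e.g. AgeStart, age, Brood); missing entries
    raise rather than defaulting silently.  ``observed_*`` arrays (raw
    weighted bird-day values) define the coverage mask; without them the
    mask is all-True.
    """
    dtr_values = np.asarray(dtr_values, dtype=float)
    mint_values = np.asarray(mint_values, dtype=float)
    c_dtr = fit.centering.get("DTR", 0.0)
    c_mint = fit.centering.get("MinT", 0.0)
    d, m = np.meshgrid(dtr_values - c_dtr, mint_values - c_mint, indexing="ij")

    def ctx(name):
        if name not in context:
            raise DataError(f"hazard-surface context missing covariate {name!r}")
        return float(context[name])

    eta = np.zeros_like(d)
    for i, term in enumerate(fit.terms):
        b = fit.beta[i]
        if term == "DTR":
            eta += b * d
        elif term == "MinT":
            eta += b * m
        elif term == "DTR:MinT":
            eta += b * d * m
        elif term.endswith(":age"):
            parent = term.split(":")[0]
            age = ctx("age")  # sqrt-transformed current age
            base = d if parent == "DTR" else m if parent == "MinT" else ctx(parent)
            eta += b * base * age
        else:
            parts = term.split(":")
            val = 1.0
            for p in parts:
                val *= ctx(p)
            eta += b * val

    mask = np.ones_like(eta, dtype=bool)
    if observed_dtr is not None:
        lo, hi = _coverage_interval(np.asarray(observed_dtr, float), coverage)
        mask &= (dtr_values[:, None] >= lo) & (dtr_values[:, None] <= hi)
    if observed_mint is not None:
        lo, hi = _coverage_interval(np.asarray(observed_mint, float), coverage)
        mask &= (mint_values[None, :] >= lo) & (mint_values[None, :] <= hi)

    return HazardSurface(
        dtr_values=dtr_values,
        mint_values=mint_values,
        relative_hazard=np.exp(eta),
        coverage_mask=mask,
        context=dict(context),
    )


# ---------------------------------------------------------------------------
# photoperiod

_MAX_LATITUDE = 66.5


def photoperiod(day_of_year, latitude: float):
    """Civil daylength in hours from solar declination and hour angle.

    Declination uses the Spencer Fourier series; daylength is
    24/pi * arccos(-tan(lat) tan(decl)).  Valid for |latitude| < 66.5 deg
    (no polar day/night).
    """
    if not abs(latitude) < _MAX_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} outside supported range (|lat| < {_MAX_LATITUDE})"
        )
    doy = np.asarray(day_of_year, dtype=float)
    g = 2.0 * np.pi * (doy - 1.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    phi = np.deg2rad(latitude)
    cos_h = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h)
    return hours if hours.ndim else float(hours)


def add_photoperiod_check(
    data: CohortIntervals,
    best_terms,
    climate,
    latitude: float,
    ties: str = "efron",
    aicc_n: str = "events",
) -> dict:
    """Refit a best model with photoperiod added; report the LR test and
    the AICc change.  ``data.day`` must carry calendar day indices."""
    if data.day is None:
        raise DataError("interval data lacks calendar day indices")
    doy = climate.dates().dayofyear.to_numpy()
    col = photoperiod(doy[data.day], latitude)
    col = col - col.mean()
    augmented = data.with_extra_column("Photoperiod", col)
    base = fit_cox(augmented, terms=tuple(best_terms), ties=ties, aicc_n=aicc_n, robust=False)
    with_pp = fit_cox(
        augmented,
        terms=tuple(best_terms) + ("Photoperiod",),
        ties=ties,
        aicc_n=aicc_n,
        robust=False,
    )
    test = lr_test(with_pp, base)
    return {
        "x2": test.x2,
        "df": test.df,
        "p_value": test.p_value,
        "delta_aicc": float(with_pp.aicc - base.aicc),
        "photoperiod_coefficient": with_pp.coef("Photoperiod"),
        "significant_at_0.05": bool(test.p_value < 0.05),
    }
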