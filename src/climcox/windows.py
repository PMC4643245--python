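"""Maximum-likelihood estimation of Weibull lag windows.

The profile objective rebuilds the weighted covariate for candidate window
parameters, refits the Cox model and returns its AICc; a multi-start
bounded Nelder-Mead searches (shape, scale, location).  Windows for the
two climate variables are estimated sequentially (first variable searched
with the other held at a neutral flat window, then the second with the
first fixed, then one refinement pass); a joint 6-parameter search is
available behind a flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt

from .climate import DailyClimate
from .cox import CohortIntervals, expand_to_intervals, fit_cox
from .errors import ClimcoxError, ConvergenceError, DataError
from .lagweights import (
    DEFAULT_MAX_LAG,
    WeibullWindow,
    cumulative_weight,
    days_to_fraction,
    normalized_weights,
    uniform_window,
    weighted_values,
)

log = logging.getLogger(__name__)

#: objective value assigned to candidate windows whose inner fit fails
FAILED_FIT_PENALTY = 1e10

#: reference model used while searching a window: both climate main
#: effects plus their interaction, no age interactions
DEFAULT_SEARCH_TERMS = ("DTR", "MinT", "DTR:MinT")


@dataclass
class WindowSearchConfig:
    """Settings for one variable's window search."""

    variable: str
    max_lag: int = DEFAULT_MAX_LAG
    restarts: int = 8
    shape_bounds: tuple = (0.1, 8.0)
    scale_bounds: tuple = (0.5, 200.0)
    location_bounds: tuple = (0.0, None)  # None -> max_lag - 1
    search_terms: tuple = DEFAULT_SEARCH_TERMS
    seed: int = 0
    maxfev: int = 200
    fatol: float = 0.01
    xatol: float = 0.01

    def bounds(self) -> list:
        loc_hi = self.location_bounds[1]
        if loc_hi is None:
            loc_hi = self.max_lag - 1.0
        return [tuple(self.shape_bounds), tuple(self.scale_bounds), (self.location_bounds[0], loc_hi)]

    def validate(self) -> None:
        if self.restarts < 1:
            raise DataError("restarts must be >= 1")
        for (lo, hi), name in zip(self.bounds(), ("shape", "scale", "location")):
            if lo >= hi:
                raise DataError(f"empty {name} bounds ({lo}, {hi})")
        if self.shape_bounds[0] <= 0 or self.scale_bounds[0] <= 0:
            raise DataError("shape and scale bounds must be positive")
        if self.bounds()[2][1] >= self.max_lag:
            raise DataError("location bound must stay below max_lag")


@dataclass
class WindowSearchResult:
    """Best window found plus search diagnostics."""

    variable: str
    window: WeibullWindow
    aicc: float
    restarts: list  # per-restart dicts: start, final params, final AICc, n evals
    n_evaluations: int
    boundary: bool
    days_to_50: int
    days_to_80: int
    days_to_100: int

    def summary(self) -> dict:
        w = self.window
        return {
            "variable": self.variable,
            "shape": w.shape,
            "scale": w.scale,
            "location": w.location,
            "max_lag": w.max_lag,
            "AICc": self.aicc,
            "days_to_50": self.days_to_50,
            "days_to_80": self.days_to_80,
            "days_to_100": self.days_to_100,
            "boundary_solution": self.boundary,
            "n_evaluations": self.n_evaluations,
        }

    def to_json(self, path) -> None:
        rec = self.summary()
        rec["restarts"] = self.restarts
        w = self.window
        cum = cumulative_weight(w)
        rec["cumulative_weight"] = {
            "lag": list(range(1, w.max_lag + 1)),
            "weight": normalized_weights(w).tolist(),
            "cumulative": cum.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2)


class ProfileContext:
    """Pre-expanded interval data whose climate columns can be rebuilt
    cheaply for candidate windows.

    The interval rows (and therefore the Cox risk-set structure and AICc
    sample size) are fixed once at construction, so AICc values for
    different candidate windows are computed on identical event sets.
    """

    def __init__(
        self,
        climate: DailyClimate,
        roster,
        terms=DEFAULT_SEARCH_TERMS,
        windows: dict | None = None,
        burn_in: int | None = None,
        max_lag: int = DEFAULT_MAX_LAG,
        timescale: str = "study",
        aicc_n: str = "events",
        ties: str = "efron",
    ):
        self.climate = climate
        self.terms = tuple(terms)
        self.max_lag = max_lag
        self.aicc_n = aicc_n
        self.ties = ties
        self.variables = tuple(
            t for t in self.terms if t in ("DTR", "MinT", "MaxT")
        )
        self.windows = {v: uniform_window(max_lag) for v in self.variables}
        if windows:
            self.windows.update(windows)
        if burn_in is None:
            burn_in = max_lag
        from .lagweights import build_weighted_covariate

        weighted = {
            v: build_weighted_covariate(climate, v, self.windows[v])
            for v in self.variables
        }
        self.full_data: CohortIntervals = expand_to_intervals(
            weighted, roster, self.terms, burn_in=burn_in, timescale=timescale
        )
        # only rows belonging to some risk set enter the partial
        # likelihood; restricting to them makes every refit much cheaper
        # without changing any likelihood, AICc (n = events) or risk set
        rs = self.full_data.risk_structure()
        keep = np.unique(rs.risk_idx)
        self.data: CohortIntervals = self.full_data.permuted(keep)
        self.data.validate()
        self._day = self.data.day
        # bird-day counts per calendar day over the *full* analysis rows,
        # so centering constants stay means over all bird-days
        full_day = self.full_data.day
        self._day_counts = np.bincount(full_day, minlength=climate.n_days).astype(float)
        self._n_bird_days = float(full_day.size)
        self._series = {v: climate.variable(v) for v in self.variables}
        self._beta_warm = None

    def _columns_for(self, windows: dict) -> dict:
        cols = {}
        centered = {}
        for v in self.variables:
            vals = weighted_values(self._series[v], windows[v])
            const = float(np.dot(self._day_counts, np.nan_to_num(vals)) / self._n_bird_days)
            centered[v] = vals[self._day] - const
            cols[v] = centered[v]
        for t in self.terms:
            if ":" in t and t not in cols:
                a, b = t.split(":")
                if a in centered and b in centered:
                    cols[t] = centered[a] * centered[b]
        return cols

    def fit_with_windows(self, windows: dict, extra_df: int = 0, warm: bool = False,
                         robust: bool = False):
        """Refit the reference Cox model with the given windows per
        variable; returns the CoxFit (AICc includes ``extra_df`` window
        parameters)."""
        data = self.data.with_columns(self._columns_for(windows))
        beta0 = self._beta_warm if warm else None
        fit = fit_cox(
            data,
            ties=self.ties,
            aicc_n=self.aicc_n,
            robust=robust,
            check_rank=False,
            beta_init=beta0,
            extra_df=extra_df,
        )
        if warm:
            self._beta_warm = fit.beta.copy()
        return fit


def profile_objective(
    params,
    context: ProfileContext,
    variable: str,
    extra_df: int = 3,
    warm: bool = False,
) -> float:
    """AICc of the reference model with ``variable`` weighted by a
    Weibull(shape, scale, location) window; failed inner fits are
    penalized, never raised."""
    shape, scale, location = params
    try:
        cand = WeibullWindow(
            shape=float(shape),
            scale=float(scale),
            location=float(location),
            max_lag=context.max_lag,
        )
        windows = dict(context.windows)
        windows[variable] = cand
        fit = context.fit_with_windows(windows, extra_df=extra_df, warm=warm)
        return float(fit.aicc)
    except (ClimcoxError, np.linalg.LinAlgError) as exc:
        log.warning("window %s rejected: %s", tuple(params), exc)
        return FAILED_FIT_PENALTY


def _start_points(
    config: WindowSearchConfig,
    rng: np.random.Generator,
    incumbent: tuple | None = None,
) -> list:
    """Deterministic coarse grid spanning short..long windows, then
    seeded jitter for the remaining restarts.  An incumbent solution (from
    an earlier sequential pass) is always included first."""
    coarse = [
        (1.0, 1.5, 0.0),
        (1.5, 4.0, 0.0),
        (2.0, 10.0, 0.0),
        (1.5, 30.0, 0.0),
        (1.5, 60.0, 0.0),
        (2.5, 90.0, 0.0),
        (1.0, 15.0, 5.0),
        (3.0, 45.0, 10.0),
    ]
    (slo, shi), (sclo, schi), (llo, lhi) = config.bounds()

    def clip(pt):
        k, lam, loc = pt
        return (
            float(np.clip(k, slo, shi)),
            float(np.clip(lam, sclo, schi)),
            float(np.clip(loc, llo, lhi)),
        )

    pts = []
    if incumbent is not None:
        pts.append(clip(incumbent))
    pts += [clip(p) for p in coarse[: max(config.restarts - len(pts), 1)]]
    while len(pts) < config.restarts:
        k = np.exp(rng.uniform(np.log(slo), np.log(shi)))
        lam = np.exp(rng.uniform(np.log(sclo), np.log(schi)))
        loc = rng.uniform(llo, min(lhi, 30.0))
        pts.append(clip((k, lam, loc)))
    return pts


def optimize_window(
    config: WindowSearchConfig,
    context: ProfileContext,
    extra_df: int = 3,
    incumbent: tuple | None = None,
) -> WindowSearchResult:
    """Multi-start bounded Nelder-Mead over (shape, scale, location).

    Returns the best window over *all* evaluated candidates (so the
    reported AICc can never exceed that of any point the search visited).
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    bounds = config.bounds()
    best = {"params": None, "aicc": np.inf}
    n_eval = 0
    restart_log = []
    failures = []

    def objective(params):
        nonlocal n_eval
        n_eval += 1
        val = profile_objective(params, context, config.variable, extra_df=extra_df, warm=True)
        if val < best["aicc"]:
            best["aicc"] = val
            best["params"] = tuple(float(v) for v in params)
        return val

    for start in _start_points(config, rng, incumbent):
        context._beta_warm = None
        try:
            res = _opt.minimize(
                objective,
                x0=np.array(start),
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxfev": config.maxfev,
                    "fatol": config.fatol,
                    "xatol": config.xatol,
                },
            )
            restart_log.append(
                {
                    "start": list(start),
                    "final_params": [float(v) for v in res.x],
                    "final_AICc": float(res.fun),
                    "n_evaluations": int(res.nfev),
                }
            )
        except Exception as exc:  # noqa: BLE001 - aggregated failure report
            failures.append(f"start {start}: {exc}")
    if best["params"] is None:
        raise ConvergenceError(
            "all window-search restarts failed: " + "; ".join(failures)
        )
    shape, scale, location = best["params"]
    window = WeibullWindow(shape=shape, scale=scale, location=location, max_lag=config.max_lag)
    boundary = any(
        min(abs(v - lo), abs(v - hi)) < 1e-3
        for v, (lo, hi) in zip(best["params"], bounds)
    )
    if boundary:
        log.warning(
            "window search for %s ended on a parameter bound: %s",
            config.variable,
            best["params"],
        )
    return WindowSearchResult(
        variable=config.variable,
        window=window,
        aicc=best["aicc"],
        restarts=restart_log,
        n_evaluations=n_eval,
        boundary=boundary,
        days_to_50=days_to_fraction(window, 0.5),
        days_to_80=days_to_fraction(window, 0.8),
        days_to_100=days_to_fraction(window, 1.0),
    )


def estimate_windows(
    climate: DailyClimate,
    roster,
    variables=("MinT", "DTR"),
    max_lag: int = DEFAULT_MAX_LAG,
    restarts: int = 8,
    seed: int = 0,
    refine: bool = True,
    search_terms=DEFAULT_SEARCH_TERMS,
    burn_in: int | None = None,
    maxfev: int = 200,
    context: ProfileContext | None = None,
    joint: bool = False,
) -> dict:
    """Sequential per-variable window estimation.

    The first variable is searched with the other at a flat window, the
    second with the first's best window fixed, then (optionally) the first
    is refined once with the second fixed.  With ``joint=True`` a final
    simultaneous 6-parameter search polishes both windows at once.
    Returns ``{variable: WindowSearchResult}`` plus the shared context
    under ``"_context"``.
    """
    if context is None:
        context = ProfileContext(
            climate, roster, terms=search_terms, burn_in=burn_in, max_lag=max_lag
        )
    results = {}
    order = list(variables)
    if refine and len(variables) > 1:
        order += list(variables)  # one refinement pass per variable
    for i, var in enumerate(order):
        is_refine = var in results
        cfg = WindowSearchConfig(
            variable=var,
            max_lag=max_lag,
            restarts=max(2, restarts - 1) if is_refine else restarts,
            seed=seed + i,
            maxfev=maxfev,
        )
        res = optimize_window(
            cfg,
            context,
            incumbent=results[var].window.params if is_refine else None,
        )
        results[var] = res
        context.windows[var] = res.window
    if joint and len(variables) > 1:
        _joint_polish(context, results, variables, max_lag, maxfev)
    results["_context"] = context
    return results


def _joint_polish(context, results, variables, max_lag, maxfev) -> None:
    """Simultaneous Nelder-Mead over both variables' (shape, scale,
    location), started from the sequential solution."""
    v1, v2 = variables[:2]
    bounds = WindowSearchConfig(variable=v1, max_lag=max_lag).bounds() * 2

    def objective(params):
        try:
            windows = dict(context.windows)
            windows[v1] = WeibullWindow(*params[:3], max_lag=max_lag)
            windows[v2] = WeibullWindow(*params[3:], max_lag=max_lag)
            return float(context.fit_with_windows(windows, extra_df=6).aicc)
        except (ClimcoxError, np.linalg.LinAlgError):
            return FAILED_FIT_PENALTY

    x0 = np.array(results[v1].window.params + results[v2].window.params)
    res = _opt.minimize(
        objective,
        x0=x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxfev": 2 * maxfev, "fatol": 0.01, "xatol": 0.01},
    )
    start_val = objective(x0)
    if res.fun < start_val:
        for var, params in ((v1, res.x[:3]), (v2, res.x[3:])):
            window = WeibullWindow(*[float(p) for p in params], max_lag=max_lag)
            old = results[var]
            results[var] = WindowSearchResult(
                variable=var,
                window=window,
                aicc=float(res.fun),
                restarts=old.restarts
                + [{"start": list(x0), "final_params": [float(p) for p in res.x],
                    "final_AICc": float(res.fun), "n_evaluations": int(res.nfev),
                    "joint": True}],
                n_evaluations=old.n_evaluations + int(res.nfev),
                boundary=old.boundary,
                days_to_50=days_to_fraction(window, 0.5),
                days_to_80=days_to_fraction(window, 0.8),
                days_to_100=days_to_fraction(window, 1.0),
            )
            context.windows[var] = window


def swap_window_test(
    context: ProfileContext,
    variable: str,
    own_window: WeibullWindow,
    foreign_window: WeibullWindow,
) -> float:
    """AICc cost of weighting ``variable`` with the other variable's
    window instead of its own: positive values favor the own window."""
    own = dict(context.windows)
    own[variable] = own_window
    foreign = dict(context.windows)
    foreign[variable] = foreign_window
    aicc_own = context.fit_with_windows(own).aicc
    aicc_foreign = context.fit_with_windows(foreign).aicc
    return float(aicc_foreign - aicc_own)


def compare_windows_between_groups(
    climate: DailyClimate,
    rosters: dict,
    variable: str,
    shared_windows: dict,
    max_lag: int = DEFAULT_MAX_LAG,
    restarts: int = 4,
    seed: int = 0,
    search_terms=DEFAULT_SEARCH_TERMS,
    burn_in: int | None = None,
    maxfev: int = 120,
) -> dict:
    """Do strata need separate windows for ``variable``?

    Fits each stratum's Cox model twice: once with the shared window for
    ``variable`` and once with a window searched within the stratum.
    Total AICc values (summed logliks / events, window parameters counted)
    are compared: ``delta_aicc = AICc(separate) - AICc(shared)``, so
    positive values mean the shared window is preferred once the extra
    parameters are penalized.
    """
    from .cox import aicc as _aicc

    if len(rosters) < 2:
        raise DataError("need at least two strata to compare windows")
    contexts = {}
    for name, roster in rosters.items():
        ctx = ProfileContext(
            climate,
            roster,
            terms=search_terms,
            windows=shared_windows,
            burn_in=burn_in,
            max_lag=max_lag,
        )
        if ctx.data.n_events == 0:
            raise DataError(f"stratum {name!r} has no events")
        contexts[name] = ctx

    p_cox = len(search_terms)
    ll_shared, ll_sep, events = 0.0, 0.0, 0
    per_stratum = {}
    for i, (name, ctx) in enumerate(contexts.items()):
        fit_shared = ctx.fit_with_windows(dict(ctx.windows))
        cfg = WindowSearchConfig(
            variable=variable, max_lag=max_lag, restarts=restarts, seed=seed + i, maxfev=maxfev
        )
        res = optimize_window(cfg, ctx)
        own = dict(ctx.windows)
        own[variable] = res.window
        fit_sep = ctx.fit_with_windows(own)
        ll_shared += fit_shared.loglik
        ll_sep += fit_sep.loglik
        events += ctx.data.n_events
        per_stratum[name] = {
            "window": res.window.params,
            "loglik_shared": fit_shared.loglik,
            "loglik_separate": fit_sep.loglik,
        }
    n_strata = len(contexts)
    # shared: one 3-parameter window; separate: one per stratum
    aicc_shared = _aicc(ll_shared, n_strata * p_cox + 3, events)
    aicc_sep = _aicc(ll_sep, n_strata * p_cox + 3 * n_strata, events)
    return {
        "delta_aicc": float(aicc_sep - aicc_shared),
        "aicc_shared": float(aicc_shared),
        "aicc_separate": float(aicc_sep),
        "per_stratum": per_stratum,
    }
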