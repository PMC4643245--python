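"""Counting-process Cox partial-likelihood engine.

Risk time is partitioned into daily (start, stop] intervals with the event
at ``stop``; covariates may change every day and individuals may enter
late (left truncation).  Ties are handled with the Efron correction
(Breslow available for cross-checks).  Fitting is Newton-Raphson with
step-halving; variance is model-based (inverse information) plus a
cluster-robust sandwich over a grouping factor (aviary).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as _linalg
from scipy import stats as _scistats

from .errors import (
    ConvergenceError,
    DataError,
    MissingCovariateError,
    RankDeficiencyError,
)
from .lagweights import WeightedSeries
from .synthetic import DAYS_PER_YEAR

#: canonical term vocabulary; ':age' denotes interaction with the
#: (sqrt-transformed) current age, which itself has no main effect because
#: it is absorbed by the baseline hazard
KNOWN_TERMS = (
    "DTR",
    "MinT",
    "MaxT",
    "DTR:MinT",
    "DTR:MaxT",
    "AgeStart",
    "AgeStart:age",
    "DTR:age",
    "MinT:age",
    "MaxT:age",
    "Brood",
    "Brood:DTR",
    "Brood:age",
    "Photoperiod",
    "Sex",
)


def term_parents(term: str) -> tuple:
    """Main-effect terms an interaction requires (marginality).  Age
    interactions require only the non-age parent."""
    if ":" not in term:
        return ()
    return tuple(p for p in term.split(":") if p != "age")


@dataclass(frozen=True)
class ModelSpec:
    """A hazard-model formula: term set plus structural choices."""

    terms: tuple
    timescale: str = "study"  # 'study' (AgeStart covariate) or 'age' (delayed entry)
    cluster: str = "aviary"
    age_transform: str = "sqrt"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        unknown = [t for t in self.terms if t not in KNOWN_TERMS]
        if unknown:
            raise DataError(f"unknown model terms: {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise DataError(f"duplicate terms in spec: {self.terms}")
        if self.timescale not in ("study", "age"):
            raise DataError(f"timescale must be 'study' or 'age', got {self.timescale!r}")
        for t in self.terms:
            for parent in term_parents(t):
                if parent not in self.terms:
                    raise DataError(
                        f"term {t!r} requires its parent {parent!r} (marginality)"
                    )

    def drop(self, *terms) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t not in terms))


# ---------------------------------------------------------------------------
# interval data

@dataclass
class CohortIntervals:
    """Daily (start, stop] risk intervals with covariates.

    ``X`` columns follow ``terms``; ``day`` is the calendar day index of
    each row's stop (for rebuilding climate covariates / photoperiod).
    """

    ids: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    X: np.ndarray
    terms: tuple
    cluster: np.ndarray
    centering: dict = field(default_factory=dict)
    day: np.ndarray | None = None
    _risksets: object = field(default=None, repr=False, compare=False)
    # shared cache for quantities depending only on ids/cluster/intervals;
    # with_columns() copies share it because those arrays are unchanged
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.terms = tuple(self.terms)
        self.cluster = np.asarray(self.cluster)

    def validate(self) -> None:
        if np.any(self.start >= self.stop):
            raise DataError("every interval must satisfy start < stop")
        if not np.allclose(self.stop - self.start, 1.0):
            raise DataError("intervals must be daily: stop - start = 1 for all rows")
        if not np.all(np.isfinite(self.X)):
            raise MissingCovariateError("covariate matrix contains non-finite values")
        ev_ids = self.ids[self.event]
        if len(ev_ids) != len(np.unique(ev_ids)):
            raise DataError("an individual has more than one event row")

    @property
    def n_rows(self) -> int:
        return self.start.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_individuals(self) -> int:
        if "n_individuals" not in self._cache:
            self._cache["n_individuals"] = int(pd.unique(self.ids).size)
        return self._cache["n_individuals"]

    @property
    def n_clusters(self) -> int:
        if "n_clusters" not in self._cache:
            self._cache["n_clusters"] = int(pd.unique(self.cluster).size)
        return self._cache["n_clusters"]

    def column(self, term: str) -> np.ndarray:
        return self.X[:, self.terms.index(term)]

    def with_columns(self, updates: dict) -> "CohortIntervals":
        """Copy with some covariate columns replaced; the cached risk-set
        structure (which depends only on start/stop/event) is shared."""
        X = self.X.copy()
        for term, values in updates.items():
            X[:, self.terms.index(term)] = values
        return replace(self, X=X)

    def with_extra_column(self, term: str, values: np.ndarray) -> "CohortIntervals":
        X = np.column_stack([self.X, np.asarray(values, dtype=float)])
        return replace(self, X=X, terms=self.terms + (term,))

    def permuted(self, order: np.ndarray) -> "CohortIntervals":
        return CohortIntervals(
            ids=self.ids[order],
            start=self.start[order],
            stop=self.stop[order],
            event=self.event[order],
            X=self.X[order],
            terms=self.terms,
            cluster=self.cluster[order],
            centering=dict(self.centering),
            day=None if self.day is None else self.day[order],
        )

    def fingerprint(self) -> str:
        if "fingerprint" not in self._cache:
            h = hashlib.sha256()
            for arr in (self.start, self.stop, self.event.astype(np.int8)):
                h.update(np.ascontiguousarray(arr).tobytes())
            self._cache["fingerprint"] = h.hexdigest()[:16]
        return self._cache["fingerprint"]

    def risk_structure(self) -> "_RiskStructure":
        if self._risksets is None:
            self._risksets = _RiskStructure(self.start, self.stop, self.event)
        return self._risksets


class _RiskStructure:
    """Flattened risk sets per distinct event time.

    Risk set at event time t = rows with start < t <= stop.  For daily
    integer intervals this is exactly {rows: stop == t}, which allows an
    O(n log n) grouped construction; otherwise a generic scan is used.
    """

    def __init__(self, start, stop, event):
        ev_times = np.unique(stop[event])
        if ev_times.size == 0:
            raise DataError("no events in interval data")
        daily = np.allclose(stop - start, 1.0) and np.allclose(stop, np.round(stop))
        risk_chunks, ev_chunks, ev_masks = [], [], []
        if daily:
            order = np.argsort(stop, kind="stable")
            sorted_stop = stop[order]
            for t in ev_times:
                lo = np.searchsorted(sorted_stop, t - 0.5)
                hi = np.searchsorted(sorted_stop, t + 0.5)
                rows = order[lo:hi]
                mask = event[rows]
                risk_chunks.append(rows)
                ev_chunks.append(rows[mask])
                ev_masks.append(mask)
        else:  # generic fallback for non-daily toy data
            for t in ev_times:
                rows = np.where((start < t) & (stop >= t))[0]
                mask = event[rows] & (stop[rows] == t)
                risk_chunks.append(rows)
                ev_chunks.append(rows[mask])
                ev_masks.append(mask)
        self.d = np.array([c.size for c in ev_chunks], dtype=float)
        if np.any(self.d == 0):
            raise DataError("internal risk-set construction lost an event")
        sizes = np.array([c.size for c in risk_chunks])
        if np.any(sizes == 0):
            raise DataError("empty risk set at an event time")
        self.risk_idx = np.concatenate(risk_chunks)
        self.risk_seg = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.seg_of_risk_row = np.repeat(np.arange(len(risk_chunks)), sizes)
        ev_sizes = np.array([c.size for c in ev_chunks])
        self.ev_idx = np.concatenate(ev_chunks)
        self.ev_seg = np.concatenate([[0], np.cumsum(ev_sizes)[:-1]])
        self.max_d = int(self.d.max())
        # flag risk rows that are tied events at their own time
        self.risk_is_event = np.concatenate(ev_masks)


class _PLEngine:
    """Efron/Breslow partial likelihood, gradient, information and
    cluster-robust score sums for a fixed design matrix."""

    def __init__(self, data: CohortIntervals, cols: np.ndarray, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise DataError(f"ties must be 'efron' or 'breslow', got {ties!r}")
        self.ties = ties
        rs = data.risk_structure()
        self.rs = rs
        self.p = len(cols)
        X = data.X[:, cols] if self.p else np.empty((data.n_rows, 0))
        self.Xr = X[rs.risk_idx]
        self.Xe = X[rs.ev_idx]
        self.cluster_r = data.cluster[rs.risk_idx]
        iu = np.triu_indices(self.p)
        self.iu0, self.iu1 = iu

    def _pair_to_full(self, pairs: np.ndarray) -> np.ndarray:
        M = np.zeros((self.p, self.p))
        M[self.iu0, self.iu1] = pairs
        M[self.iu1, self.iu0] = pairs
        return M

    def stats(self, beta: np.ndarray, order: int = 2):
        """Return (loglik, gradient, information); higher orders optional."""
        rs = self.rs
        p = self.p
        eta = self.Xr @ beta if p else np.zeros(self.Xr.shape[0])
        shift = eta.max() if eta.size else 0.0
        r = np.exp(eta - shift)
        S0 = np.add.reduceat(r, rs.risk_seg)
        eta_e = self.Xe @ beta if p else np.zeros(self.Xe.shape[0])
        re = np.exp(eta_e - shift)
        s0d = np.add.reduceat(re, rs.ev_seg)
        ll = float(np.sum(eta_e - shift))
        grad = self.Xe.sum(axis=0) if p else np.zeros(0)
        info_pairs = np.zeros(self.iu0.size)
        if order >= 1 and p:
            rX = r[:, None] * self.Xr
            S1 = np.add.reduceat(rX, rs.risk_seg, axis=0)
            reX = re[:, None] * self.Xe
            s1d = np.add.reduceat(reX, rs.ev_seg, axis=0)
        if order >= 2 and p:
            rXX = rX[:, self.iu0] * self.Xr[:, self.iu1]
            S2 = np.add.reduceat(rXX, rs.risk_seg, axis=0)
            reXX = reX[:, self.iu0] * self.Xe[:, self.iu1]
            s2d = np.add.reduceat(reXX, rs.ev_seg, axis=0)
        efron = self.ties == "efron"
        for l in range(rs.max_d):
            act = rs.d > l
            f = (l / rs.d[act]) if efron else np.zeros(int(act.sum()))
            S0l = S0[act] - f * s0d[act]
            if np.any(S0l <= 0):
                raise DataError("non-positive risk-set mass (numerical underflow)")
            ll -= float(np.log(S0l).sum())
            if order >= 1 and p:
                S1l = S1[act] - f[:, None] * s1d[act]
                xbar = S1l / S0l[:, None]
                grad = grad - xbar.sum(axis=0)
            if order >= 2 and p:
                S2l = S2[act] - f[:, None] * s2d[act]
                info_pairs += (S2l / S0l[:, None] - xbar[:, self.iu0] * xbar[:, self.iu1]).sum(
                    axis=0
                )
        info = self._pair_to_full(info_pairs) if p else np.zeros((0, 0))
        if order == 0:
            return ll
        return ll, grad, info

    def cluster_score_sums(self, beta: np.ndarray) -> tuple:
        """Per-cluster sums of score residuals (for the sandwich)."""
        rs = self.rs
        p = self.p
        eta = self.Xr @ beta if p else np.zeros(self.Xr.shape[0])
        shift = eta.max() if eta.size else 0.0
        r = np.exp(eta - shift)
        S0 = np.add.reduceat(r, rs.risk_seg)
        rX = r[:, None] * self.Xr
        S1 = np.add.reduceat(rX, rs.risk_seg, axis=0)
        ev_mask = rs.risk_is_event
        re_full = np.where(ev_mask, r, 0.0)
        s0d = np.add.reduceat(re_full, rs.risk_seg)
        s1d = np.add.reduceat(re_full[:, None] * self.Xr, rs.risk_seg, axis=0)
        seg = rs.seg_of_risk_row
        d_row = rs.d[seg]
        resid = np.zeros((rs.risk_idx.size, p))
        efron = self.ties == "efron"
        for l in range(rs.max_d):
            act_row = d_row > l
            f_row = (l / d_row[act_row]) if efron else np.zeros(int(act_row.sum()))
            seg_a = seg[act_row]
            S0l_row = S0[seg_a] - f_row * s0d[seg_a]
            S1l_row = S1[seg_a] - f_row[:, None] * s1d[seg_a]
            xbar_row = S1l_row / S0l_row[:, None]
            c_il = 1.0 - f_row * ev_mask[act_row]
            dx = self.Xr[act_row] - xbar_row
            w = (
                ev_mask[act_row] / d_row[act_row]
                - c_il * r[act_row] / S0l_row
            )
            resid[act_row] += w[:, None] * dx
        clusters, codes = np.unique(self.cluster_r, return_inverse=True)
        U = np.zeros((clusters.size, p))
        np.add.at(U, codes, resid)
        return U, clusters


# ---------------------------------------------------------------------------
# public operations

def partial_loglik(beta, data: CohortIntervals, terms=None, ties: str = "efron") -> float:
    """Cox partial log likelihood at ``beta`` for the given term columns."""
    terms = tuple(terms) if terms is not None else data.terms
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != len(terms):
        raise DataError(f"beta has {beta.size} entries for {len(terms)} terms")
    if not np.all(np.isfinite(beta)):
        raise DataError("beta must be finite")
    if data.n_events == 0:
        return 0.0
    cols = np.array([data.terms.index(t) for t in terms], dtype=int)
    return _PLEngine(data, cols, ties).stats(beta, order=0)


@dataclass
class CoxFit:
    """A fitted hazard model."""

    terms: tuple
    beta: np.ndarray
    se: np.ndarray
    robust_se: np.ndarray | None
    loglik: float
    loglik_null: float
    n_events: int
    n_rows: int
    n_individuals: int
    n_clusters: int
    aicc: float
    ties: str
    converged: bool
    n_iter: int
    centering: dict = field(default_factory=dict)
    data_fingerprint: str = ""

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def n_params(self) -> int:
        return len(self.terms)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def hazard_ratio(self, term: str) -> float:
        return float(np.exp(self.coef(term)))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": self.beta,
                "hazard_ratio": self.hazard_ratios,
                "se": self.se,
                "robust_se": self.robust_se
                if self.robust_se is not None
                else np.full(len(self.terms), np.nan),
            }
        )

    def to_record(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.beta.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "se": self.se.tolist(),
            "robust_se": None if self.robust_se is None else self.robust_se.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
            "n_individuals": self.n_individuals,
            "n_clusters": self.n_clusters,
            "AICc": self.aicc,
            "ties": self.ties,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "centering": self.centering,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_record(), fh, indent=2)


def aicc(loglik: float, p: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2p + 2p(p+1)/(n - p - 1)."""
    if n <= p + 1:
        raise DataError(f"AICc correction undefined for n={n} <= p+1={p + 1}")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def _aicc_n(data: CohortIntervals, convention: str) -> int:
    if convention == "events":
        return data.n_events
    if convention == "rows":
        return data.n_rows
    if convention == "individuals":
        return data.n_individuals
    raise DataError(f"unknown AICc sample-size convention {convention!r}")


def fit_cox(
    data: CohortIntervals,
    terms=None,
    ties: str = "efron",
    aicc_n: str = "events",
    robust: bool = True,
    check_rank: bool = True,
    beta_init: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    extra_df: int = 0,
) -> CoxFit:
    """Fit by Newton-Raphson with step-halving to gradient sup-norm < tol.

    ``aicc_n`` selects the AICc small-sample size (events by default);
    ``extra_df`` adds non-Cox parameters (e.g. window parameters estimated
    upstream) to the AICc penalty.
    """
    terms = tuple(terms) if terms is not None else data.terms
    p = len(terms)
    cols = np.array([data.terms.index(t) for t in terms], dtype=int)
    engine = _PLEngine(data, cols, ties)

    if p and check_rank:
        _check_rank(engine.Xr, terms)

    trace = []
    if p == 0:
        ll = engine.stats(np.zeros(0), order=0)
        beta = np.zeros(0)
        ll_null = ll
        n_iter = 0
        converged = True
        se = np.zeros(0)
        robust_se = np.zeros(0) if robust else None
    else:
        beta = (
            np.zeros(p)
            if beta_init is None
            else np.array(beta_init, dtype=float).reshape(p)
        )
        ll, grad, info = engine.stats(beta, order=2)
        ll_null = ll if not beta.any() else engine.stats(np.zeros(p), order=0)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            trace.append((n_iter, ll, float(np.abs(grad).max())))
            if np.abs(grad).max() < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular information matrix at iteration {n_iter}", trace
                ) from exc
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                try:
                    ll_new = engine.stats(cand, order=0)
                except DataError:
                    ll_new = -np.inf
                if ll_new > ll - 1e-12:
                    break
                scale *= 0.5
            else:
                raise ConvergenceError(
                    f"step-halving failed at iteration {n_iter}", trace
                )
            beta = cand
            ll, grad, info = engine.stats(beta, order=2)
        else:
            n_iter = max_iter
            converged = bool(np.abs(grad).max() < tol)
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not reach gradient tolerance {tol} in "
                f"{max_iter} iterations (final sup-norm {np.abs(grad).max():.3g})",
                trace,
            )
        info_inv = np.linalg.inv(info)
        se = np.sqrt(np.diag(info_inv))
        robust_se = None
        if robust:
            U, _ = engine.cluster_score_sums(beta)
            meat = U.T @ U
            robust_cov = info_inv @ meat @ info_inv
            robust_se = np.sqrt(np.clip(np.diag(robust_cov), 0.0, None))

    n_for_aicc = _aicc_n(data, aicc_n)
    value = aicc(ll, p + extra_df, n_for_aicc)
    return CoxFit(
        terms=terms,
        beta=beta,
        se=se,
        robust_se=robust_se,
        loglik=ll,
        loglik_null=ll_null,
        n_events=data.n_events,
        n_rows=data.n_rows,
        n_individuals=data.n_individuals,
        n_clusters=data.n_clusters,
        aicc=value,
        ties=ties,
        converged=converged,
        n_iter=n_iter,
        centering=dict(data.centering),
        data_fingerprint=data.fingerprint(),
    )


def _check_rank(X: np.ndarray, terms) -> None:
    if X.shape[0] < X.shape[1]:
        raise RankDeficiencyError(terms)
    _, R, piv = _linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = np.where(diag <= tol)[0]
    if bad.size:
        aliased = [terms[piv[i]] for i in bad]
        raise RankDeficiencyError(aliased)


def lr_test(full: CoxFit, reduced: CoxFit):
    """Likelihood-ratio test of nested fits on the same data."""
    if not set(reduced.terms) <= set(full.terms):
        raise DataError(
            f"models are not nested: {reduced.terms} is not a subset of {full.terms}"
        )
    if full.data_fingerprint != reduced.data_fingerprint:
        raise DataError("fits come from different interval data")
    x2 = 2.0 * (full.loglik - reduced.loglik)
    df = full.n_params - reduced.n_params
    if df == 0:
        return LRTest(x2=float(x2), df=0, p_value=1.0)
    p = float(_scistats.chi2.sf(max(x2, 0.0), df))
    return LRTest(x2=float(x2), df=df, p_value=p)


@dataclass(frozen=True)
class LRTest:
    x2: float
    df: int
    p_value: float


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise DataError("akaike_weights needs at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# interval expansion

def expand_to_intervals(
    weighted: dict,
    roster: pd.DataFrame,
    terms,
    burn_in: int = 30,
    timescale: str = "study",
    climate=None,
    latitude: float | None = None,
) -> CohortIntervals:
    """Expand an event table into daily (start, stop] rows with covariates.

    ``weighted`` maps climate variable names ('DTR', 'MinT', ...) to
    :class:`WeightedSeries`.  One row is produced per individual per
    at-risk day after the ``burn_in`` exclusion; the event sits on the
    final row of a dying individual.  Weighted climate covariates are
    re-centered over the bird-days actually entering the analysis and the
    constants are recorded.
    """
    terms = tuple(terms)
    spec = ModelSpec(terms=terms, timescale=timescale)  # validates marginality

    required_cols = {"id", "entry_day", "exit_day", "event", "age_entry_years"}
    missing = required_cols - set(roster.columns)
    if missing:
        raise DataError(f"roster missing columns: {sorted(missing)}")

    entry = roster["entry_day"].to_numpy(int)
    exit_ = roster["exit_day"].to_numpy(int)
    ev = roster["event"].to_numpy(int)
    n_at_risk = exit_ - entry  # days at risk (risk starts the day after entry)
    keep = n_at_risk > burn_in
    if not keep.any():
        raise DataError("no individual survives the burn-in exclusion")

    counts = (n_at_risk[keep] - burn_in).astype(int)
    rep = np.repeat(np.arange(len(roster))[keep], counts)
    tau = np.concatenate([np.arange(burn_in + 1, n + 1) for n in n_at_risk[keep]])
    day = entry[rep] + tau
    event_rows = np.zeros(rep.size, dtype=bool)
    last_row = np.cumsum(counts) - 1
    event_rows[last_row] = ev[keep].astype(bool)

    age_entry = roster["age_entry_years"].to_numpy(float)[rep]
    age_years = age_entry + tau / DAYS_PER_YEAR
    sqrt_age = np.sqrt(age_years) if spec.age_transform == "sqrt" else age_years

    if timescale == "study":
        stop = tau.astype(float)
    else:
        stop = age_entry * DAYS_PER_YEAR + tau
    start = stop - 1.0

    # raw weighted climate values at each row's day, centered over bird-days
    climate_cols = {}
    centering = {}
    for var, series in weighted.items():
        if not isinstance(series, WeightedSeries):
            raise DataError(f"weighted[{var!r}] must be a WeightedSeries")
        raw = series.raw
        vals = raw[day] if day.max() < raw.size else None
        if vals is None or np.any(np.isnan(raw[np.minimum(day, raw.size - 1)])):
            bad_days = day[(day >= raw.size) | np.isnan(raw[np.minimum(day, raw.size - 1)])]
            raise MissingCovariateError(
                f"weighted {var} covariate missing on day(s) starting at "
                f"{int(bad_days.min())}; extend the climate record or raise burn_in"
            )
        const = float(vals.mean())
        climate_cols[var] = vals - const
        centering[var] = const

    def _factor(name, level_one):
        if name not in roster.columns:
            raise DataError(f"roster missing column {name!r} required by the model terms")
        return (roster[name].to_numpy()[rep] == level_one).astype(float)

    def _col(term):
        if term in ("DTR", "MinT", "MaxT"):
            if term not in climate_cols:
                raise MissingCovariateError(f"no weighted series supplied for {term}")
            return climate_cols[term]
        if term == "AgeStart":
            return roster["age_entry_years"].to_numpy(float)[rep]
        if term == "Brood":
            return _factor("brood", "large")
        if term == "Sex":
            return _factor("sex", "f")
        if term == "Photoperiod":
            if climate is None or latitude is None:
                raise DataError("Photoperiod term needs `climate` and `latitude`")
            from .report import photoperiod

            doy = climate.dates().dayofyear.to_numpy()
            return photoperiod(doy[day], latitude)
        if ":" in term:
            a, b = term.split(":")
            left = _col(a)
            right = sqrt_age if b == "age" else _col(b)
            return left * right
        raise DataError(f"cannot build design column for term {term!r}")

    X = (
        np.column_stack([_col(t) for t in terms])
        if terms
        else np.empty((rep.size, 0))
    )

    cluster = (
        roster["aviary"].to_numpy()[rep]
        if "aviary" in roster.columns
        else roster["id"].to_numpy()[rep]
    )
    data = CohortIntervals(
        ids=roster["id"].to_numpy()[rep],
        start=start,
        stop=stop,
        event=event_rows,
        X=X,
        terms=terms,
        cluster=cluster,
        centering=centering,
        day=day,
    )
    data.validate()
    return data


def reduce_to_risk_rows(data: CohortIntervals) -> CohortIntervals:
    """Drop rows that belong to no risk set (their stop is not an event
    time).  Such rows contribute nothing to the partial likelihood, so
    loglik, estimates and AICc (with n = events or individuals) are
    unchanged while refits get much cheaper."""
    rs = data.risk_structure()
    keep = np.unique(rs.risk_idx)
    return data.permuted(keep)


# ---------------------------------------------------------------------------
# submodel enumeration helper (used by model selection)

def marginality_closed_subsets(terms) -> list:
    """All subsets of ``terms`` respecting marginality, including the
    empty (baseline-only) model, in a deterministic order."""
    terms = tuple(terms)
    out = []
    for k in range(len(terms) + 1):
        for combo in itertools.combinations(terms, k):
            ok = all(parent in combo for t in combo for parent in term_parents(t))
            if ok:
                out.append(combo)
    return out
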