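"""All-subsets hazard-model generation and AICc ranking.

Given a global term set, every marginality-respecting subset (including
the baseline-only model) is fitted on identical interval data; models are
ranked by AICc with Akaike weights computed over all fitted models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import (
    CohortIntervals,
    ConvergenceError,
    ModelSpec,
    akaike_weights,
    fit_cox,
    marginality_closed_subsets,
)
from .errors import DataError

log = logging.getLogger(__name__)


def enumerate_submodels(global_spec: ModelSpec) -> list:
    """All subsets of the global term set respecting marginality
    (interaction => parents present), baseline-only model included."""
    subsets = marginality_closed_subsets(global_spec.terms)
    return [
        ModelSpec(
            terms=combo,
            timescale=global_spec.timescale,
            cluster=global_spec.cluster,
            age_transform=global_spec.age_transform,
        )
        for combo in subsets
    ]


@dataclass
class SelectionTable:
    """Ranked submodels: the machine twin of a published model table."""

    table: pd.DataFrame  # one row per model, sorted by AICc
    global_spec: ModelSpec
    fits: list  # CoxFit per row (aligned with table), None if failed
    data_fingerprint: str

    def __len__(self) -> int:
        return len(self.table)

    @property
    def best_fit(self):
        return self.fits[0]

    def within_delta(self, delta: float) -> "SelectionTable":
        """Rows with delta_AICc <= delta, order preserved."""
        if len(self.table) == 0:
            raise DataError("selection table is empty")
        mask = self.table["delta_aicc"].to_numpy() <= delta
        return SelectionTable(
            table=self.table.loc[mask].reset_index(drop=True),
            global_spec=self.global_spec,
            fits=[f for f, m in zip(self.fits, mask) if m],
            data_fingerprint=self.data_fingerprint,
        )

    def term_support(self, term: str, delta: float | None = None) -> dict:
        """How often and with how much weight a term appears among the
        ranked models (optionally restricted to delta_AICc <= delta)."""
        if term not in self.global_spec.terms:
            raise DataError(f"term {term!r} is not in the global model")
        sub = self if delta is None else self.within_delta(delta)
        contains = sub.table["terms"].apply(lambda ts: term in ts)
        n = len(sub.table)
        return {
            "term": term,
            "n_models": int(n),
            "n_containing": int(contains.sum()),
            "fraction": float(contains.mean()) if n else 0.0,
            "summed_weight": float(sub.table.loc[contains, "weight"].sum()),
        }

    def to_csv(self, path) -> None:
        """Export in a wide published-table layout: one column per
        candidate term holding the hazard ratio (empty if absent), then
        df, AICc, delta AICc and weight."""
        rows = []
        for _, row in self.table.iterrows():
            rec = {"model": row["rank"]}
            hr = dict(zip(row["terms"], row["hazard_ratios"]))
            for t in self.global_spec.terms:
                rec[t] = round(hr[t], 4) if t in hr else "NA"
            rec["df"] = row["df"]
            rec["AICc"] = round(row["aicc"], 2)
            rec["dAICc"] = round(row["delta_aicc"], 2)
            rec["weight"] = round(row["weight"], 3)
            rows.append(rec)
        pd.DataFrame(rows).to_csv(path, index=False)


def dredge(
    data: CohortIntervals,
    global_spec: ModelSpec,
    ties: str = "efron",
    aicc_n: str = "events",
    robust: bool = False,
    extra_df: int = 0,
) -> SelectionTable:
    """Fit every marginality-respecting submodel on the same data.

    Non-convergent submodels are recorded with NA fit statistics and
    excluded from the Akaike-weight normalization (with a warning).
    Deterministic: fitting is exact-likelihood, candidate order is fixed,
    and ties in AICc are broken by the enumeration index.
    """
    missing = set(global_spec.terms) - set(data.terms)
    if missing:
        raise DataError(
            f"interval data lacks columns for global terms: {sorted(missing)}"
        )
    specs = enumerate_submodels(global_spec)
    records, fits = [], []
    for idx, spec in enumerate(specs):
        try:
            fit = fit_cox(
                data,
                terms=spec.terms,
                ties=ties,
                aicc_n=aicc_n,
                robust=robust,
                extra_df=extra_df,
            )
        except ConvergenceError as exc:
            log.warning("submodel %s did not converge: %s", spec.terms, exc)
            records.append(
                {
                    "order": idx,
                    "terms": spec.terms,
                    "df": len(spec.terms) + extra_df,
                    "loglik": np.nan,
                    "aicc": np.nan,
                    "hazard_ratios": (),
                    "converged": False,
                }
            )
            fits.append(None)
            continue
        records.append(
            {
                "order": idx,
                "terms": spec.terms,
                "df": len(spec.terms) + extra_df,
                "loglik": fit.loglik,
                "aicc": fit.aicc,
                "hazard_ratios": tuple(fit.hazard_ratios),
                "converged": True,
            }
        )
        fits.append(fit)

    df = pd.DataFrame(records)
    ok = df["converged"]
    if not ok.any():
        raise DataError("no submodel converged")
    weights = np.full(len(df), np.nan)
    weights[ok.to_numpy()] = akaike_weights(df.loc[ok, "aicc"])
    df["weight"] = weights
    df["delta_aicc"] = df["aicc"] - df.loc[ok, "aicc"].min()

    sort_key = df["aicc"].fillna(np.inf)
    order = np.lexsort((df["order"].to_numpy(), sort_key.to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    sorted_fits = [fits[i] for i in order]
    cols = ["rank", "terms", "hazard_ratios", "df", "loglik", "aicc", "delta_aicc", "weight", "converged"]
    return SelectionTable(
        table=df[cols],
        global_spec=global_spec,
        fits=sorted_fits,
        data_fingerprint=data.fingerprint(),
    )
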