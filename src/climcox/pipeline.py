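"""End-to-end pipeline: read inputs, estimate lag windows, dredge hazard
models per foraging treatment, and emit reports with a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .climate import DailyClimate
from .cox import ModelSpec, expand_to_intervals, fit_cox
from .errors import ConfigurationError
from .lagweights import build_weighted_covariate
from .report import (
    add_photoperiod_check,
    conditional_dtr_effect,
    hazard_ratio_percent,
    hazard_surface,
)
from .selection import dredge
from .synthetic import cohort_from_csv
from .windows import estimate_windows, swap_window_test

log = logging.getLogger(__name__)

DEFAULT_GLOBAL_TERMS = (
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


@dataclass
class PipelineConfig:
    climate_csv: str
    cohort_csv: str
    output_dir: str
    global_terms: tuple = DEFAULT_GLOBAL_TERMS
    max_lag: int = 120
    burn_in: int | None = None  # None -> max_lag (identical event sets)
    restarts: int = 8
    maxfev: int = 200
    seed: int = 0
    delta_aicc: float = 4.0
    timescale: str = "study"
    latitude: float | None = 53.2  # for the photoperiod confound check
    mean_mint_reference: float = 6.0
    # explicit covariate context for hazard surfaces (no silent defaults:
    # these values are part of the run configuration)
    surface_context: dict = field(
        default_factory=lambda: {"AgeStart": 1.0, "age": float(np.sqrt(1.36)), "Brood": 0.0}
    )
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("pipeline config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("climate_csv", "cohort_csv", "output_dir"):
            if key not in raw:
                raise ConfigurationError(f"pipeline config missing required key {key!r}")
        if "global_terms" in raw:
            raw["global_terms"] = tuple(raw["global_terms"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute read -> window search -> per-treatment dredge -> reports.

    Writes all artifacts under ``config.output_dir`` and returns it.
    Pure function of (input files, config, seed): reruns produce identical
    outputs.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.climate_csv, config.cohort_csv):
        if not Path(path).exists():
            raise ConfigurationError(f"input path does not exist: {path}")

    root_log = logging.getLogger("climcox")
    file_handler = logging.FileHandler(out / "pipeline.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    file_handler.setLevel(logging.INFO)
    root_log.addHandler(file_handler)
    old_level = root_log.level
    if root_log.level > logging.INFO or root_log.level == logging.NOTSET:
        root_log.setLevel(logging.INFO)

    stage_times = {}

    def stage(name):
        stage_times[name] = time.time() - t0
        log.info("stage %s done at %.1fs", name, stage_times[name])

    try:
        return _run_pipeline_stages(config, out, stage, stage_times)
    finally:
        root_log.removeHandler(file_handler)
        file_handler.close()
        root_log.setLevel(old_level)


def _run_pipeline_stages(config, out, stage, stage_times) -> Path:

    climate = DailyClimate.from_csv(config.climate_csv)
    cohort = cohort_from_csv(config.cohort_csv, climate)
    stage("read")

    burn_in = config.burn_in if config.burn_in is not None else config.max_lag
    win = estimate_windows(
        climate,
        cohort,
        max_lag=config.max_lag,
        restarts=config.restarts,
        seed=config.seed,
        burn_in=burn_in,
        maxfev=config.maxfev,
    )
    context = win.pop("_context")
    windows = {v: r.window for v, r in win.items()}
    for var, res in win.items():
        res.to_json(out / f"window_{var}.json")
        _cumulative_csv(res, out / f"window_{var}_cumulative.csv")
    stage("window_search")

    swaps = {}
    for var in windows:
        other = next(v for v in windows if v != var)
        swaps[var] = swap_window_test(context, var, windows[var], windows[other])
    (out / "swap_test.json").write_text(json.dumps(swaps, indent=2))
    stage("swap_test")

    weighted = {
        v: build_weighted_covariate(climate, v, w) for v, w in windows.items()
    }
    global_spec = ModelSpec(terms=config.global_terms, timescale=config.timescale)
    tables = {}
    reports = {}
    for level in sorted(cohort["foraging"].unique()):
        roster = cohort[cohort["foraging"] == level].reset_index(drop=True)
        data = expand_to_intervals(
            weighted,
            roster,
            config.global_terms,
            burn_in=burn_in,
            timescale=config.timescale,
        )
        table = dredge(data, global_spec)
        shown = table.within_delta(config.delta_aicc)
        shown.to_csv(out / f"selection_{level}.csv")
        tables[level] = table
        best = table.best_fit
        best.to_json(out / f"best_fit_{level}.json")
        rep = {
            "n_events": data.n_events,
            "n_bird_days": data.n_rows,
            "best_terms": list(best.terms),
            "best_aicc": best.aicc,
            "interaction_support": table.term_support("DTR:MinT", delta=config.delta_aicc)
            if "DTR:MinT" in config.global_terms
            else None,
        }
        if "DTR" in best.terms:
            rep["dtr_hazard_ratio"] = best.hazard_ratio("DTR")
            rep["dtr_percent_per_degc"] = hazard_ratio_percent(best.hazard_ratio("DTR"))
            if "DTR:MinT" in best.terms:
                hr = conditional_dtr_effect(best, config.mean_mint_reference)
                rep["dtr_hazard_ratio_at_reference_mint"] = hr
                rep["dtr_percent_at_reference_mint"] = hazard_ratio_percent(hr)
        if config.latitude is not None:
            rep["photoperiod_check"] = add_photoperiod_check(
                data, best.terms, climate, config.latitude
            )
        if {"DTR", "MinT"} <= set(best.terms):
            surf = _surface_for(best, data, config)
            surf.to_frame().to_csv(out / f"hazard_surface_{level}.csv", index=False)
            if config.figures:
                _surface_figure(surf, out / f"hazard_surface_{level}.png", level)
        reports[level] = rep
    (out / "report.json").write_text(json.dumps(reports, indent=2))
    if config.figures:
        for var, res in win.items():
            _cumulative_figure(res, out / f"window_{var}_cumulative.png")
    stage("selection")

    manifest = {
        "climcox_version": __version__,
        "numpy_version": np.__version__,
        "inputs": {
            "climate_csv": _sha256(config.climate_csv),
            "cohort_csv": _sha256(config.cohort_csv),
        },
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        "windows": {v: list(w.params) + [w.max_lag] for v, w in windows.items()},
        # pipeline.log carries wall-clock timestamps, so it is excluded
        # from the determinism-checked output hashes
        "outputs": sorted(
            {
                p.name: _sha256(p)
                for p in out.iterdir()
                if p.is_file() and p.name != "pipeline.log"
            }.items()
        ),
        "stage_seconds": stage_times,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _surface_for(best, data, config):
    """Fig-4-style relative-hazard surface over the observed raw weighted
    climate ranges, masked to 95% data coverage."""
    obs_dtr = data.column("DTR") + data.centering["DTR"]
    obs_mint = data.column("MinT") + data.centering["MinT"]
    grid_dtr = np.linspace(obs_dtr.min(), obs_dtr.max(), 41)
    grid_mint = np.linspace(obs_mint.min(), obs_mint.max(), 7)
    return hazard_surface(
        best, grid_dtr, grid_mint, context=dict(config.surface_context),
        observed_dtr=obs_dtr, observed_mint=obs_mint,
    )


def _matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        return plt
    except ImportError:  # pragma: no cover - plotting is best-effort
        log.warning("matplotlib unavailable; skipping figures")
        return None


def _surface_figure(surf, path, title) -> None:
    plt = _matplotlib()
    if plt is None:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    for j, m in enumerate(surf.mint_values):
        line = np.where(surf.coverage_mask[:, j], surf.relative_hazard[:, j], np.nan)
        ax.plot(surf.dtr_values, line, label=f"MinT {m:.1f}")
    ax.set_yscale("log")
    ax.set_xlabel("weighted DTR (deg C)")
    ax.set_ylabel("relative hazard")
    ax.set_title(str(title))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cumulative_figure(result, path) -> None:
    plt = _matplotlib()
    if plt is None:
        return
    from .lagweights import cumulative_weight

    w = result.window
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.step(np.arange(1, w.max_lag + 1), 100 * cumulative_weight(w), where="post")
    ax.set_xlabel("days before event")
    ax.set_ylabel("cumulative weight (%)")
    ax.set_title(result.variable)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cumulative_csv(result, path) -> None:
    import pandas as pd

    from .lagweights import cumulative_weight, normalized_weights

    w = result.window
    pd.DataFrame(
        {
            "lag": np.arange(1, w.max_lag + 1),
            "weight": normalized_weights(w),
            "cumulative": cumulative_weight(w),
        }
    ).to_csv(path, index=False)
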