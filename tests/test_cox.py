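import numpy as np
import pandas as pd
import pytest

from climcox.cox import (
    CohortIntervals,
    ModelSpec,
    aicc,
    akaike_weights,
    expand_to_intervals,
    fit_cox,
    lr_test,
    partial_loglik,
    reduce_to_risk_rows,
)
from climcox.errors import (
    ConvergenceError,
    DataError,
    MissingCovariateError,
    RankDeficiencyError,
)
from climcox.lagweights import WeibullWindow, build_weighted_covariate

from conftest import make_intervals


# ---------------------------------------------------------------------------
# independent brute-force partial-likelihood oracle (risk-set enumeration)

def brute_force_loglik(df, beta, terms, ties="efron"):
    beta = np.atleast_1d(beta)
    eta = df[list(terms)].to_numpy(float) @ beta
    r = np.exp(eta)
    ll = 0.0
    for t in sorted(df.loc[df["event"] == 1, "stop"].unique()):
        at_risk = (df["start"].to_numpy() < t) & (df["stop"].to_numpy() >= t)
        dead = at_risk & (df["event"].to_numpy() == 1) & (df["stop"].to_numpy() == t)
        d = int(dead.sum())
        s0 = r[at_risk].sum()
        s0_dead = r[dead].sum()
        ll += eta[dead].sum()
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= np.log(s0 - frac * s0_dead)
    return ll


class TestPartialLoglik:
    def test_single_event_beta_zero(self):
        # one event with m=4 in the risk set: contribution is -log 4
        df = pd.DataFrame(
            {
                "id": [0, 1, 2, 3],
                "start": [0.0] * 4,
                "stop": [1.0] * 4,
                "event": [1, 0, 0, 0],
                "x": [0.3, -1.0, 0.5, 2.0],
            }
        )
        data = make_intervals(df, ("x",))
        assert partial_loglik([0.0], data) == pytest.approx(-np.log(4), abs=1e-12)

    def test_no_events_is_zero(self):
        df = pd.DataFrame(
            {"id": [0, 1], "start": [0.0, 0.0], "stop": [1.0, 1.0], "event": [0, 0], "x": [1.0, 2.0]}
        )
        data = make_intervals(df, ("x",))
        assert partial_loglik([0.5], data) == 0.0

    def test_hand_computed_risk_sets(self):
        # 5 rows, 2 untied events (id1 at t=1, id0 at t=2), beta=0.5
        df = pd.DataFrame(
            {
                "id": [0, 0, 1, 2, 2],
                "start": [0.0, 1.0, 0.0, 0.0, 1.0],
                "stop": [1.0, 2.0, 1.0, 1.0, 2.0],
                "event": [0, 1, 1, 0, 0],
                "x": [0.2, 0.2, -0.4, 1.0, 1.0],
            }
        )
        data = make_intervals(df, ("x",))
        beta = np.array([0.5])
        expected = brute_force_loglik(df, beta, ("x",))
        assert partial_loglik(beta, data) == pytest.approx(expected, abs=1e-12)
        # explicitly: t=1 risk = rows {0, 2, 3}, event row 2;
        #             t=2 risk = rows {1, 4}, event row 1
        r = np.exp(0.5 * df["x"].to_numpy())
        manual = (0.5 * -0.4 - np.log(r[[0, 2, 3]].sum())) + (
            0.5 * 0.2 - np.log(r[[1, 4]].sum())
        )
        assert partial_loglik(beta, data) == pytest.approx(manual, abs=1e-12)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_brute_force_with_ties(self, toy_cox_frame, ties):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        beta = np.array([0.3, -0.2])
        assert partial_loglik(beta, data, ties=ties) == pytest.approx(
            brute_force_loglik(toy_cox_frame, beta, ("x1", "x2"), ties), abs=1e-10
        )

    def test_efron_equals_breslow_when_untied(self, toy_cox_frame):
        # keep at most one event per day
        df = toy_cox_frame.copy()
        seen = set()
        for i, row in df.iterrows():
            if row["event"] == 1:
                if row["stop"] in seen:
                    df.loc[i, "event"] = 0
                seen.add(row["stop"])
        data = make_intervals(df, ("x1", "x2"))
        beta = np.array([0.4, 0.1])
        assert partial_loglik(beta, data, ties="efron") == pytest.approx(
            partial_loglik(beta, data, ties="breslow"), abs=1e-12
        )

    def test_permutation_invariance(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        rng = np.random.default_rng(1)
        perm = data.permuted(rng.permutation(data.n_rows))
        beta = np.array([0.25, -0.5])
        assert partial_loglik(beta, perm) == pytest.approx(
            partial_loglik(beta, data), abs=1e-10
        )

    def test_bad_beta(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        with pytest.raises(DataError):
            partial_loglik([np.inf, 0.0], data)
        with pytest.raises(DataError):
            partial_loglik([0.1], data)


class TestFitCox:
    def test_matches_lifelines(self, toy_cox_frame):
        from lifelines import CoxTimeVaryingFitter

        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        fit = fit_cox(data)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            toy_cox_frame,
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="event",
            formula="x1 + x2",
        )
        assert np.allclose(fit.beta, ctv.params_.to_numpy(), atol=1e-6)
        assert fit.loglik == pytest.approx(ctv.log_likelihood_, abs=1e-8)
        assert np.allclose(fit.se, ctv.standard_errors_.to_numpy(), atol=1e-6)

    def test_hazard_ratio_identity(self, toy_cox_frame):
        fit = fit_cox(make_intervals(toy_cox_frame, ("x1", "x2")))
        assert np.array_equal(fit.hazard_ratios, np.exp(fit.beta))

    def test_duplication_invariance(self, toy_cox_frame):
        # duplicating every individual under shifted ids leaves the
        # Breslow estimate exactly unchanged (the Efron correction is not
        # duplication-invariant because the tie fractions l/d change when
        # tied event counts double)
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        dup = toy_cox_frame.copy()
        dup["id"] = dup["id"] + 1000
        both = pd.concat([toy_cox_frame, dup], ignore_index=True)
        data2 = make_intervals(both, ("x1", "x2"))
        f1 = fit_cox(data, ties="breslow")
        f2 = fit_cox(data2, ties="breslow")
        assert np.allclose(f1.beta, f2.beta, atol=1e-7)
        # Efron estimates remain close, just not identical
        e1 = fit_cox(data)
        e2 = fit_cox(data2)
        assert np.allclose(e1.beta, e2.beta, atol=0.02)

    def test_centering_invariance(self, toy_cox_frame):
        # adding a constant to a covariate column changes no hazard ratio
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        shifted = data.with_columns({"x1": data.column("x1") + 17.3})
        f1, f2 = fit_cox(data), fit_cox(shifted)
        assert np.allclose(f1.beta, f2.beta, atol=1e-7)
        assert np.allclose(f1.se, f2.se, atol=1e-7)

    def test_permutation_invariance_of_fit(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        rng = np.random.default_rng(5)
        perm = data.permuted(rng.permutation(data.n_rows))
        f1, f2 = fit_cox(data), fit_cox(perm)
        assert np.allclose(f1.beta, f2.beta, atol=1e-9)
        assert f1.aicc == pytest.approx(f2.aicc, abs=1e-8)

    def test_simulation_consistency_binary_covariate(self):
        # true log-HR 0.7 on a binary covariate; estimate within 3 SE
        rng = np.random.default_rng(12)
        rows = []
        for i in range(600):
            x = float(i % 2)
            p = 1 - np.exp(-0.004 * np.exp(0.7 * x))
            for d in range(1, 301):
                ev = rng.uniform() < p
                rows.append((i, d - 1.0, float(d), int(ev), x))
                if ev:
                    break
        df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x"])
        fit = fit_cox(make_intervals(df, ("x",)), robust=False)
        assert abs(fit.coef("x") - 0.7) < 3 * fit.se[0]

    def test_rank_deficiency_names_terms(self, toy_cox_frame):
        df = toy_cox_frame.copy()
        df["x3"] = 2.0 * df["x1"]
        data = make_intervals(df, ("x1", "x2", "x3"))
        with pytest.raises(RankDeficiencyError) as err:
            fit_cox(data)
        assert any(t in err.value.aliased for t in ("x1", "x3"))

    def test_reduce_to_risk_rows_preserves_fit(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        reduced = reduce_to_risk_rows(data)
        f1, f2 = fit_cox(data), fit_cox(reduced)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-10)
        assert f1.aicc == pytest.approx(f2.aicc, abs=1e-10)

    def test_null_model(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        fit = fit_cox(data, terms=())
        assert fit.n_params == 0
        assert fit.loglik == pytest.approx(
            brute_force_loglik(toy_cox_frame, np.zeros(2), ("x1", "x2")), abs=1e-10
        )

    def test_nonconvergence_reports_trace(self):
        # complete separation: covariate is the event indicator at the
        # individual level, likelihood increases without bound
        df = pd.DataFrame(
            {
                "id": np.arange(20),
                "start": 0.0,
                "stop": 1.0,
                "event": [1] * 10 + [0] * 10,
                "x": [1.0] * 10 + [0.0] * 10,
            }
        )
        data = make_intervals(df, ("x",))
        with pytest.raises(ConvergenceError) as err:
            fit_cox(data, max_iter=8)
        assert len(err.value.trace) > 0


class TestAicc:
    def test_arithmetic(self):
        assert aicc(-50.0, 3, 50) == pytest.approx(106 + 24 / 46, abs=1e-12)

    def test_p_zero(self):
        assert aicc(-123.4, 0, 10) == pytest.approx(246.8, abs=1e-12)

    def test_asymptotic_aic(self):
        a = aicc(-100.0, 5, int(1e9))
        assert abs(a - (200 + 10)) < 1e-6

    def test_undefined(self):
        with pytest.raises(DataError):
            aicc(-10.0, 5, 6)


class TestLrTest:
    def test_identical_models(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        f = fit_cox(data)
        res = lr_test(f, f)
        assert res.x2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_chi2_quantile_identity(self):
        from scipy import stats as scistats

        assert scistats.chi2.sf(3.841, 1) == pytest.approx(0.0500, abs=1e-4)
        assert scistats.chi2.sf(10.411, 1) == pytest.approx(0.00125, abs=5e-5)

    def test_nested_test(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        full = fit_cox(data)
        reduced = fit_cox(data, terms=("x1",))
        res = lr_test(full, reduced)
        assert res.df == 1
        assert res.x2 == pytest.approx(2 * (full.loglik - reduced.loglik), abs=1e-10)
        assert 0.0 <= res.p_value <= 1.0

    def test_non_nested_rejected(self, toy_cox_frame):
        data = make_intervals(toy_cox_frame, ("x1", "x2"))
        f1 = fit_cox(data, terms=("x1",))
        f2 = fit_cox(data, terms=("x2",))
        with pytest.raises(DataError):
            lr_test(f1, f2)


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_values(self):
        w = akaike_weights([50.0] * 4)
        assert np.allclose(w, 0.25)

    def test_sum_to_one(self):
        rng = np.random.default_rng(2)
        w = akaike_weights(rng.uniform(100, 140, size=9))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            akaike_weights([])


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(DataError):
            ModelSpec(terms=("DTR:MinT", "DTR"))  # missing MinT

    def test_age_interactions_need_only_non_age_parent(self):
        spec = ModelSpec(terms=("DTR", "MinT", "DTR:age", "AgeStart", "AgeStart:age"))
        assert "DTR:age" in spec.terms

    def test_unknown_term(self):
        with pytest.raises(DataError):
            ModelSpec(terms=("Humidity",))


class TestExpandToIntervals:
    @pytest.fixture()
    def setup(self, small_sim):
        sim = small_sim
        weighted = {
            "MinT": build_weighted_covariate(sim["climate"], "MinT", sim["truth"].mint_window),
            "DTR": build_weighted_covariate(sim["climate"], "DTR", sim["truth"].dtr_window),
        }
        return sim, weighted

    def test_row_counts_and_events(self, setup):
        sim, weighted = setup
        burn = 30
        data = expand_to_intervals(
            weighted, sim["events"], ("DTR", "MinT"), burn_in=burn
        )
        ev = sim["events"]
        at_risk = ev["exit_day"] - ev["entry_day"]
        kept = ev[at_risk > burn]
        assert data.n_rows == int((at_risk[at_risk > burn] - burn).sum())
        assert data.n_events == int(kept["event"].sum())

    def test_single_survivor_rows(self):
        roster = pd.DataFrame(
            {
                "id": [0],
                "entry_day": [40],
                "exit_day": [80],
                "event": [0],
                "age_entry_years": [1.0],
                "aviary": ["a"],
            }
        )
        climate_vals = np.arange(120, dtype=float)
        from climcox.climate import DailyClimate
        from climcox.lagweights import WeibullWindow as W

        clim = DailyClimate(mint=climate_vals, dtr=np.ones(120))
        weighted = {
            "MinT": build_weighted_covariate(clim, "MinT", W(shape=1.5, scale=3, max_lag=20))
        }
        data = expand_to_intervals(weighted, roster, ("MinT",), burn_in=30)
        assert data.n_rows == 10
        assert data.n_events == 0
        assert np.all(data.stop - data.start == 1.0)

    def test_death_event_on_final_row(self, setup):
        sim, weighted = setup
        data = expand_to_intervals(weighted, sim["events"], ("DTR", "MinT"), burn_in=30)
        ev = sim["events"]
        dead = ev[(ev["event"] == 1) & (ev["exit_day"] - ev["entry_day"] > 30)]
        for _, row in dead.head(5).iterrows():
            rows = data.ids == row["id"]
            assert data.event[rows].sum() == 1
            tau_ev = data.stop[rows][data.event[rows]][0]
            assert tau_ev == row["exit_day"] - row["entry_day"]

    def test_staggered_enumeration_by_hand(self):
        # 3 birds entering on different days over a toy climate
        from climcox.climate import DailyClimate
        from climcox.lagweights import WeibullWindow as W

        clim = DailyClimate(mint=np.zeros(60), dtr=np.ones(60))
        roster = pd.DataFrame(
            {
                "id": [0, 1, 2],
                "entry_day": [10, 15, 20],
                "exit_day": [30, 40, 26],
                "event": [1, 0, 1],
                "age_entry_years": [1.0, 2.0, 0.5],
                "aviary": ["a", "a", "b"],
            }
        )
        weighted = {"MinT": build_weighted_covariate(clim, "MinT", W(shape=1, scale=2, max_lag=10))}
        data = expand_to_intervals(weighted, roster, ("MinT",), burn_in=5)
        # at-risk days after burn-in: (30-10-5) + (40-15-5) + (26-20-5) = 15+20+1
        assert data.n_rows == 36
        assert data.n_events == 2

    def test_missing_covariate_day_error(self):
        from climcox.climate import DailyClimate
        from climcox.lagweights import WeibullWindow as W

        clim = DailyClimate(mint=np.zeros(50), dtr=np.ones(50))
        roster = pd.DataFrame(
            {
                "id": [0],
                "entry_day": [5],  # window needs 20 days of history
                "exit_day": [30],
                "event": [0],
                "age_entry_years": [1.0],
                "aviary": ["a"],
            }
        )
        weighted = {"MinT": build_weighted_covariate(clim, "MinT", W(shape=1, scale=2, max_lag=20))}
        with pytest.raises(MissingCovariateError):
            expand_to_intervals(weighted, roster, ("MinT",), burn_in=2)

    def test_centering_is_bird_day_mean(self, setup):
        sim, weighted = setup
        data = expand_to_intervals(weighted, sim["events"], ("DTR", "MinT"), burn_in=30)
        assert data.column("DTR").mean() == pytest.approx(0.0, abs=1e-9)
        assert data.column("MinT").mean() == pytest.approx(0.0, abs=1e-9)
        raw = weighted["DTR"].raw[data.day]
        assert data.centering["DTR"] == pytest.approx(raw.mean(), rel=1e-12)

    def test_age_timescale_delayed_entry(self, setup):
        sim, weighted = setup
        data = expand_to_intervals(
            weighted, sim["events"], ("DTR", "MinT"), burn_in=30, timescale="age"
        )
        # starts reflect entry age: all positive, heterogeneous
        assert np.all(data.start > 0)
        assert np.unique(np.round(data.start[np.argsort(data.ids)], 3)).size > 10
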