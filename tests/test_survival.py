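"""Parametric survival engine: closed-form oracles, recovery simulations,
an independent lifelines cross-check, and the model-selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuapath.states import EventHistory, HealthState
from cuapath.survival import (
    FitError,
    MODEL_GROUP_PLAN,
    build_first_event_dataset,
    build_other_cause_dataset,
    build_transition_dataset,
    fit_parametric,
    fit_spline_odds,
    select_model,
)

HS = HealthState


def _sim_weibull(n, shape, scale, beta_aft=0.0, cens_hi=6.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = scale * np.exp(beta_aft * x) * rng.weibull(shape, n)
    cens = rng.uniform(0, cens_hi, n)
    return pd.DataFrame(dict(time=np.minimum(t, cens),
                             event=(t <= cens).astype(int), x=x))


class TestFitParametric:
    def test_exponential_closed_form_mle(self):
        """Rate MLE = events / person-time (10 events, 100 person-years)."""
        ds = pd.DataFrame(dict(time=np.ones(100),
                               event=np.r_[np.ones(10), np.zeros(90)]))
        m = fit_parametric(ds, "exponential")
        assert np.exp(m.params[0]) == pytest.approx(0.10, rel=1e-5)
        # AIC = 2k - 2 logL with the analytic exponential log-likelihood
        ll = 10 * np.log(0.10) - 0.10 * 100
        assert m.aic == pytest.approx(2 - 2 * ll, rel=1e-6)

    def test_weibull_shape_ci_coverage(self):
        """95% CI for the Weibull shape covers the true value 1 in >= 90% of
        100 replicates (exponential data, shape = 1)."""
        cover = 0
        for rep in range(100):
            ds = _sim_weibull(300, 1.0, 2.0, seed=rep)
            m = fit_parametric(ds, "weibull")
            log_shape, se = m.params[0], np.sqrt(m.vcov[0, 0])
            if log_shape - 1.96 * se <= 0.0 <= log_shape + 1.96 * se:
                cover += 1
        assert cover >= 90

    def test_all_censored_refuses(self):
        ds = pd.DataFrame(dict(time=np.ones(50), event=np.zeros(50)))
        with pytest.raises(FitError):
            fit_parametric(ds, "lognormal")

    def test_lifelines_oracle_weibull_aft(self):
        """Coefficients agree with the independent lifelines Weibull AFT fit."""
        from lifelines import WeibullAFTFitter

        ds = _sim_weibull(1500, 1.4, 2.0, beta_aft=0.4, seed=5)
        m = fit_parametric(ds, "weibull", ["x"])
        aft = WeibullAFTFitter().fit(ds, duration_col="time", event_col="event")
        assert m.params[1] == pytest.approx(
            aft.params_[("lambda_", "Intercept")], abs=0.02)
        assert m.params[2] == pytest.approx(aft.params_[("lambda_", "x")], abs=0.02)
        assert np.exp(m.params[0]) == pytest.approx(
            np.exp(aft.params_[("rho_", "Intercept")]), rel=0.02)

    def test_generalized_gamma_nests_lognormal(self):
        rng = np.random.default_rng(9)
        t = np.exp(rng.normal(0.5, 0.6, 1200))
        ds = pd.DataFrame(dict(time=t, event=1))
        mg = fit_parametric(ds, "generalized_gamma")
        ml = fit_parametric(ds, "lognormal")
        assert mg.loglik >= ml.loglik - 0.5
        # Q should sit near 0 (the lognormal point)
        assert abs(mg.params[1]) < 0.35


class TestSplineOdds:
    def test_df1_matches_loglogistic(self):
        """df=1 is the proportional-odds log-logistic model: survival curves
        agree with the closed-form MLE fit at grid points."""
        t = stats.fisk.rvs(c=2.0, scale=1.5, size=3000, random_state=3)
        ds = pd.DataFrame(dict(time=t, event=1))
        m = fit_spline_odds(ds, df=1)
        c, _, sc = stats.fisk.fit(t, floc=0)
        grid = np.array([0.5, 1.0, 1.5, 2.5, 4.0])
        assert np.abs(m.sf(grid) - stats.fisk.sf(grid, c, scale=sc)).max() < 1e-3

    def test_survival_structure(self):
        ds = _sim_weibull(800, 1.2, 2.0, seed=2)
        m = fit_spline_odds(ds, df=5)
        grid = np.geomspace(1e-4, 60.0, 200)
        s = m.sf(grid)
        assert m.sf(1e-10) > 0.999  # S(0) = 1
        assert (np.diff(s) <= 1e-10).all()  # monotone non-increasing

    def test_covariate_recovery(self):
        """A simulated -0.5 log-odds arm effect is recovered within 3 SE at
        n=2000 (proportional-odds data)."""
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        # proportional odds: S = 1/(1 + exp(beta*x) * (t/s)^c)
        u = rng.uniform(size=n)
        c, s_, beta = 2.0, 2.0, -0.5
        t = s_ * ((1 - u) / (u * np.exp(beta * x))) ** (1 / c)
        cens = rng.uniform(0, 8, n)
        ds = pd.DataFrame(dict(time=np.minimum(t, cens),
                               event=(t <= cens).astype(int), x=x))
        m = fit_spline_odds(ds, df=3, covariates=["x"])
        b = m.params[-1]
        se = np.sqrt(m.vcov[-1, -1])
        assert abs(b - beta) < 3 * se

    def test_too_few_events_instructs_df_reduction(self):
        ds = pd.DataFrame(dict(time=[1.0, 2.0, 3.0] + [5.0] * 50,
                               event=[1, 1, 1] + [0] * 50))
        with pytest.raises(FitError, match="df"):
            fit_spline_odds(ds, df=5)


class TestSelectModel:
    def _m(self, family, aic, k):
        from tests.conftest import make_exp_model
        m = make_exp_model(1.0)
        m.family = family
        m.aic = aic
        m.params = np.zeros(k)
        return m

    def test_minimum_aic(self):
        ms = [self._m("exponential", 100.0, 1), self._m("weibull", 98.2, 2),
              self._m("lognormal", 120.5, 2)]
        assert select_model(ms).aic == 98.2

    def test_tie_prefers_fewer_parameters(self):
        ms = [self._m("weibull", 98.2, 2), self._m("exponential", 98.2, 1)]
        assert select_model(ms).family == "exponential"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_exponential_data_selects_nesting_family(self):
        """On exponential data the selected model is exponential or Weibull
        and its survival curve is within 0.02 of truth at 5 grid times."""
        rng = np.random.default_rng(11)
        lam = 0.5
        t = rng.exponential(1 / lam, 4000)
        cens = np.full(4000, 8.0)
        ds = pd.DataFrame(dict(time=np.minimum(t, cens),
                               event=(t <= cens).astype(int)))
        fits = [fit_parametric(ds, f)
                for f in ("exponential", "weibull", "lognormal",
                          "generalized_gamma")]
        best = select_model(fits)
        assert best.family in ("exponential", "weibull")
        grid = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        assert np.abs(best.sf(grid) - np.exp(-lam * grid)).max() < 0.02

    def test_aic_within_two_of_generating_family(self):
        """The generating family's AIC is within 2 of the minimum in >= 80%
        of replicates at n=2000."""
        ok = 0
        for rep in range(15):
            ds = _sim_weibull(2000, 1.0, 2.0, seed=100 + rep)  # exponential
            fits = [fit_parametric(ds, f)
                    for f in ("exponential", "weibull", "lognormal")]
            aics = {f.family: f.aic for f in fits}
            if aics["exponential"] <= min(aics.values()) + 2.0:
                ok += 1
        assert ok >= 12  # 80% of 15


class TestSampling:
    def test_exponential_mean(self):
        from tests.conftest import make_exp_model
        m = make_exp_model(0.5)
        rng = np.random.default_rng(0)
        draws = np.array([m.sample(rng) for _ in range(100_000)])
        se = 2.0 / np.sqrt(len(draws))
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_memorylessness(self):
        """Conditional exponential excess times match the unconditional
        distribution (KS test)."""
        from tests.conftest import make_exp_model
        m = make_exp_model(0.5)
        rng = np.random.default_rng(1)
        uncond = np.array([m.sample(rng) for _ in range(4000)])
        excess = np.array([m.sample(rng, conditional_on=3.0) - 3.0
                           for _ in range(4000)])
        assert (excess > 0).all()
        assert stats.ks_2samp(uncond, excess).pvalue > 0.01

    def test_seed_reproducibility(self):
        from tests.conftest import make_exp_model
        m = make_exp_model(0.3)
        d1 = m.sample(np.random.default_rng(42))
        d2 = m.sample(np.random.default_rng(42))
        assert d1 == d2

    def test_spline_sampling_matches_sf(self):
        """Inverse-CDF draws from the spline model reproduce its own survival
        function (empirical S(t) within MC error)."""
        ds = _sim_weibull(800, 1.3, 2.0, seed=3)
        m = fit_spline_odds(ds, df=3)
        rng = np.random.default_rng(2)
        draws = np.array([m.sample(rng) for _ in range(3000)])
        for t0 in (0.5, 1.5, 3.0):
            p = float(m.sf(t0))
            se = np.sqrt(p * (1 - p) / len(draws))
            assert abs((draws > t0).mean() - p) < 4 * se


class TestDatasetsAndSuite:
    def test_first_event_recount(self, cohort300):
        ds = build_first_event_dataset(cohort300.histories, cohort300.profiles)
        assert len(ds) == len(cohort300.histories)
        brute = sum(
            1 for h in cohort300.histories
            if len(h.records) > 1 and h.records[1][0] is not HS.HS9
        )
        assert ds.event.sum() == brute
        row = ds[ds.patient_id == cohort300.histories[0].patient_id].iloc[0]
        h0 = cohort300.histories[0]
        expect = (h0.records[1][1] if len(h0.records) > 1 else h0.censor_day)
        assert row.time == pytest.approx(expect / 365.25)

    def test_transition_dataset_competing_censor(self):
        h = EventHistory("a", [(HS.HS2, 0.0), (HS.HS5, 100.0),
                               (HS.HS6, 300.0)], 500.0, True)
        profiles = pd.DataFrame([dict(patient_id="a", arm="SOC",
                                      baseline_state="HS2", age_group="<60",
                                      who_status="0", nodal_stage="N0",
                                      england=1, era_post2013=0)])
        ds = build_transition_dataset([h], profiles, {HS.HS5}, {HS.HS8})
        assert len(ds) == 1
        assert ds.event.iloc[0] == 0  # HS6 exit censors the HS5->HS8 row
        assert ds.time.iloc[0] == pytest.approx(200 / 365.25)
        assert ds.failure_years.iloc[0] == pytest.approx(100 / 365.25)

    def test_other_cause_dataset(self, cohort300):
        ds = build_other_cause_dataset(cohort300.histories, cohort300.profiles)
        brute = sum(h.records[-1][0] is HS.HS9 for h in cohort300.histories)
        assert ds.event.sum() == brute

    def test_suite_covers_all_transitions(self, suite300):
        covered = sorted(
            t for m in suite300.models.values() for t in m.transition_group
        )
        assert len(covered) == 25 and len(set(covered)) == 25
        # post-failure models accept the time-from-randomisation-to-failure
        for g in ("to_hs7", "hs4_hs5", "hs5_hs6", "hs4_hs8", "hs5_hs8",
                  "hs6_hs8", "hs7_hs8"):
            assert "failure_years" in suite300.models[g].covariates

    def test_suite_arm_effect_recovered(self, suite300):
        """The fitted first-event model shows the AAP arm's strongly reduced
        failure hazard (generating log-HR -0.9)."""
        m = suite300.models["first_event"]
        i = m.covariates.index("arm_aap")
        shapes = 1 if m.family == "weibull" else 0
        b = m.params[len(m.params) - len(m.covariates) + i]
        # in AFT form a hazard reduction is a positive time-scale effect
        assert m.sf(2.0, {"arm_aap": 1.0}) > m.sf(2.0, {"arm_aap": 0.0})

    def test_selected_first_event_tracks_kaplan_meier(self, cohort300, suite300):
        """Predicted within-sample survival lies inside the Kaplan-Meier 95%
        band at the quartiles of observed event times."""
        from lifelines import KaplanMeierFitter

        ds = build_first_event_dataset(cohort300.histories, cohort300.profiles)
        km = KaplanMeierFitter().fit(ds.time, ds.event)
        m = suite300.models["first_event"]
        qs = np.quantile(ds.loc[ds.event == 1, "time"], [0.25, 0.5, 0.75])
        ci = km.confidence_interval_survival_function_
        for t0 in qs:
            idx = ci.index[ci.index <= t0][-1]
            lo, hi = ci.loc[idx].to_numpy()
            pred = float(np.mean([
                m.sf(t0, dict(r)) for r in
                ds[m.covariates].sample(100, random_state=0).to_dict("records")
            ]))
            assert lo - 0.03 <= pred <= hi + 0.03

    def test_model_suite_json_round_trip(self, suite300, tmp_path):
        from cuapath.survival import ModelSuite

        p = tmp_path / "suite.json"
        suite300.to_json(p)
        back = ModelSuite.from_json(p)
        for k, m in suite300.models.items():
            np.testing.assert_allclose(back.models[k].params, m.params)
            assert back.models[k].family == m.family
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        cov = {"arm_aap": 1.0}
        assert back.models["first_event"].sample(rng1, cov) == \
            suite300.models["first_event"].sample(rng2, cov)
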