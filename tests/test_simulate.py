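"""Microsimulation engine: closed-form lifetime oracles, the mortality
splice, discounting arithmetic, and structural accrual invariants."""

import numpy as np
import pandas as pd
import pytest

from cuapath.costs import CYCLE_DAYS, UnitCostTable
from cuapath.simulate import (
    GompertzLifeTable,
    MortalitySplice,
    SimulationSettings,
    accrue_costs,
    accrue_qalys,
    apply_mortality_splice,
    run_deterministic,
    simulate_patient,
)
from cuapath.states import DEAD_STATES, EventHistory, HealthState

from tests.conftest import make_exp_model, make_exp_suite

HS = HealthState
DAYS = 365.25


def _flat_utility(value):
    return lambda profile, state, in_y1, arm: value


ZERO_COSTS = UnitCostTable(
    end_of_life=0.0, sae_flat=0.0, monitoring_per_cycle=0.0, stop_cost=0.0
)


class TestSimulatePatient:
    def test_zero_hazards_alive_full_horizon(self, profile_m0):
        suite = make_exp_suite()  # everything ~0
        settings = SimulationSettings(seed=1)
        rng = np.random.default_rng(0)
        h = simulate_patient(profile_m0, suite, settings, rng,
                             MortalitySplice(life_table=GompertzLifeTable(
                                 level=1e-300), splice_day=1e9))
        assert h.censored
        q = accrue_qalys(h, _flat_utility(1.0),
                         profile_m0, SimulationSettings(discount_rate=0.0))
        assert q["life_years"] == pytest.approx(45.0, abs=1e-6)

    def test_all_cause_exponential_truncated_mean(self, profile_m0):
        """With a single 0.2/yr other-cause hazard, mean life-years over the
        45-year horizon match the truncated-exponential closed form within
        3 SE at 1e4 replicates."""
        lam, T = 0.2, 45.0
        suite = make_exp_suite(other_cause_rate=lam)
        settings = SimulationSettings(seed=2, discount_rate=0.0)
        splice = MortalitySplice(life_table=GompertzLifeTable(level=1e-300),
                                 splice_day=1e9)
        rng = np.random.default_rng(3)
        n = 10_000
        ly = np.empty(n)
        for i in range(n):
            h = simulate_patient(profile_m0, suite, settings, rng, splice)
            ly[i] = (min(h.end_day, settings.horizon_days)) / DAYS
        true_mean = (1 - np.exp(-lam * T)) / lam
        se = ly.std(ddof=1) / np.sqrt(n)
        assert abs(ly.mean() - true_mean) < 3 * se

    def test_histories_structurally_valid(self, profile_m1):
        suite = make_exp_suite(first_rate=0.4, other_cause_rate=0.02,
                               crpc_death_rate=0.5, crpc_prog_rate=0.3)
        rng = np.random.default_rng(4)
        settings = SimulationSettings(seed=5)
        for _ in range(200):
            h = simulate_patient(profile_m1, suite, settings, rng)
            days = [d for _, d in h.records]
            assert all(b > a for a, b in zip(days, days[1:]))
            dead = [s for s, _ in h.records if s in DEAD_STATES]
            assert len(dead) <= 1

    def test_occupancy_exhaustive(self, profile_m1):
        """Summed state occupancy equals time to death or horizon."""
        suite = make_exp_suite(first_rate=0.5, other_cause_rate=0.05,
                               crpc_death_rate=0.4, crpc_prog_rate=0.3)
        rng = np.random.default_rng(6)
        settings = SimulationSettings(seed=7)
        for _ in range(50):
            h = simulate_patient(profile_m1, suite, settings, rng)
            total = sum(hi - lo for _, lo, hi in
                        h.intervals(settings.horizon_days))
            expect = min(h.end_day, settings.horizon_days)
            assert total == pytest.approx(expect, abs=1e-6)


class TestMortalitySplice:
    def test_trial_draw_before_splice_kept(self, profile_m0):
        suite = make_exp_suite(other_cause_rate=5.0)  # death ~70 days
        splice = MortalitySplice(splice_day=5 * DAYS)
        rng = np.random.default_rng(0)
        draws = [apply_mortality_splice(profile_m0, suite, splice, rng)
                 for _ in range(500)]
        early = [d for d in draws if d <= splice.splice_day]
        # at rate 5/yr essentially every draw is pre-splice and untouched
        assert len(early) > 490

    def test_negligible_trial_hazard_gives_life_table_median(self, profile_m0):
        """With ~zero trial hazard, the simulated median age at death matches
        the conditional Gompertz median."""
        lt = GompertzLifeTable()
        suite = make_exp_suite(other_cause_rate=0.0)  # never dies in trial
        splice = MortalitySplice(life_table=lt, splice_day=5 * DAYS)
        rng = np.random.default_rng(1)
        n = 4000
        ages = np.empty(n)
        age0 = 65.0  # profile_m0 is 60-69
        for i in range(n):
            d = apply_mortality_splice(profile_m0, suite, splice, rng)
            ages[i] = age0 + d / DAYS
        age_splice = age0 + 5.0
        med_true = lt.median_death_age(age_splice)
        # binomial SE of the sample median via density at the median
        med_hat = np.median(ages)
        assert abs(med_hat - med_true) < 0.5  # years; ~10x the MC error

    def test_infinite_slope_dies_at_splice(self, profile_m0):
        lt = GompertzLifeTable(slope=40.0, level=1e-4)
        suite = make_exp_suite(other_cause_rate=0.0)
        splice = MortalitySplice(life_table=lt, splice_day=3 * DAYS)
        rng = np.random.default_rng(2)
        d = apply_mortality_splice(profile_m0, suite, splice, rng)
        assert d == pytest.approx(3 * DAYS, rel=1e-3)

    def test_gompertz_sampler_matches_survival(self):
        lt = GompertzLifeTable()
        rng = np.random.default_rng(3)
        ages = np.array([lt.sample_death_age(70.0, rng) for _ in range(5000)])
        for a in (75.0, 80.0, 90.0):
            p = lt.survival(a, 70.0)
            se = np.sqrt(p * (1 - p) / len(ages))
            assert abs((ages > a).mean() - p) < 4 * se


class TestAccrueQalys:
    def test_full_health_no_discount_is_horizon(self, profile_m0):
        h = EventHistory("p", [(HS.HS1, 0.0)], 46 * DAYS, True)
        q = accrue_qalys(h, _flat_utility(1.0), profile_m0,
                         SimulationSettings(discount_rate=0.0))
        assert q["qalys"] == pytest.approx(45.0, abs=1e-9)

    def test_one_year_at_08(self, profile_m0):
        h = EventHistory("p", [(HS.HS1, 0.0)], DAYS, True)
        q = accrue_qalys(h, _flat_utility(0.8), profile_m0,
                         SimulationSettings(discount_rate=0.0))
        assert q["qalys"] == pytest.approx(0.8, abs=1e-9)

    def test_annuity_closed_form(self, profile_m0):
        """Discounted full-health QALYs over 45 years match the continuous
        annuity integral within 0.1% (midpoint discounting)."""
        h = EventHistory("p", [(HS.HS1, 0.0)], 46 * DAYS, True)
        settings = SimulationSettings(discount_rate=0.035)
        q = accrue_qalys(h, _flat_utility(1.0), profile_m0, settings)
        r = np.log(1.035)
        annuity = (1 - np.exp(-r * 45.0)) / r
        assert q["qalys"] == pytest.approx(annuity, rel=1e-3)

    def test_discounted_not_more_than_undiscounted(self, profile_m1):
        suite = make_exp_suite(first_rate=0.4, other_cause_rate=0.05,
                               crpc_death_rate=0.4, crpc_prog_rate=0.2)
        rng = np.random.default_rng(8)
        settings = SimulationSettings(seed=9)
        for _ in range(30):
            h = simulate_patient(profile_m1, suite, settings, rng)
            q = accrue_qalys(h, _flat_utility(0.85), profile_m1, settings)
            assert q["qalys"] <= q["qalys_undiscounted"] + 1e-12
            assert q["qalys_undiscounted"] <= q["life_years"] + 1e-12
            assert q["life_years"] <= settings.horizon_years + 1e-9


class TestAccrueCosts:
    def test_zero_unit_costs_zero_total(self, profile_m0):
        h = EventHistory("p", [(HS.HS1, 0.0), (HS.HS8, 500.0)], 500.0, False)
        c = accrue_costs(h, None, None, ZERO_COSTS, profile_m0,
                         SimulationSettings())
        assert c["total"] == 0.0

    def test_end_of_life_discounting(self, profile_m0):
        """A single end-of-life charge at year 10 is 6,897 x 1.035^-10 within
        cycle-midpoint tolerance."""
        death = 10 * DAYS
        h = EventHistory("p", [(HS.HS1, 0.0), (HS.HS8, death)], death, False)
        uc = UnitCostTable(sae_flat=0.0, monitoring_per_cycle=0.0)
        settings = SimulationSettings()
        c = accrue_costs(h, None, None, uc, profile_m0, settings)
        expect = 6897.0 * 1.035 ** (-10.0)
        assert c["addon"] == pytest.approx(expect, rel=0.005)

    def test_doubling_abiraterone_price_doubles_investigational(
            self, cohort300, suite300, utility_model300, cost_artifacts300,
            profile_m1):
        uc = cost_artifacts300["unit_costs"]
        mt = cost_artifacts300["med_table"]
        settings = SimulationSettings(seed=10)
        rng = np.random.default_rng(11)
        h = simulate_patient(profile_m1, suite300, settings, rng)
        c1 = accrue_costs(h, None, mt, uc, profile_m1, settings)
        c2 = accrue_costs(h, None, mt,
                          uc.with_abiraterone_price(2 * 97.68),
                          profile_m1, settings)
        pred_daily = uc.items["prednisolone"].gbp
        base_abi = c1["aap_days_disc"] * 97.68
        assert c2["investigational"] - c1["investigational"] == pytest.approx(
            base_abi, rel=1e-9)

    def test_zero_price_removes_aap_component(self, cost_artifacts300,
                                              profile_m1, suite300):
        uc = cost_artifacts300["unit_costs"]
        mt = cost_artifacts300["med_table"]
        settings = SimulationSettings(seed=12)
        rng = np.random.default_rng(13)
        h = simulate_patient(profile_m1, suite300, settings, rng)
        c0 = accrue_costs(h, None, mt, uc.with_abiraterone_price(0.0),
                          profile_m1, settings)
        c1 = accrue_costs(h, None, mt, uc, profile_m1, settings)
        pred_daily = uc.items["prednisolone"].gbp
        assert c1["investigational"] - c0["investigational"] == pytest.approx(
            c1["aap_days_disc"] * 97.68, rel=1e-9)


class TestRunDeterministic:
    def _small(self, cohort300, suite300, utility_model300, cost_artifacts300,
               seed=0, n=6, n_sims=4):
        from cuapath.simulate import make_utility_fn

        return run_deterministic(
            cohort300.profiles.head(n), suite300,
            make_utility_fn(utility_model300),
            cost_artifacts300["cost_model"], cost_artifacts300["med_table"],
            cost_artifacts300["unit_costs"],
            SimulationSettings(seed=seed), n_sims=n_sims,
        )

    def test_seeded_rerun_is_bitwise_identical(self, cohort300, suite300,
                                               utility_model300,
                                               cost_artifacts300):
        a = self._small(cohort300, suite300, utility_model300, cost_artifacts300)
        b = self._small(cohort300, suite300, utility_model300, cost_artifacts300)
        pd.testing.assert_frame_equal(a, b)

    def test_both_arms_simulated_per_profile(self, cohort300, suite300,
                                             utility_model300,
                                             cost_artifacts300):
        s = self._small(cohort300, suite300, utility_model300, cost_artifacts300)
        assert set(s.arm) == {"AAP_SOC", "SOC"}

    def test_aap_extends_failure_free_survival(self, cohort300, suite300,
                                               utility_model300,
                                               cost_artifacts300):
        """With the generator's large first-event hazard reduction, simulated
        failure-free survival is longer under AAP in both subgroups."""
        from cuapath.simulate import make_utility_fn

        s = run_deterministic(
            cohort300.profiles.head(40), suite300,
            make_utility_fn(utility_model300), None,
            cost_artifacts300["med_table"], cost_artifacts300["unit_costs"],
            SimulationSettings(seed=21), n_sims=8,
        )
        for sg in ("M0", "M1"):
            sub = s[s.subgroup == sg]
            if len(sub) < 2:
                continue
            ffs_aap = sub[sub.arm == "AAP_SOC"].ffs_years.iloc[0]
            ffs_soc = sub[sub.arm == "SOC"].ffs_years.iloc[0]
            assert ffs_aap > ffs_soc

    def test_monte_carlo_se_scales_inverse_sqrt(self, profile_m1):
        """SD of the mean QALY estimate shrinks roughly as 1/sqrt(n_sims)."""
        suite = make_exp_suite(first_rate=0.4, other_cause_rate=0.05,
                               crpc_death_rate=0.5, crpc_prog_rate=0.2)
        settings = SimulationSettings(discount_rate=0.0)

        def mean_qaly(n_sims, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(n_sims):
                h = simulate_patient(profile_m1, suite, settings, rng)
                vals.append(accrue_qalys(h, _flat_utility(1.0), profile_m1,
                                         settings)["qalys"])
            return np.mean(vals)

        sds = []
        for n_sims in (5, 20, 80):
            means = [mean_qaly(n_sims, 1000 + n_sims * 100 + r)
                     for r in range(40)]
            sds.append(np.std(means, ddof=1))
        # each 4x increase in sims should halve the SD, within broad MC slack
        assert 1.3 < sds[0] / sds[1] < 3.1
        assert 1.3 < sds[1] / sds[2] < 3.1
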