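"""Cost pipeline: dose-imputation rules, cycle costing arithmetic, the
boundary-split two-part regression, state/band tables and add-on costs."""

import numpy as np
import pandas as pd
import pytest

from cuapath.costs import (
    CYCLE_DAYS,
    SpecificMedCostTable,
    UnitCostTable,
    add_on_costs,
    band_for,
    build_general_cycle_table,
    cost_records,
    fit_two_part_cost,
    impute_doses,
)
from cuapath.states import EventHistory, HealthState

HS = HealthState
DAYS = 365.25


def _rec(pid, item, cat, dose, start, stop):
    return dict(patient_id=pid, item=item, category=cat, dose=dose,
                unit="mg/day", start_day=float(start), stop_day=float(stop))


def _alive(pid="p", end=10 * DAYS):
    return EventHistory(pid, [(HS.HS2, 0.0)], end, True)


class TestImputeDoses:
    def test_soc_abiraterone_blank_gets_full_dose(self):
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 np.nan, 0, 42)])
        out, log = impute_doses(rec)
        assert out.dose.iloc[0] == 1000.0
        assert len(log) == 1 and "1000" in log.rule.iloc[0]
        # at full dose the daily cost is the base price
        uc = UnitCostTable()
        assert uc.daily_cost("abiraterone", 1000.0) == pytest.approx(97.68)

    def test_prednisolone_dates_copied_from_abiraterone(self):
        rec = pd.DataFrame([
            _rec("p", "abiraterone", "investigational", 1000.0, 10, 400),
            _rec("p", "prednisolone", "investigational", np.nan, 0, 50),
        ])
        out, _ = impute_doses(rec)
        pred = out[out.item == "prednisolone"].iloc[0]
        assert pred.dose == 5.0
        assert (pred.start_day, pred.stop_day) == (10.0, 400.0)

    def test_other_drug_uses_modal_dose(self):
        rec = pd.DataFrame([
            _rec("a", "docetaxel", "specific", 2.0, 0, 10),
            _rec("b", "docetaxel", "specific", 2.0, 0, 10),
            _rec("c", "docetaxel", "specific", np.nan, 0, 10),
        ])
        out, log = impute_doses(rec)
        assert out.dose.iloc[2] == 2.0
        assert log.rule.iloc[0] == "modal observed dose"

    def test_no_missing_identity_and_empty_log(self):
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 1000.0, 0, 42)])
        out, log = impute_doses(rec)
        pd.testing.assert_frame_equal(out, rec)
        assert log.empty

    def test_unknown_item_without_default_raises(self):
        rec = pd.DataFrame([_rec("p", "mystery_drug", "specific",
                                 np.nan, 0, 10)])
        with pytest.raises(ValueError, match="mystery_drug"):
            impute_doses(rec)


class TestCostRecords:
    def test_one_full_cycle_of_abiraterone(self):
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 1000.0, 0, 42)])
        out = cost_records(rec, UnitCostTable(), [_alive()])
        assert out.amount.sum() == pytest.approx(42 * 97.68)  # 4102.56

    def test_record_spanning_cycles_splits_by_days(self):
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 1000.0, 0, 63)])
        out = cost_records(rec, UnitCostTable(), [_alive()]).sort_values(
            "cycle_index")
        assert list(out.cycle_index) == [0, 1]
        np.testing.assert_allclose(out.amount, [42 * 97.68, 21 * 97.68])

    def test_annualised_base_case_exceeds_35k(self):
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 1000.0, 0, 365)])
        out = cost_records(rec, UnitCostTable(), [_alive()])
        assert out.amount.sum() == pytest.approx(365 * 97.68)
        assert out.amount.sum() > 35_000

    def test_truncation_past_death(self):
        h = EventHistory("p", [(HS.HS2, 0.0), (HS.HS8, 100.0)], 100.0, False)
        rec = pd.DataFrame([_rec("p", "abiraterone", "investigational",
                                 1000.0, 0, 400)])
        with pytest.warns(UserWarning, match="truncated"):
            out = cost_records(rec, UnitCostTable(), [h])
        assert out.amount.sum() == pytest.approx(100 * 97.68)

    def test_order_invariance(self, cohort300, cost_artifacts300):
        rec = cost_artifacts300["records"]
        shuffled = rec.sample(frac=1.0, random_state=1)
        a = cost_records(rec, cost_artifacts300["unit_costs"],
                         cohort300.histories)
        b = cost_records(shuffled, cost_artifacts300["unit_costs"],
                         cohort300.histories)
        key = ["patient_id", "cycle_index", "category"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_no_double_counting(self, cost_artifacts300):
        """Total cohort cost via categories equals total via cycles."""
        cyc = cost_artifacts300["cycles"]
        by_cat = cyc.groupby("category").amount.sum().sum()
        by_cycle = cyc.groupby(["patient_id", "cycle_index"]).amount.sum().sum()
        assert by_cat == pytest.approx(by_cycle, rel=1e-12)


class TestTwoPartCost:
    def _cycles(self, n, seed=0, p_high=0.10, low_mean=400.0, high_mean=3000.0):
        rng = np.random.default_rng(seed)
        hi = rng.random(n) < p_high
        amount = np.where(
            hi,
            rng.normal(high_mean, 300.0, n),
            rng.gamma(2.0, low_mean / 2.0, n),
        )
        df = pd.DataFrame(dict(
            patient_id=[f"p{i % 200}" for i in range(n)],
            cycle_index=np.arange(n) % 20,
            arm="SOC", state="HS1", band="lt_1y",
            amount=np.clip(amount, 1.0, None),
        ))
        for c in ("age_60_69", "age_70plus", "who_1_2", "nodal_pos",
                  "ty_aap_y1", "ty_soc_y1"):
            df[c] = 0.0
        return df

    def test_all_below_boundary_mean_is_lower_mean(self):
        df = self._cycles(2000, p_high=0.0)
        m = fit_two_part_cost(df, boundary=1500.0)
        pred = m.predict_mean("SOC", "HS1", {})
        assert pred == pytest.approx(df.amount.mean(), rel=0.05)

    def test_mixture_recovery(self):
        """90% gamma (mean £400) / 10% Gaussian (mean £3,000) mixture:
        component means recovered within 3 SE at n=10,000 cycles."""
        df = self._cycles(10_000, seed=3)
        m = fit_two_part_cost(df, boundary=1500.0)
        st = m._stratum("SOC", "HS1")
        x = m._xrow({})
        p_hat = 1 / (1 + np.exp(-(x @ st.p_params)))
        true_p = (df.amount > 1500).mean()
        assert abs(p_hat - true_p) < 3 * np.sqrt(true_p * (1 - true_p) / len(df))
        hi = df[df.amount > 1500]
        mean_hi_hat = float(np.maximum(x @ st.upper_params, 1500.0))
        assert abs(mean_hi_hat - hi.amount.mean()) < 3 * hi.amount.std() / np.sqrt(len(hi))
        lo = df[df.amount <= 1500]
        eta = st.lower._eta({})
        mean_lo_hat = min(np.exp(eta) * st.lower_mean_const, 1500.0)
        assert abs(mean_lo_hat - lo.amount.mean()) < 3 * lo.amount.std() / np.sqrt(len(lo))

    def test_mean_mixture_identity(self):
        """Predicted mean equals P(<=b)E[low] + P(>b)E[high] exactly."""
        df = self._cycles(3000, seed=4)
        m = fit_two_part_cost(df, boundary=1500.0)
        st = m._stratum("SOC", "HS1")
        x = m._xrow({})
        p_hi = float(1 / (1 + np.exp(-(x @ st.p_params))))
        mean_lo = min(np.exp(st.lower._eta({})) * st.lower_mean_const, 1500.0)
        mean_hi = max(float(x @ st.upper_params), 1500.0)
        assert m.predict_mean("SOC", "HS1", {}) == pytest.approx(
            (1 - p_hi) * mean_lo + p_hi * mean_hi, abs=1e-12)

    def test_small_stratum_pooled_fallback(self):
        df = self._cycles(500, seed=5)
        df.loc[:3, "state"] = "HS7"  # tiny stratum
        with pytest.warns(UserWarning, match="pooled"):
            m = fit_two_part_cost(df, boundary=1500.0)
        assert np.isfinite(m.predict_mean("SOC", "HS7", {}))


class TestSpecificMedTable:
    def test_band_partition(self):
        assert band_for(0.0) == "lt_1y"
        assert band_for(0.999) == "lt_1y"
        assert band_for(1.0) == "y1_2"
        assert band_for(2.5) == "gt_2y"

    def test_cell_mean_equals_brute_force(self, cohort300, cost_artifacts300):
        mt = cost_artifacts300["med_table"]
        cyc = cost_artifacts300["cycles"]
        gen = build_general_cycle_table(cyc, cohort300.histories,
                                        cohort300.profiles)
        spec = (
            cyc[cyc.category == "specific"]
            .set_index(["patient_id", "cycle_index"])["amount"]
        )
        sub = gen[(gen.state == "HS5") & (gen.band == "lt_1y")]
        if len(sub):
            brute = np.mean([
                float(spec.get((r.patient_id, r.cycle_index), 0.0))
                for r in sub.itertuples()
            ])
            assert mt.specific["HS5", "lt_1y"] == pytest.approx(brute, rel=1e-9)

    def test_unknown_state_zero_with_warning(self, cost_artifacts300):
        mt = SpecificMedCostTable({}, {}, set())
        with pytest.warns(UserWarning, match="never visited"):
            assert mt.specific_cost("HS7", "lt_1y") == 0.0

    def test_aap_cells_differ_by_arm(self, cost_artifacts300):
        """The generator gives AAP mostly to the AAP arm, so treated-days per
        cycle differ by arm in the naive bone-met state."""
        mt = cost_artifacts300["med_table"]
        aap = mt.aap_days_per_cycle("HS2", "lt_1y", "AAP_SOC")
        soc = mt.aap_days_per_cycle("HS2", "lt_1y", "SOC")
        assert aap > soc

    def test_band_borrowing(self):
        mt = SpecificMedCostTable({("HS5", "lt_1y"): 100.0}, {}, {"HS5"})
        with pytest.warns(UserWarning, match="borrowing"):
            assert mt.specific_cost("HS5", "gt_2y") == 100.0


class TestAddOns:
    def test_end_of_life_once_at_death(self):
        h = EventHistory("p", [(HS.HS2, 0.0), (HS.HS8, 10.5 * CYCLE_DAYS)],
                         10.5 * CYCLE_DAYS, False)
        out = add_on_costs(h, UnitCostTable())
        eol = out[out.item == "end_of_life"]
        assert len(eol) == 1
        assert eol.amount.iloc[0] == 6897.0
        assert eol.cycle_index.iloc[0] == 10

    def test_no_end_of_life_if_alive(self):
        out = add_on_costs(_alive(), UnitCostTable())
        assert (out.item != "end_of_life").all()

    def test_other_cause_death_excluded_by_default(self):
        h = EventHistory("p", [(HS.HS2, 0.0), (HS.HS9, 100.0)], 100.0, False)
        assert (add_on_costs(h, UnitCostTable()).item != "end_of_life").all()
        all_deaths = add_on_costs(h, UnitCostTable(),
                                  end_of_life_all_deaths=True)
        assert (all_deaths.item == "end_of_life").sum() == 1

    def test_three_saes_flat_cost(self):
        out = add_on_costs(_alive(), UnitCostTable(), sae_count=3)
        assert out[out.item == "sae"].amount.sum() == pytest.approx(3 * 1200.0)
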