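"""Patient-level Markov microsimulation over 42-day cycles.

Lifetimes are simulated in continuous time: from the current state a time
is drawn for each allowed exit from its fitted transition model (inverse
CDF), the minimum wins, and the walk repeats until death or the 45-year
horizon.  Other-cause mortality runs on its own clock from randomisation
and is spliced with a Gompertz life-table hazard beyond the patient's last
documented follow-up, since a trial-fitted parametric model has no support
for extrapolating decades past the data.  Quality-adjusted survival and
costs are then accrued by exact day-overlap with the cycle grid
(area-under-the-curve, no half-cycle bias) and discounted at the cycle
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import (
    BANDS,
    CYCLE_DAYS,
    SpecificMedCostTable,
    TwoPartCostModel,
    UnitCostTable,
    _cost_design_row,
)
from .states import (
    CRPC_STATES,
    DEAD_STATES,
    EventHistory,
    HealthState,
)
from .survival import ModelSuite, encode_covariates
from .utility import TwoPartUtilityModel, predict_state_utility

DAYS_PER_YEAR = 365.25

__all__ = [
    "SimulationSettings",
    "GompertzLifeTable",
    "MortalitySplice",
    "apply_mortality_splice",
    "simulate_patient",
    "accrue_qalys",
    "accrue_costs",
    "run_deterministic",
    "make_utility_fn",
    "AGE_MIDPOINTS",
]

AGE_MIDPOINTS = {"<60": 55.0, "60-69": 65.0, ">=70": 73.0}


@dataclass(frozen=True)
class SimulationSettings:
    cycle_days: float = CYCLE_DAYS
    horizon_years: float = 45.0
    discount_rate: float = 0.035  # per year, costs and outcomes alike
    n_sims_deterministic: int = 40  # replicates per patient profile
    n_sims_psa: int = 25
    psa_iterations: int = 500
    seed: int = 0
    discount_at: str = "midpoint"  # midpoint | start

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years <= 0 or self.cycle_days <= 0:
            raise ValueError("horizon and cycle length must be positive")

    @property
    def horizon_days(self) -> float:
        return self.horizon_years * DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(np.ceil(self.horizon_days / self.cycle_days))

    def discount_factors(self) -> np.ndarray:
        """Per-cycle discount factors (midpoint convention by default)."""
        c = np.arange(self.n_cycles)
        offset = 0.5 if self.discount_at == "midpoint" else 0.0
        t_years = (c + offset) * self.cycle_days / DAYS_PER_YEAR
        return (1.0 + self.discount_rate) ** (-t_years)


@dataclass(frozen=True)
class GompertzLifeTable:
    """Gompertz all-other-cause mortality: h(age) = level * exp(slope*age).

    Defaults approximate published UK male life-table mortality (hazard
    doubling roughly every 7-8 years, about 2%/year at age 70).
    """

    slope: float = 0.095  # per year of age
    level: float = 2.6e-5  # hazard per year at age 0

    def survival(self, age: float, from_age: float) -> float:
        a, b = self.slope, self.level
        return float(np.exp(-(b / a) * (np.exp(a * age) - np.exp(a * from_age))))

    def _inv(self, from_age: float, neg_log_u: float) -> float:
        # age solving S(age|from_age) = u, computed in log space to survive
        # extreme slopes (exp(a*age) overflows double precision)
        a, b = self.slope, self.level
        la = a * from_age
        with np.errstate(over="ignore", under="ignore"):
            x = (a / b) * neg_log_u * np.exp(-la)
        return float(from_age + np.log1p(x) / a)

    def sample_death_age(self, from_age: float, rng: np.random.Generator) -> float:
        return self._inv(from_age, -np.log(rng.uniform()))

    def median_death_age(self, from_age: float) -> float:
        return self._inv(from_age, np.log(2.0))


@dataclass(frozen=True)
class MortalitySplice:
    """Trial other-cause model up to the last documented follow-up, Gompertz
    life table beyond it."""

    life_table: GompertzLifeTable = field(default_factory=GompertzLifeTable)
    splice_day: float = 5 * DAYS_PER_YEAR
    age_midpoints: dict = field(default_factory=lambda: dict(AGE_MIDPOINTS))


def apply_mortality_splice(profile: dict, suite: ModelSuite,
                           splice: MortalitySplice,
                           rng: np.random.Generator) -> float:
    """Other-cause death day: trial-model draw if it lands before the splice
    day, else a Gompertz life-table draw conditional on survival to it."""
    cov = encode_covariates(profile)
    t_trial = suite.models["other_cause"].sample(rng, cov) * DAYS_PER_YEAR
    if t_trial <= splice.splice_day:
        return t_trial
    age0 = splice.age_midpoints[profile["age_group"]]
    age_at_splice = age0 + splice.splice_day / DAYS_PER_YEAR
    death_age = splice.life_table.sample_death_age(age_at_splice, rng)
    return splice.splice_day + (death_age - age_at_splice) * DAYS_PER_YEAR


# exits from each CRPC state: (destination, model-group name)
_CRPC_EXITS = {
    HealthState.HS4: ((HealthState.HS5, "hs4_hs5"), (HealthState.HS7, "to_hs7"),
                      (HealthState.HS8, "hs4_hs8")),
    HealthState.HS5: ((HealthState.HS6, "hs5_hs6"), (HealthState.HS7, "to_hs7"),
                      (HealthState.HS8, "hs5_hs8")),
    HealthState.HS6: ((HealthState.HS7, "to_hs7"), (HealthState.HS8, "hs6_hs8")),
    HealthState.HS7: ((HealthState.HS8, "hs7_hs8"),),
}


def simulate_patient(profile: dict, suite: ModelSuite,
                     settings: SimulationSettings, rng: np.random.Generator,
                     splice: MortalitySplice | None = None) -> EventHistory:
    """Simulate one lifetime trajectory for a patient profile.

    The joint first-event model gives the exit time from the naive state and
    the destination model allocates where it lands; CRPC stays are then
    sampled clock-reset from the fitted post-failure models with time from
    randomisation to failure as a covariate.  Other-cause death competes on
    the randomisation clock throughout, via the mortality splice.
    """
    splice = splice or MortalitySplice()
    cov = encode_covariates(profile)
    horizon = settings.horizon_days
    t9 = apply_mortality_splice(profile, suite, splice, rng)
    records: list[tuple[HealthState, float]] = [
        (HealthState[profile["baseline_state"]], 0.0)
    ]
    t_first = max(
        suite.models["first_event"].sample(rng, cov) * DAYS_PER_YEAR, 1e-6
    )
    dest = suite.destination.sample(profile["baseline_state"], profile["arm"], rng)

    def finish(day: float, state: HealthState | None):
        if state is not None:
            records.append((state, day))
        censored = state is None or state not in DEAD_STATES
        return EventHistory(
            patient_id=str(profile.get("patient_id", "sim")),
            records=records,
            censor_day=min(day, horizon) if censored else day,
            censored=censored,
        )

    if t9 <= min(t_first, horizon):
        return finish(t9, HealthState.HS9)
    if t_first >= horizon:
        return finish(horizon, None)
    if dest is HealthState.HS8:
        return finish(t_first, HealthState.HS8)

    day, state = t_first, dest
    records.append((state, day))
    failure_years = t_first / DAYS_PER_YEAR
    cov_post = cov | {"failure_years": failure_years}
    while True:
        best_day, best_dst = np.inf, None
        for dst, group in _CRPC_EXITS[state]:
            t = max(suite.models[group].sample(rng, cov_post) * DAYS_PER_YEAR,
                    1e-6)
            if day + t < best_day:
                best_day, best_dst = day + t, dst
        if t9 <= min(best_day, horizon):
            return finish(t9, HealthState.HS9)
        if best_day >= horizon:
            return finish(horizon, None)
        day, state = best_day, best_dst
        records.append((state, day))
        if state in DEAD_STATES:
            return EventHistory(
                patient_id=str(profile.get("patient_id", "sim")),
                records=records, censor_day=day, censored=False,
            )


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

def _interval_cycle_days(lo: float, hi: float, cycle_days: float,
                         n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    """(cycle indices, day overlap) of [lo, hi) with the cycle grid."""
    hi = min(hi, n_cycles * cycle_days)
    if hi <= lo:
        return np.empty(0, int), np.empty(0)
    c0, c1 = int(lo // cycle_days), int(np.ceil(hi / cycle_days))
    c = np.arange(c0, c1)
    days = np.minimum(hi, (c + 1) * cycle_days) - np.maximum(lo, c * cycle_days)
    keep = days > 0
    return c[keep], days[keep]


def make_utility_fn(model: TwoPartUtilityModel):
    """Adapter: fitted two-part model -> utility_fn(profile, state, in_y1, arm)."""
    def fn(profile, state, in_first_year, arm):
        return predict_state_utility(model, profile, state, in_first_year, arm)
    return fn


def accrue_qalys(history: EventHistory, utility_fn, profile: dict,
                 settings: SimulationSettings,
                 arm: str | None = None) -> dict:
    """Discounted and undiscounted QALYs and life-years for one lifetime.

    Per-cycle accrual = state utility x fraction of cycle alive x discount
    factor; utilities are zero after death by construction (occupancy
    intervals end at death).
    """
    arm = arm or profile.get("arm")
    disc = settings.discount_factors()
    n = settings.n_cycles
    qaly_d = qaly_u = ly = 0.0
    y1_cut = DAYS_PER_YEAR
    for state, lo, hi in history.intervals(settings.horizon_days):
        c, days = _interval_cycle_days(lo, hi, settings.cycle_days, n)
        if len(c) == 0:
            continue
        in_y1 = (c * settings.cycle_days) < y1_cut
        u = np.where(
            in_y1,
            utility_fn(profile, state.name, True, arm),
            utility_fn(profile, state.name, False, arm),
        )
        frac_years = days / DAYS_PER_YEAR
        qaly_d += float((u * frac_years * disc[c]).sum())
        qaly_u += float((u * frac_years).sum())
        ly += float(frac_years.sum())
    return dict(qalys=qaly_d, qalys_undiscounted=qaly_u, life_years=ly)


def accrue_costs(history: EventHistory, cost_model: TwoPartCostModel | None,
                 med_table: SpecificMedCostTable | None,
                 unit_costs: UnitCostTable, profile: dict,
                 settings: SimulationSettings, arm: str | None = None,
                 sae_rate_per_cycle: float = 0.0,
                 end_of_life_all_deaths: bool = False) -> dict:
    """Discounted lifetime costs by category for one simulated lifetime.

    Per alive cycle: the general-management two-part prediction, the
    specific-medication state/band mean, the investigational (AAP) cost as
    treated-days x daily price, expected SAE cost and monitoring; plus
    end-of-life care once at death.  Also returns the discounted
    AAP-treated days, the exposure the price-threshold analysis needs.
    """
    arm = arm or profile.get("arm")
    disc = settings.discount_factors()
    n = settings.n_cycles
    prof = dict(profile) | {"arm": arm}
    out = dict(general=0.0, specific=0.0, investigational=0.0, addon=0.0)
    aap_days_disc = 0.0
    pred_daily = unit_costs.items["prednisolone"].gbp
    y1_cut = DAYS_PER_YEAR
    # per-(state, band, y1) caches: predictions are deterministic per profile
    gen_cache: dict = {}
    for state, lo, hi in history.intervals(settings.horizon_days):
        c, days = _interval_cycle_days(lo, hi, settings.cycle_days, n)
        if len(c) == 0:
            continue
        frac = days / settings.cycle_days
        dfac = disc[c]
        starts = c * settings.cycle_days
        years_in = np.clip(starts - lo, 0.0, None) / DAYS_PER_YEAR
        band_i = np.searchsorted([1.0, 2.0], years_in, side="right")
        in_y1 = starts < y1_cut
        for bi in np.unique(band_i):
            for y1 in (True, False):
                m = (band_i == bi) & (in_y1 == y1)
                if not m.any():
                    continue
                key = (state.name, bi, y1)
                if key not in gen_cache:
                    row = _cost_design_row(prof, y1)
                    band = BANDS[bi]
                    gen = (
                        cost_model.predict_mean(arm, state.name, row)
                        if cost_model is not None else 0.0
                    )
                    spec = (
                        med_table.specific_cost(state.name, band)
                        if med_table is not None else 0.0
                    )
                    aapd = (
                        med_table.aap_days_per_cycle(state.name, band, arm)
                        if med_table is not None else 0.0
                    )
                    gen_cache[key] = (gen, spec, aapd)
                gen, spec, aapd = gen_cache[key]
                w = float((frac[m] * dfac[m]).sum())
                out["general"] += gen * w
                out["specific"] += spec * w
                ad = aapd * w
                aap_days_disc += ad
                out["investigational"] += ad * (
                    unit_costs.abiraterone_daily + pred_daily
                )
                out["addon"] += (
                    unit_costs.monitoring_per_cycle
                    + sae_rate_per_cycle * unit_costs.sae_flat
                ) * w
    # end-of-life care, once, at the death cycle
    last_state, last_day = history.records[-1]
    eligible = (last_state is HealthState.HS8) or (
        end_of_life_all_deaths and last_state in DEAD_STATES
    )
    if eligible and last_day < settings.horizon_days:
        cyc = min(int(last_day // settings.cycle_days), n - 1)
        out["addon"] += unit_costs.end_of_life * float(disc[cyc])
    out["total"] = sum(out.values())
    out["aap_days_disc"] = aap_days_disc
    return out


# ---------------------------------------------------------------------------
# deterministic cohort run
# ---------------------------------------------------------------------------

def run_deterministic(profiles: pd.DataFrame, suite: ModelSuite,
                      utility_fn, cost_model: TwoPartCostModel | None,
                      med_table: SpecificMedCostTable | None,
                      unit_costs: UnitCostTable,
                      settings: SimulationSettings,
                      splice: MortalitySplice | None = None,
                      n_sims: int | None = None,
                      sae_rate_per_cycle: float = 0.0,
                      collect_lifetimes: bool = False
                      ) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Mean lifetime outcomes per arm x subgroup at point estimates.

    Every profile is simulated under **both** arms (counterfactual pairing)
    with ``n_sims`` replicate lifetimes each, then averaged within arm and
    baseline subgroup (M0 = HS1 baseline, M1 = HS2/HS3).
    """
    n_sims = n_sims or settings.n_sims_deterministic
    splice = splice or MortalitySplice()
    seeds = np.random.SeedSequence(settings.seed).spawn(len(profiles))
    rows = []
    for (idx, prof_row), ss in zip(profiles.iterrows(), seeds):
        base_prof = dict(prof_row)
        rng = np.random.default_rng(ss)
        for arm in ("AAP_SOC", "SOC"):
            prof = base_prof | {"arm": arm}
            acc: dict[str, float] = {}
            for _ in range(n_sims):
                h = simulate_patient(prof, suite, settings, rng, splice)
                q = accrue_qalys(h, utility_fn, prof, settings, arm)
                c = accrue_costs(h, cost_model, med_table, unit_costs, prof,
                                 settings, arm, sae_rate_per_cycle)
                ffs_day = h.records[1][1] if len(h.records) > 1 else h.end_day
                rep = q | {f"cost_{k}": v for k, v in c.items() if k != "aap_days_disc"}
                rep["aap_days_disc"] = c["aap_days_disc"]
                rep["ffs_years"] = min(ffs_day, settings.horizon_days) / DAYS_PER_YEAR
                for k, v in rep.items():
                    acc[k] = acc.get(k, 0.0) + v
            mean = {k: v / n_sims for k, v in acc.items()}
            rows.append(
                dict(patient_id=base_prof["patient_id"], arm=arm,
                     subgroup=base_prof["subgroup"]) | mean
            )
    lifetimes = pd.DataFrame(rows)
    value_cols = [c for c in lifetimes.columns
                  if c not in ("patient_id", "arm", "subgroup")]
    summary = (
        lifetimes.groupby(["subgroup", "arm"], as_index=False)[value_cols].mean()
    )
    if collect_lifetimes:
        return summary, lifetimes
    return summary
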