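"""Cost pipeline under the English NHS perspective (2017-18 GBP).

Resource-use records are costed in three trial categories — investigational
medications (abiraterone plus prednisolone), other specific expensive
medications (docetaxel, enzalutamide, cabazitaxel, radium), and general
disease management — on a 42-day cycle grid.  Missing doses are imputed by
fixed rules (abiraterone 1000 mg/day, prednisolone 5 mg/day with dates
copied from abiraterone, other drugs at the modal observed or listed
default dose).  Skewed general-management cycle costs are modelled in two
parts around a boundary (default £1,500/cycle): a generalised-gamma
regression below and a Gaussian regression above.  Specific-medication and
AAP costs are summarised per health state and time-in-state band (<1 year,
1-2 years, >2 years), AAP additionally by arm, with the AAP cell stored as
treated-days per cycle so that lifetime costs are exactly linear in the
abiraterone daily price.

The default unit-cost table ships with the package as documented defaults
and is fully overridable; the listed abiraterone price is £97.68/day with
roughly 20% reductions applied to enzalutamide, cabazitaxel and radium
list prices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate

from .states import CRPC_STATES, DEAD_STATES, EventHistory, HealthState
from .survival import TransitionModel, fit_parametric

CYCLE_DAYS = 42.0
DAYS_PER_YEAR = 365.25

BANDS = ("lt_1y", "y1_2", "gt_2y")

__all__ = [
    "UnitCostTable",
    "impute_doses",
    "cost_records",
    "build_general_cycle_table",
    "fit_two_part_cost",
    "TwoPartCostModel",
    "SpecificMedCostTable",
    "add_on_costs",
    "band_for",
    "CYCLE_DAYS",
]


def band_for(years_in_state: float) -> str:
    """Time-in-state band: <1 year, 1-2 years, >2 years."""
    if years_in_state < 1.0:
        return "lt_1y"
    if years_in_state < 2.0:
        return "y1_2"
    return "gt_2y"


@dataclass(frozen=True)
class ItemCost:
    category: str  # investigational | specific | general | sae
    gbp: float  # per day at the reference dose, or per event
    basis: str = "per_day"  # per_day | per_event
    reference_dose: float | None = None  # dose at which ``gbp`` applies
    default_dose: float | None = None  # listed dose for imputation
    note: str = ""


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs in 2017-18 GBP.  Package defaults are documented,
    plausible NHS-scale values and are fully overridable; the abiraterone
    daily price is the quantity varied in the threshold analysis."""

    items: dict = field(default_factory=lambda: dict(_DEFAULT_ITEMS))
    abiraterone_daily: float = 97.68
    end_of_life: float = 6897.0
    sae_flat: float = 1200.0
    monitoring_per_cycle: float = 120.0
    stop_cost: float = 50.0
    price_year: str = "2017-18"

    def with_abiraterone_price(self, gbp_per_day: float) -> "UnitCostTable":
        return replace(self, abiraterone_daily=float(gbp_per_day))

    def daily_cost(self, item: str, dose: float) -> float:
        """GBP/day for a dose-bearing medication record."""
        spec = self.items[item]
        base = self.abiraterone_daily if item == "abiraterone" else spec.gbp
        if spec.basis != "per_day":
            raise ValueError(f"{item} is costed per event, not per day")
        if spec.reference_dose and np.isfinite(dose):
            return base * float(dose) / spec.reference_dose
        return base

    def event_cost(self, item: str) -> float:
        spec = self.items[item]
        if spec.basis != "per_event":
            raise ValueError(f"{item} is costed per day, not per event")
        return spec.gbp


_DEFAULT_ITEMS = {
    "abiraterone": ItemCost("investigational", 97.68, "per_day", 1000.0, 1000.0,
                            "list price; overridden by abiraterone_daily"),
    "prednisolone": ItemCost("investigational", 0.02, "per_day", 5.0, 5.0),
    "docetaxel": ItemCost("specific", 52.0, "per_day", 1.0, 1.0,
                          "per day of course"),
    "enzalutamide": ItemCost("specific", 74.10, "per_day", 1.0, 1.0,
                             "~20% off list"),
    "cabazitaxel": ItemCost("specific", 141.0, "per_day", 1.0, 1.0,
                            "~20% off list"),
    "radium": ItemCost("specific", 115.0, "per_day", 1.0, 1.0, "~20% off list"),
    "adt": ItemCost("general", 4.2, "per_day", 1.0, 1.0,
                    "LHRH-agonist backbone, per day"),
    "gp_visit": ItemCost("general", 38.0, "per_event"),
    "outpatient_visit": ItemCost("general", 150.0, "per_event"),
    "inpatient_stay": ItemCost("general", 2500.0, "per_event"),
    "radiotherapy": ItemCost("general", 600.0, "per_event"),
    "sae": ItemCost("sae", 0.0, "per_event", note="costed via sae_flat"),
}


# ---------------------------------------------------------------------------
# dose imputation
# ---------------------------------------------------------------------------

def impute_doses(records: pd.DataFrame,
                 unit_costs: UnitCostTable | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing medication doses by the fixed imputation rules.

    abiraterone -> 1000 mg/day; prednisolone -> 5 mg/day with start/stop
    dates copied from the same patient's abiraterone record; other items ->
    modal observed dose in the dataset, else the listed default dose.
    Returns (completed records, imputation log).  Raises if an item has a
    missing dose but neither a modal observed dose nor a listed default.
    """
    unit_costs = unit_costs or UnitCostTable()
    out = records.copy().reset_index(drop=True)
    log = []
    aap_dates = (
        out[out["item"] == "abiraterone"]
        .groupby("patient_id")[["start_day", "stop_day"]]
        .first()
    )
    modal = {
        item: grp["dose"].mode().iloc[0]
        for item, grp in out.dropna(subset=["dose"]).groupby("item")
        if len(grp)
    }
    for i in out.index[out["dose"].isna()]:
        row = out.loc[i]
        item = row["item"]
        if item == "abiraterone":
            dose, rule = 1000.0, "indicated/modal 1000mg/day"
        elif item == "prednisolone":
            dose, rule = 5.0, "protocol 5mg/day, dates from abiraterone"
            if row["patient_id"] in aap_dates.index:
                out.loc[i, ["start_day", "stop_day"]] = aap_dates.loc[
                    row["patient_id"]
                ].to_numpy()
        elif item in modal:
            dose, rule = float(modal[item]), "modal observed dose"
        else:
            spec = unit_costs.items.get(item)
            if spec is None or spec.default_dose is None:
                raise ValueError(
                    f"cannot impute dose for {item!r}: no modal observed dose "
                    "and no listed default"
                )
            dose, rule = float(spec.default_dose), "listed default dose"
        out.loc[i, "dose"] = dose
        log.append(dict(patient_id=row["patient_id"], item=item,
                        imputed_dose=dose, rule=rule))
    return out, pd.DataFrame(log, columns=["patient_id", "item", "imputed_dose", "rule"])


# ---------------------------------------------------------------------------
# cycle costing
# ---------------------------------------------------------------------------

def _cycle_overlaps(start: float, stop: float) -> list[tuple[int, float]]:
    """Day overlap of the half-open interval [start, stop) with each 42-day
    cycle it touches: [(cycle_index, days), ...]."""
    if stop <= start:
        return []
    first = int(start // CYCLE_DAYS)
    last = int(np.ceil(stop / CYCLE_DAYS))
    out = []
    for c in range(first, last):
        lo, hi = c * CYCLE_DAYS, (c + 1) * CYCLE_DAYS
        days = min(stop, hi) - max(start, lo)
        if days > 0:
            out.append((c, days))
    return out


def cost_records(records: pd.DataFrame, unit_costs: UnitCostTable,
                 histories: list[EventHistory]) -> pd.DataFrame:
    """Cost every record onto the 42-day cycle grid.

    Daily-costed items accrue daily cost x day-overlap per cycle; per-event
    items charge once in the cycle containing the event.  Records extending
    past the patient's alive interval are truncated with a warning.
    Returns columns patient_id, cycle_index, category, amount.
    """
    ends = {h.patient_id: h.end_day for h in histories}
    rows = []
    n_trunc = 0
    for r in records.itertuples(index=False):
        end = ends.get(str(r.patient_id), np.inf)
        start, stop = float(r.start_day), float(r.stop_day)
        if stop > end:
            n_trunc += 1
            stop = end
        if stop <= start:
            continue
        spec = unit_costs.items[r.item]
        if spec.basis == "per_day":
            daily = unit_costs.daily_cost(r.item, float(r.dose))
            for c, days in _cycle_overlaps(start, stop):
                rows.append((str(r.patient_id), c, spec.category, daily * days))
        else:
            gbp = unit_costs.sae_flat if r.item == "sae" else unit_costs.event_cost(r.item)
            rows.append((str(r.patient_id), int(start // CYCLE_DAYS),
                         spec.category, gbp))
    if n_trunc:
        warnings.warn(f"{n_trunc} records extended past the alive interval and "
                      "were truncated")
    df = pd.DataFrame(rows, columns=["patient_id", "cycle_index", "category", "amount"])
    return (
        df.groupby(["patient_id", "cycle_index", "category"], as_index=False)["amount"]
        .sum()
    )


# ---------------------------------------------------------------------------
# per-cycle analysis tables
# ---------------------------------------------------------------------------

_COST_COVARIATES = ["age_60_69", "age_70plus", "who_1_2", "nodal_pos",
                    "ty_aap_y1", "ty_soc_y1"]


def _cost_design_row(profile: dict, in_first_year: bool) -> dict:
    arm = profile.get("arm")
    return {
        "age_60_69": 1.0 if profile.get("age_group") == "60-69" else 0.0,
        "age_70plus": 1.0 if profile.get("age_group") == ">=70" else 0.0,
        "who_1_2": 1.0 if profile.get("who_status") == "1-2" else 0.0,
        "nodal_pos": 1.0 if profile.get("nodal_stage") == "N+" else 0.0,
        "ty_aap_y1": 1.0 if (in_first_year and arm == "AAP_SOC") else 0.0,
        "ty_soc_y1": 1.0 if (in_first_year and arm == "SOC") else 0.0,
    }


def _cycle_state_rows(history: EventHistory) -> list[dict]:
    """Majority state and years-in-state at cycle start for each alive cycle."""
    out = []
    n_cycles = int(np.ceil(history.end_day / CYCLE_DAYS))
    ivals = history.intervals()
    for c in range(max(n_cycles, 0)):
        lo, hi = c * CYCLE_DAYS, (c + 1) * CYCLE_DAYS
        best, best_days, entry = None, 0.0, 0.0
        for state, a, b in ivals:
            days = min(hi, b) - max(lo, a)
            if days > best_days:
                best, best_days, entry = state, days, a
        if best is None:
            continue
        out.append(dict(cycle_index=c, state=best.name,
                        years_in_state=max(lo - entry, 0.0) / DAYS_PER_YEAR))
    return out


def build_general_cycle_table(cycle_costs: pd.DataFrame,
                              histories: list[EventHistory],
                              profiles: pd.DataFrame) -> pd.DataFrame:
    """One row per patient x alive cycle with the general-management amount
    (0 if none recorded), occupied state, band, and model covariates."""
    gen = (
        cycle_costs[cycle_costs.category == "general"]
        .set_index(["patient_id", "cycle_index"])["amount"]
    )
    pmap = {str(r["patient_id"]): dict(r) for _, r in profiles.iterrows()}
    rows = []
    for h in histories:
        prof = pmap[h.patient_id]
        for cyc in _cycle_state_rows(h):
            c = cyc["cycle_index"]
            in_y1 = c * CYCLE_DAYS < DAYS_PER_YEAR
            rows.append(
                dict(
                    patient_id=h.patient_id,
                    cycle_index=c,
                    arm=prof["arm"],
                    state=cyc["state"],
                    band=band_for(cyc["years_in_state"]),
                    amount=float(gen.get((h.patient_id, c), 0.0)),
                )
                | _cost_design_row(prof, in_y1)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-part boundary cost model
# ---------------------------------------------------------------------------

@dataclass
class _CostStratum:
    p_params: np.ndarray  # logit for P(amount > boundary)
    p_vcov: np.ndarray
    lower: TransitionModel | None  # generalised gamma on (0, boundary]
    lower_mean_const: float  # E[c]/exp(mu) for the fitted shape parameters
    upper_params: np.ndarray | None  # Gaussian (OLS) above the boundary
    upper_vcov: np.ndarray | None
    pooled: bool = False


@dataclass
class TwoPartCostModel:
    """Boundary-split two-part model for general-management cycle costs.

    Stratified by arm x health state; within each stratum a logit gives
    P(cost > boundary), a generalised-gamma regression models the lower
    costs and a Gaussian regression the higher costs.  The predicted mean
    is P(<=b) E[c | <=b] + P(>b) E[c | >b], with the upper mean floored at
    the boundary.
    """

    boundary: float
    covariates: list[str]
    strata: dict  # (arm, state) -> _CostStratum
    qic: float = np.nan

    def _xrow(self, row: dict) -> np.ndarray:
        return np.r_[1.0, [float(row.get(c, 0.0)) for c in self.covariates]]

    def _stratum(self, arm: str, state: str) -> "_CostStratum":
        key = (arm, state)
        if key not in self.strata:
            key = ("__pooled__", "__pooled__")
        return self.strata[key]

    def predict_mean(self, arm: str, state: str, row: dict | None = None) -> float:
        row = row or {}
        st = self._stratum(arm, state)
        x = self._xrow(row)
        p_hi = float(1.0 / (1.0 + np.exp(-(x @ st.p_params))))
        if st.lower is None:
            mean_lo = 0.0
        else:
            eta = st.lower._eta({c: row.get(c, 0.0) for c in st.lower.covariates})
            mean_lo = float(min(np.exp(eta) * st.lower_mean_const, self.boundary))
        if st.upper_params is None:
            p_hi = 0.0
            mean_hi = self.boundary
        else:
            mean_hi = float(max(x @ st.upper_params, self.boundary))
        return (1.0 - p_hi) * mean_lo + p_hi * mean_hi

    def draw(self, rng: np.random.Generator) -> "TwoPartCostModel":
        """Multivariate-normal parameter draw of every stratum (for PSA)."""
        new = {}
        for key, st in self.strata.items():
            p = rng.multivariate_normal(st.p_params, _psd(st.p_vcov))
            lower = st.lower
            if lower is not None:
                lp = rng.multivariate_normal(lower.params, _psd(lower.vcov))
                lower = replace_params(lower, lp)
            up, uv = st.upper_params, st.upper_vcov
            if up is not None:
                up = rng.multivariate_normal(up, _psd(uv))
            new[key] = _CostStratum(p, st.p_vcov, lower,
                                    _gg_mean_const(lower) if lower else 0.0,
                                    up, uv, st.pooled)
        return TwoPartCostModel(self.boundary, list(self.covariates), new, self.qic)


def replace_params(model: TransitionModel, params: np.ndarray) -> TransitionModel:
    from dataclasses import replace as dc_replace
    return dc_replace(model, params=np.asarray(params, float))


def _psd(v: np.ndarray) -> np.ndarray:
    """Nearest-PSD repair (eigenvalue clipping) with a warning if needed."""
    v = np.asarray(v, float)
    if not np.all(np.isfinite(v)):
        warnings.warn("covariance contains non-finite entries; zeroing them")
        v = np.where(np.isfinite(v), v, 0.0)
    v = 0.5 * (v + v.T)
    try:
        w, q = np.linalg.eigh(v)
    except np.linalg.LinAlgError:
        warnings.warn("covariance eigendecomposition failed; using diagonal")
        d = np.clip(np.diag(v), 0.0, None)
        return np.diag(d)
    if w.min() < -1e-10:
        warnings.warn("covariance not positive semi-definite; clipping eigenvalues")
    w = np.clip(w, 0.0, None)
    return (q * w) @ q.T


def _gg_mean_const(model: TransitionModel) -> float:
    """E[c] / exp(mu) for a fitted log-location family (numeric integral of
    the survival function at mu = 0)."""
    base = replace_params(model, model.params)
    shapes, _, _ = base._split()
    zero_loc = base.params.copy()
    nshape = len(shapes)
    zero_loc[nshape] = 0.0
    zero_loc[nshape + 1:] = 0.0
    val, _ = integrate.quad(
        lambda t: float(np.exp(base.log_sf(t, {}, params=zero_loc))),
        0.0, np.inf, limit=200,
    )
    return float(val)


def fit_two_part_cost(general_cycles: pd.DataFrame, boundary: float = 1500.0,
                      covariates: list[str] | None = None,
                      by: tuple[str, ...] = ("arm", "state"),
                      min_stratum: int = 60) -> TwoPartCostModel:
    """Fit the boundary-split two-part cost model.

    ``general_cycles`` comes from :func:`build_general_cycle_table`.
    Strata with fewer than ``min_stratum`` cycles fall back to a pooled
    stratum with a warning.  Zero-cost cycles enter the lower part at a £1
    floor (the generalised gamma needs positive support).
    """
    covariates = list(covariates or _COST_COVARIATES)
    df = general_cycles.copy()
    if not (df["amount"] > boundary).any():
        # degenerate but legal: everything below the boundary
        pass

    def fit_stratum(sub: pd.DataFrame) -> _CostStratum:
        hi = (sub["amount"] > boundary).astype(float)
        X = sm.add_constant(sub[covariates].to_numpy(float), has_constant="add")
        if hi.sum() == 0 or hi.sum() == len(hi):
            p_params = np.r_[np.sign(hi.mean() - 0.5) * 30.0, np.zeros(len(covariates))]
            p_vcov = np.zeros((len(covariates) + 1,) * 2)
        else:
            try:
                res = sm.GLM(hi.to_numpy(), X, family=sm.families.Binomial()).fit()
                p_params, p_vcov = np.asarray(res.params), np.asarray(res.cov_params())
            except Exception:
                p = hi.mean()
                p_params = np.r_[np.log(p / (1 - p)), np.zeros(len(covariates))]
                p_vcov = np.zeros((len(covariates) + 1,) * 2)
        low = sub[sub["amount"] <= boundary]
        lower = None
        mean_const = 0.0
        if len(low):
            ds = low[covariates].copy()
            ds["time"] = low["amount"].clip(lower=1.0).to_numpy()
            ds["event"] = 1
            lower = fit_parametric(ds, "generalized_gamma", covariates)
            mean_const = _gg_mean_const(lower)
        up = sub[sub["amount"] > boundary]
        upper_params = upper_vcov = None
        if len(up) >= 3:
            Xu = sm.add_constant(up[covariates].to_numpy(float), has_constant="add")
            res = sm.OLS(up["amount"].to_numpy(), Xu).fit()
            upper_params, upper_vcov = np.asarray(res.params), np.asarray(res.cov_params())
        elif len(up):
            upper_params = np.r_[up["amount"].mean(), np.zeros(len(covariates))]
            upper_vcov = np.zeros((len(covariates) + 1,) * 2)
        return _CostStratum(p_params, p_vcov, lower, mean_const,
                            upper_params, upper_vcov)

    strata: dict = {}
    small = []
    for key, sub in df.groupby(list(by)):
        key = tuple(key) if isinstance(key, tuple) else (key,)
        if len(sub) >= min_stratum and sub["amount"].gt(0).sum() >= 10:
            strata[key] = fit_stratum(sub)
        else:
            small.append(key)
    strata[("__pooled__", "__pooled__")] = fit_stratum(df)
    if small:
        warnings.warn(f"strata {small} too small; using pooled fallback")
    return TwoPartCostModel(boundary=boundary, covariates=covariates, strata=strata)


# ---------------------------------------------------------------------------
# specific-medication / AAP state-band cost table
# ---------------------------------------------------------------------------

@dataclass
class SpecificMedCostTable:
    """Empirical mean cycle costs by state and time-in-state band.

    ``specific``: (state, band) -> GBP per cycle for the expensive
    non-investigational medications.  ``aap_days``: (state, band, arm) ->
    mean abiraterone-treated days per cycle, so the investigational cost of
    a cycle is aap_days x (daily abiraterone + prednisolone price) — exactly
    linear in the abiraterone price.
    """

    specific: dict
    aap_days: dict
    states_seen: set

    @classmethod
    def build(cls, cycle_costs: pd.DataFrame, records: pd.DataFrame,
              histories: list[EventHistory], profiles: pd.DataFrame,
              unit_costs: UnitCostTable) -> "SpecificMedCostTable":
        arm_of = dict(zip(profiles.patient_id.astype(str), profiles.arm))
        spec_amt = (
            cycle_costs[cycle_costs.category == "specific"]
            .set_index(["patient_id", "cycle_index"])["amount"]
        )
        # abiraterone-treated days per (patient, cycle)
        aap = records[records["item"] == "abiraterone"]
        aap_days_pc: dict[tuple[str, int], float] = {}
        for r in aap.itertuples(index=False):
            for c, days in _cycle_overlaps(float(r.start_day), float(r.stop_day)):
                key = (str(r.patient_id), c)
                aap_days_pc[key] = aap_days_pc.get(key, 0.0) + days
        spec_cells: dict[tuple, list] = {}
        aap_cells: dict[tuple, list] = {}
        states_seen = set()
        for h in histories:
            arm = arm_of[h.patient_id]
            for cyc in _cycle_state_rows(h):
                c, state = cyc["cycle_index"], cyc["state"]
                band = band_for(cyc["years_in_state"])
                states_seen.add(state)
                spec_cells.setdefault((state, band), []).append(
                    float(spec_amt.get((h.patient_id, c), 0.0))
                )
                aap_cells.setdefault((state, band, arm), []).append(
                    aap_days_pc.get((h.patient_id, c), 0.0)
                )
        return cls(
            specific={k: float(np.mean(v)) for k, v in spec_cells.items()},
            aap_days={k: float(np.mean(v)) for k, v in aap_cells.items()},
            states_seen=states_seen,
        )

    def _borrow(self, table: dict, key: tuple, band_pos: int):
        if key in table:
            return table[key]
        band_i = BANDS.index(key[band_pos])
        for b in range(band_i - 1, -1, -1):
            k2 = key[:band_pos] + (BANDS[b],) + key[band_pos + 1:]
            if k2 in table:
                warnings.warn(f"cell {key} empty; borrowing earlier band {k2}")
                return table[k2]
        return None

    def specific_cost(self, state: str, band: str) -> float:
        """Mean specific-medication GBP per cycle for (state, band)."""
        if state not in self.states_seen:
            warnings.warn(f"state {state} never visited in costing data; cost 0")
            return 0.0
        val = self._borrow(self.specific, (state, band), 1)
        return 0.0 if val is None else val

    def aap_days_per_cycle(self, state: str, band: str, arm: str) -> float:
        if state not in self.states_seen:
            return 0.0
        val = self._borrow(self.aap_days, (state, band, arm), 1)
        return 0.0 if val is None else val

    def gamma_draw(self, rng: np.random.Generator, cv: float = 0.2
                   ) -> "SpecificMedCostTable":
        """Gamma-perturbed copy of the cost cells (for PSA), keeping means and
        applying the given coefficient of variation."""
        def perturb(table):
            if cv <= 0:
                return dict(table)
            out = {}
            for k, v in table.items():
                if v <= 0:
                    out[k] = v
                    continue
                shape = 1.0 / cv**2
                out[k] = float(rng.gamma(shape, v / shape))
            return out
        return SpecificMedCostTable(perturb(self.specific), perturb(self.aap_days),
                                    set(self.states_seen))


# ---------------------------------------------------------------------------
# add-on costs
# ---------------------------------------------------------------------------

def add_on_costs(history: EventHistory, unit_costs: UnitCostTable,
                 sae_count: int = 0, n_med_stops: int = 0,
                 end_of_life_all_deaths: bool = False) -> pd.DataFrame:
    """One-off and per-cycle extras for one observed/simulated lifetime.

    End-of-life care (£6,897 default) is charged once at death — to
    prostate-cancer deaths by default, optionally to all deaths; SAEs carry
    a flat cost each; monitoring accrues per alive cycle; medication stops
    carry a small resource cost.
    """
    rows = []
    last_state, last_day = history.records[-1]
    death_cycle = int(last_day // CYCLE_DAYS)
    eligible = (last_state is HealthState.HS8) or (
        end_of_life_all_deaths and last_state in DEAD_STATES
    )
    if eligible:
        rows.append(dict(cycle_index=death_cycle, item="end_of_life",
                         amount=unit_costs.end_of_life))
    for _ in range(sae_count):
        rows.append(dict(cycle_index=0, item="sae", amount=unit_costs.sae_flat))
    n_cycles = int(np.ceil(history.end_day / CYCLE_DAYS))
    for c in range(n_cycles):
        rows.append(dict(cycle_index=c, item="monitoring",
                         amount=unit_costs.monitoring_per_cycle))
    for _ in range(n_med_stops):
        rows.append(dict(cycle_index=0, item="med_stop", amount=unit_costs.stop_cost))
    return pd.DataFrame(rows, columns=["cycle_index", "item", "amount"])
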