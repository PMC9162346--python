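"""Synthetic trial-like cohort generator with known ground truth.

Emulates patient-level data from a two-arm randomised comparison of adding
abiraterone acetate plus prednisolone (AAP) to standard-of-care long-term
hormone therapy (SOC): baseline covariates, multistate event histories over
the nine-state disease model, EQ-5D-3L questionnaire panels on the protocol
visit schedule (with configurable missingness), and dated resource-use
records (medications with doses, visits, procedures, serious adverse
events).  Every stochastic quantity is driven by an explicit ground-truth
configuration, so downstream fitting stages can be validated by parameter
recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .states import (
    CRPC_STATES,
    DEAD_STATES,
    NAIVE_STATES,
    TRANSITIONS,
    EventHistory,
    HealthState,
)
from .tariff import DIMENSIONS, TariffTable

DAYS_PER_YEAR = 365.25

__all__ = [
    "HazardSpec",
    "GroundTruthConfig",
    "VisitSchedule",
    "Cohort",
    "generate_cohort",
    "sample_event_history",
    "generate_eq5d_panel",
    "generate_resource_use",
    "default_transition_hazards",
]


class ConfigError(ValueError):
    """Invalid ground-truth configuration; message names the offending field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardSpec:
    """Ground-truth hazard for one transition.

    ``rate`` is the baseline hazard per year (exponential) or implied by
    (shape, scale_years) for a Weibull with proportional-hazards covariate
    effects.  ``arm_lhr`` is the log hazard ratio for the AAP arm;
    ``age_lhr`` maps age-group labels to log hazard ratios.
    """

    family: str = "exponential"  # exponential | weibull
    rate: float = 0.0  # per year (exponential)
    shape: float = 1.0  # weibull shape
    scale_years: float = 1.0  # weibull scale
    arm_lhr: float = 0.0
    age_lhr: dict = field(default_factory=dict)

    def lhr(self, arm: str, age_group: str) -> float:
        out = self.arm_lhr if arm == "AAP_SOC" else 0.0
        out += self.age_lhr.get(age_group, 0.0)
        return out

    def sample_years(self, rng: np.random.Generator, lhr: float) -> float:
        """Draw an event time (years) under the proportional-hazards spec."""
        if self.family == "exponential":
            lam = self.rate * np.exp(lhr)
            if lam <= 0:
                return np.inf
            return rng.exponential(1.0 / lam)
        if self.family == "weibull":
            e = rng.exponential(1.0)
            return self.scale_years * (e / np.exp(lhr)) ** (1.0 / self.shape)
        raise ConfigError(f"transition_hazards: unknown family {self.family!r}")


def default_transition_hazards() -> dict[str, HazardSpec]:
    """Per-year baseline hazards for the 25 transitions (SOC arm).

    First-event (naive-exit) rates are split across destinations roughly in
    proportion to observed transition usage, with totals giving median
    failure-free survival of several years for non-metastatic patients and
    around 2.5 years for metastatic patients; the AAP arm hazard ratio on
    naive exits is exp(-0.9) ~ 0.41, matching the large failure-free
    survival benefit this class of trial reports.  Post-CRPC rates give
    post-progression survival of roughly 1.5-3 years.
    """
    aap = -0.9  # log HR on first-event transitions
    aap_post = -0.2  # milder effect after castration resistance
    age = {"<60": -0.5, "60-69": 0.0, ">=70": 0.6}
    h = {
        # naive exits (joint first-event group)
        "HS1->HS4": HazardSpec(rate=0.089, arm_lhr=aap),
        "HS1->HS5": HazardSpec(rate=0.0065, arm_lhr=aap),
        "HS1->HS7": HazardSpec(rate=0.0032, arm_lhr=aap),
        "HS1->HS8": HazardSpec(rate=0.0018, arm_lhr=aap),
        "HS2->HS5": HazardSpec(rate=0.252, arm_lhr=aap),
        "HS2->HS7": HazardSpec(rate=0.0075, arm_lhr=aap),
        "HS2->HS8": HazardSpec(rate=0.0, arm_lhr=aap),
        "HS3->HS7": HazardSpec(rate=0.28, arm_lhr=aap),
        "HS3->HS8": HazardSpec(rate=0.02, arm_lhr=aap),
        # CRPC progression
        "HS4->HS5": HazardSpec(rate=0.15, arm_lhr=aap_post),
        "HS4->HS7": HazardSpec(rate=0.06, arm_lhr=aap_post),
        "HS5->HS6": HazardSpec(rate=0.25, arm_lhr=aap_post),
        "HS5->HS7": HazardSpec(rate=0.08, arm_lhr=aap_post),
        "HS6->HS7": HazardSpec(rate=0.02, arm_lhr=aap_post),
        # prostate-cancer death from CRPC
        "HS4->HS8": HazardSpec(rate=0.06, arm_lhr=aap_post),
        "HS5->HS8": HazardSpec(rate=0.30, arm_lhr=aap_post),
        "HS6->HS8": HazardSpec(rate=0.55, arm_lhr=aap_post),
        "HS7->HS8": HazardSpec(rate=0.70, arm_lhr=aap_post),
    }
    # other-cause death from every alive state, age-dependent
    for s in sorted(NAIVE_STATES | CRPC_STATES):
        h[f"{s.name}->HS9"] = HazardSpec(rate=0.015, age_lhr=dict(age))
    return h


@dataclass(frozen=True)
class UtilityTruth:
    """Per-state full-health probability and mean disutility when not full.

    Mean state utility is p_full + (1 - p_full) * (1 - mean_disutility).
    ``aap_first_year_disutility`` is an extra mean disutility applied to the
    AAP arm in the first year after randomisation (transient toxicity),
    implementing a first-year-only arm effect on quality of life.
    """

    p_full: dict = field(
        default_factory=lambda: {
            "HS1": 0.33, "HS2": 0.28, "HS3": 0.26,
            "HS4": 0.20, "HS5": 0.15, "HS6": 0.12, "HS7": 0.12,
        }
    )
    mean_disutility: dict = field(
        default_factory=lambda: {
            "HS1": 0.31, "HS2": 0.32, "HS3": 0.33,
            "HS4": 0.36, "HS5": 0.40, "HS6": 0.42, "HS7": 0.42,
        }
    )
    disutility_shape: float = 4.0  # gamma shape of the disutility draw
    aap_first_year_disutility: float = 0.02

    def state_mean(self, state: str) -> float:
        p = self.p_full[state]
        return p + (1.0 - p) * (1.0 - self.mean_disutility[state])


@dataclass(frozen=True)
class CostTruth:
    """Ground truth for resource-use generation (rates per year unless noted)."""

    outpatient_rate: dict = field(
        default_factory=lambda: {"naive": 6.0, "crpc": 12.0}
    )
    gp_rate: dict = field(default_factory=lambda: {"naive": 8.0, "crpc": 10.0})
    inpatient_rate: dict = field(
        default_factory=lambda: {"naive": 0.08, "crpc": 0.45}
    )
    radiotherapy_rate: dict = field(
        default_factory=lambda: {"naive": 0.05, "crpc": 0.25}
    )
    sae_rate: float = 0.10
    # probability a CRPC episode starts a specific (expensive) medication
    specific_med_prob: dict = field(
        default_factory=lambda: {"docetaxel": 0.25, "enzalutamide": 0.20}
    )
    specific_med_duration_days: float = 126.0
    soc_late_aap_fraction: float = 0.126  # SOC-arm patients receiving AAP later


@dataclass(frozen=True)
class Missingness:
    """Questionnaire and dose missingness.

    Default mechanism is missing-at-random given arm, disease phase and time
    (logistic model); set ``mechanism='mcar'`` to use the base rate alone.
    """

    p_missing_questionnaire: float = 0.10
    p_partial_questionnaire: float = 0.05
    p_missing_dose: float = 0.05
    mechanism: str = "mar"  # mar | mcar
    mar_crpc_lor: float = 0.8  # log-odds shift once castration-resistant
    mar_late_lor: float = 0.4  # log-odds shift for visits after 2 years
    mar_soc_lor: float = 0.2  # log-odds shift in the SOC-only arm


@dataclass(frozen=True)
class GroundTruthConfig:
    n_patients: int = 1000
    allocation_ratio: float = 0.5  # P(AAP_SOC), 1:1 default
    seed: int = 0
    follow_up_days: float = 5 * DAYS_PER_YEAR  # administrative censoring
    baseline_state_probs: dict = field(
        default_factory=lambda: {"HS1": 0.48, "HS2": 0.44, "HS3": 0.08}
    )
    age_group_probs: dict = field(
        default_factory=lambda: {"<60": 0.25, "60-69": 0.45, ">=70": 0.30}
    )
    who_status_probs: dict = field(default_factory=lambda: {"0": 0.77, "1-2": 0.23})
    nodal_stage_probs: dict = field(
        default_factory=lambda: {"N0": 0.52, "N+": 0.38, "NX": 0.10}
    )
    p_england: float = 0.88
    p_era_post2013: float = 0.35
    transition_hazards: dict = field(default_factory=default_transition_hazards)
    utility_truth: UtilityTruth = field(default_factory=UtilityTruth)
    cost_truth: CostTruth = field(default_factory=CostTruth)
    missingness: Missingness = field(default_factory=Missingness)

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients: must be >= 2")
        if not 0.0 < self.allocation_ratio < 1.0:
            raise ConfigError("allocation_ratio: must be in (0, 1)")
        if self.follow_up_days < 0:
            raise ConfigError("follow_up_days: must be non-negative")
        for name in (
            "baseline_state_probs",
            "age_group_probs",
            "who_status_probs",
            "nodal_stage_probs",
        ):
            table = getattr(self, name)
            vals = np.asarray(list(table.values()), float)
            if (vals < 0).any() or (vals > 1).any():
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities must sum to 1")
        if set(self.baseline_state_probs) != {"HS1", "HS2", "HS3"}:
            raise ConfigError("baseline_state_probs: states must be HS1/HS2/HS3")
        for p in (self.p_england, self.p_era_post2013):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("p_england/p_era_post2013: must lie in [0, 1]")
        for key, spec in self.transition_hazards.items():
            src, dst = key.split("->")
            pair = (HealthState[src], HealthState[dst])
            if not TRANSITIONS.is_allowed(*pair):
                raise ConfigError(f"transition_hazards: {key} is not an allowed transition")
            if spec.rate < 0 or spec.shape <= 0 or spec.scale_years <= 0:
                raise ConfigError(f"transition_hazards[{key}]: parameters must be positive")
        m = self.missingness
        for f in ("p_missing_questionnaire", "p_partial_questionnaire", "p_missing_dose"):
            if not 0.0 <= getattr(m, f) <= 1.0:
                raise ConfigError(f"missingness.{f}: must lie in [0, 1]")
        if m.mechanism not in ("mar", "mcar"):
            raise ConfigError("missingness.mechanism: must be 'mar' or 'mcar'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_hazards"] = {k: asdict(v) for k, v in self.transition_hazards.items()}
        return d


# ---------------------------------------------------------------------------
# visit schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitSchedule:
    """Protocol questionnaire grid, in days since randomisation.

    Every 6 weeks to 6 months, every 12 weeks to 2 years, every 6 months to
    5 years.  The grid is laid out in whole weeks (42/84/182-day steps from
    day 0), so "6 months" lands on day 168, "2 years" on day 756, and the
    last 6-monthly visit inside 5 years on day 1666 — the closest
    whole-visit days to the calendar anchors.
    """

    visit_times: tuple[float, ...]

    @classmethod
    def protocol(cls) -> "VisitSchedule":
        days = list(range(0, 169, 42))  # 0 .. 168 every 6 weeks
        days += list(range(252, 757, 84))  # to 2 years every 12 weeks
        days += list(range(938, 1821, 182))  # to 5 years every 6 months
        return cls(visit_times=tuple(float(d) for d in days))


# ---------------------------------------------------------------------------
# event-history sampling
# ---------------------------------------------------------------------------

def sample_event_history(
    profile: dict,
    hazards: dict[str, HazardSpec],
    follow_up: float,
    rng: np.random.Generator,
) -> EventHistory:
    """Competing-risks sampling of one patient's multistate trajectory.

    From the current state, a latent time is drawn for every allowed exit
    transition with a configured hazard; the minimum wins and the patient
    moves, repeating until an absorbing state or administrative censoring at
    ``follow_up`` days.
    """
    state = HealthState[profile["baseline_state"]]
    if state not in NAIVE_STATES:
        raise ConfigError("baseline_state: must be a naive state (HS1-HS3)")
    day = 0.0
    records: list[tuple[HealthState, float]] = [(state, 0.0)]
    arm, age = profile["arm"], profile["age_group"]
    while state not in DEAD_STATES and day < follow_up:
        best_t, best_dst = np.inf, None
        for dst in TRANSITIONS.exits(state):
            spec = hazards.get(f"{state.name}->{dst.name}")
            if spec is None:
                continue
            t = spec.sample_years(rng, spec.lhr(arm, age)) * DAYS_PER_YEAR
            if t < best_t:
                best_t, best_dst = t, dst
        if best_dst is None or day + best_t >= follow_up:
            break
        day += best_t
        state = best_dst
        records.append((state, day))
    censored = state not in DEAD_STATES
    return EventHistory(
        patient_id=str(profile["patient_id"]),
        records=records,
        censor_day=day if not censored else float(follow_up),
        censored=censored,
    )


# ---------------------------------------------------------------------------
# EQ-5D panel
# ---------------------------------------------------------------------------

def _tariff_lookup(tariff: TariffTable) -> tuple[np.ndarray, np.ndarray]:
    df = tariff.all_states().sort_values("utility").reset_index(drop=True)
    profiles = df[list(DIMENSIONS)].to_numpy()
    return profiles, df["utility"].to_numpy()


def generate_eq5d_panel(
    history: EventHistory,
    schedule: VisitSchedule,
    utility_truth: UtilityTruth,
    missingness: Missingness,
    rng: np.random.Generator,
    arm: str = "SOC",
    tariff: TariffTable | None = None,
) -> pd.DataFrame:
    """EQ-5D-3L responses on the visit grid while the patient is alive.

    A latent utility is drawn per visit from the state's ground truth (point
    mass at 1 with probability p_full, else 1 minus a gamma disutility) and
    converted to the nearest response profile under the tariff.  Whole
    questionnaires go missing at the configured (MAR or MCAR) rate; partial
    questionnaires blank one random dimension.
    """
    tariff = tariff or TariffTable.uk_default()
    profiles, values = _tariff_lookup(tariff)
    death = history.death_day
    rows = []
    for day in schedule.visit_times:
        if death is not None and day > death:
            break  # no responses after death
        if day > history.end_day:
            break
        state = history.state_at(day)
        if state in DEAD_STATES:
            break
        # whole-questionnaire missingness
        p_miss = missingness.p_missing_questionnaire
        if missingness.mechanism == "mar" and 0.0 < p_miss < 1.0:
            logit = np.log(p_miss / (1.0 - p_miss))
            if state in CRPC_STATES:
                logit += missingness.mar_crpc_lor
            if day > 2 * DAYS_PER_YEAR:
                logit += missingness.mar_late_lor
            if arm == "SOC":
                logit += missingness.mar_soc_lor
            p_miss = 1.0 / (1.0 + np.exp(-logit))
        if rng.random() < p_miss:
            continue
        # latent utility -> nearest tariff profile
        truth = utility_truth
        extra = (
            truth.aap_first_year_disutility
            if (arm == "AAP_SOC" and day < DAYS_PER_YEAR)
            else 0.0
        )
        if rng.random() < truth.p_full[state.name] and extra == 0.0:
            levels = np.ones(5, dtype=int)
        else:
            mean_d = truth.mean_disutility[state.name] + extra
            shape = truth.disutility_shape
            d = rng.gamma(shape, mean_d / shape)
            u = float(np.clip(1.0 - d, tariff.min_value, 1.0 - 1e-6))
            idx = int(np.searchsorted(values, u))
            idx = min(idx, len(values) - 1)
            if idx > 0 and abs(values[idx - 1] - u) < abs(values[idx] - u):
                idx -= 1
            levels = profiles[idx].copy()
        resp = {d: float(l) for d, l in zip(DIMENSIONS, levels)}
        if rng.random() < missingness.p_partial_questionnaire:
            resp[DIMENSIONS[rng.integers(5)]] = np.nan
        rows.append(dict(patient_id=history.patient_id, visit_day=day) | resp)
    cols = ["patient_id", "visit_day", *DIMENSIONS]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# resource use
# ---------------------------------------------------------------------------

def _first_crpc_entry(history: EventHistory) -> float | None:
    for s, d in history.records:
        if s in CRPC_STATES:
            return d
    return None


def _failure_day(history: EventHistory) -> float | None:
    """Day of first exit from the naive state (any destination incl. death)."""
    if len(history.records) > 1:
        return history.records[1][1]
    return None


def generate_resource_use(
    history: EventHistory,
    profile: dict,
    cost_truth: CostTruth,
    missingness: Missingness,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Medication / procedure / visit / SAE records for one patient.

    AAP-arm abiraterone (with prednisolone) starts at randomisation and
    stops at treatment failure (metastatic baseline) or at min(failure,
    2 years) (non-metastatic baseline).  A configurable fraction of SOC-arm
    patients start AAP at castration resistance with the dose field missing.
    All record dates lie within the patient's alive interval.
    """
    rows: list[dict] = []
    end = history.end_day
    m0 = profile["baseline_state"] == "HS1"
    fail = _failure_day(history)

    def add(item, category, dose, unit, start, stop):
        stop = min(stop, end)
        if stop <= start:
            return
        rows.append(
            dict(
                patient_id=history.patient_id,
                item=item,
                category=category,
                dose=dose,
                unit=unit,
                start_day=float(start),
                stop_day=float(stop),
            )
        )

    if profile["arm"] == "AAP_SOC":
        stop = fail if fail is not None else end
        if m0:
            stop = min(stop if stop is not None else end, 2 * DAYS_PER_YEAR)
        aap_dose = np.nan if rng.random() < missingness.p_missing_dose else 1000.0
        pred_dose = np.nan if rng.random() < missingness.p_missing_dose else 5.0
        add("abiraterone", "investigational", aap_dose, "mg/day", 0.0, stop)
        add("prednisolone", "investigational", pred_dose, "mg/day", 0.0, stop)
    else:
        crpc = _first_crpc_entry(history)
        if crpc is not None and rng.random() < cost_truth.soc_late_aap_fraction:
            # dose information for SOC-arm AAP is always missing
            nxt = next((d for _, d in history.records if d > crpc), end)
            add("abiraterone", "investigational", np.nan, "mg/day", crpc, nxt)
            add("prednisolone", "investigational", np.nan, "mg/day", crpc, nxt)

    # specific (expensive) medications during CRPC episodes
    for state, lo, hi in history.intervals():
        if state not in CRPC_STATES:
            continue
        for med, prob in cost_truth.specific_med_prob.items():
            if rng.random() < prob:
                start = lo + rng.uniform(0.0, max(hi - lo, 1.0) * 0.3)
                add(med, "specific", 1.0, "course/day", start,
                    start + cost_truth.specific_med_duration_days)

    # continuous ADT backbone therapy (both arms, all alive time)
    add("adt", "general", 1.0, "course/day", 0.0, end)

    # general disease-management encounters, Poisson by state group
    for state, lo, hi in history.intervals():
        grp = "crpc" if state in CRPC_STATES else "naive"
        years = (hi - lo) / DAYS_PER_YEAR
        for item, rate in (
            ("outpatient_visit", cost_truth.outpatient_rate[grp]),
            ("gp_visit", cost_truth.gp_rate[grp]),
            ("inpatient_stay", cost_truth.inpatient_rate[grp]),
            ("radiotherapy", cost_truth.radiotherapy_rate[grp]),
        ):
            for _ in range(rng.poisson(rate * years)):
                day = lo + rng.uniform(0.0, hi - lo)
                add(item, "general", 1.0, "event", day, day + 1.0)

    # serious adverse events
    years_alive = end / DAYS_PER_YEAR
    for _ in range(rng.poisson(cost_truth.sae_rate * years_alive)):
        day = rng.uniform(0.0, end)
        add("sae", "sae", 1.0, "event", day, day + 1.0)

    cols = ["patient_id", "item", "category", "dose", "unit", "start_day", "stop_day"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

# emission map used when writing a raw dated-event table from a history;
# classify_events() inverts it exactly
_EMISSION = {
    ("HS1", "HS4"): ("failure", ""),
    ("HS1", "HS5"): ("metastasis", "bone"),
    ("HS1", "HS7"): ("metastasis", "visceral"),
    ("HS2", "HS5"): ("failure", ""),
    ("HS2", "HS7"): ("metastasis", "visceral"),
    ("HS3", "HS7"): ("failure", ""),
    ("HS4", "HS5"): ("metastasis", "bone"),
    ("HS4", "HS7"): ("metastasis", "visceral"),
    ("HS5", "HS6"): ("sre", ""),
    ("HS5", "HS7"): ("metastasis", "visceral"),
    ("HS6", "HS7"): ("metastasis", "visceral"),
}


def emit_raw_events(history: EventHistory) -> pd.DataFrame:
    """Dated clinical events equivalent to a state history (round-trippable)."""
    rows = []
    for (s, _), (t, d) in zip(history.records, history.records[1:]):
        if t is HealthState.HS8:
            kind, detail = "death", "pc"
        elif t is HealthState.HS9:
            kind, detail = "death", "other"
        else:
            kind, detail = _EMISSION[(s.name, t.name)]
        rows.append(
            dict(patient_id=history.patient_id, day=d, kind=kind, detail=detail)
        )
    return pd.DataFrame(rows, columns=["patient_id", "day", "kind", "detail"])


@dataclass
class Cohort:
    profiles: pd.DataFrame
    histories: list[EventHistory]
    eq5d: pd.DataFrame
    resource_use: pd.DataFrame
    config: GroundTruthConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "profiles.csv", index=False)
        frames = [f for h in self.histories
                  if len(f := emit_raw_events(h))]
        (pd.concat(frames, ignore_index=True) if frames
         else emit_raw_events(self.histories[0]).iloc[:0]
         ).to_csv(outdir / "events.csv", index=False)
        self.eq5d.to_csv(outdir / "eq5d.csv", index=False)
        self.resource_use.to_csv(outdir / "resource_use.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=1, default=str)


def _sample_profiles(config: GroundTruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients

    def draw(table: dict) -> np.ndarray:
        keys = list(table)
        return rng.choice(keys, size=n, p=[table[k] for k in keys])

    df = pd.DataFrame(
        dict(
            patient_id=[f"P{i:05d}" for i in range(n)],
            arm=np.where(
                rng.random(n) < config.allocation_ratio, "AAP_SOC", "SOC"
            ),
            baseline_state=draw(config.baseline_state_probs),
            age_group=draw(config.age_group_probs),
            who_status=draw(config.who_status_probs),
            nodal_stage=draw(config.nodal_stage_probs),
            england=(rng.random(n) < config.p_england).astype(int),
            era_post2013=(rng.random(n) < config.p_era_post2013).astype(int),
        )
    )
    df["subgroup"] = np.where(df.baseline_state == "HS1", "M0", "M1")
    return df


def generate_cohort(config: GroundTruthConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = _sample_profiles(config, rng)
    schedule = VisitSchedule.protocol()
    tariff = TariffTable.uk_default()
    histories, eq5d_parts, ru_parts = [], [], []
    for prof in profiles.to_dict("records"):
        h = sample_event_history(
            prof, config.transition_hazards, config.follow_up_days, rng
        )
        histories.append(h)
        eq5d_parts.append(
            generate_eq5d_panel(
                h, schedule, config.utility_truth, config.missingness, rng,
                arm=prof["arm"], tariff=tariff,
            )
        )
        ru_parts.append(
            generate_resource_use(
                h, prof, config.cost_truth, config.missingness, rng
            )
        )
    return Cohort(
        profiles=profiles,
        histories=histories,
        eq5d=pd.concat(eq5d_parts, ignore_index=True),
        resource_use=pd.concat(ru_parts, ignore_index=True),
        config=config,
    )
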