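"""Utility pipeline: EQ-5D scoring, chained-equation imputation, and the
two-part utility regression.

Utility scores have a ceiling at 1 (full health) and a long lower tail, so
the regression is split in two: a logit model for P(utility = 1) and a
gamma regression with identity link for the disutility (1 - utility) when
below the ceiling.  Repeated measures within patients are handled by
working-independence estimating equations with robust (cluster) standard
errors, and competing covariate sets are compared by QIC.  Missing scores
(skipped or partially completed questionnaires) are multiply imputed by
chained equations with predictive mean matching, separately by randomised
arm; by default the best-fitting imputation (lowest QIC) feeds the
simulator, with a pooled mode available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Independence
from statsmodels.imputation.mice import MICEData

from .cohort import DAYS_PER_YEAR, VisitSchedule
from .states import DEAD_STATES, EventHistory, HealthState
from .tariff import DIMENSIONS, TariffTable

__all__ = [
    "build_utility_panel",
    "impute_utilities",
    "fit_two_part_utility",
    "TwoPartUtilityModel",
    "utility_design_row",
    "UTILITY_COVARIATES",
]

UTILITY_COVARIATES = [
    "age_60_69", "age_70plus", "who_1_2", "nodal_pos",
    "hs2", "hs3", "hs4", "hs5", "hs6", "hs7",
    "ty_aap_y1", "ty_soc_y1",
]


def utility_design_row(profile: dict, state: str, in_first_year: bool,
                       arm: str | None = None) -> dict:
    """Covariate encoding for the two-part utility model.

    The treatment-in-first-year covariate has three categories: first-year
    AAP+SOC, first-year SOC-only, and second year onwards in either arm
    (the reference) — the arm effect on quality of life is first-year only.
    """
    arm = arm or profile.get("arm")
    return {
        "age_60_69": 1.0 if profile.get("age_group") == "60-69" else 0.0,
        "age_70plus": 1.0 if profile.get("age_group") == ">=70" else 0.0,
        "who_1_2": 1.0 if profile.get("who_status") == "1-2" else 0.0,
        "nodal_pos": 1.0 if profile.get("nodal_stage") == "N+" else 0.0,
        **{f"hs{i}": 1.0 if state == f"HS{i}" else 0.0 for i in range(2, 8)},
        "ty_aap_y1": 1.0 if (in_first_year and arm == "AAP_SOC") else 0.0,
        "ty_soc_y1": 1.0 if (in_first_year and arm == "SOC") else 0.0,
    }


def build_utility_panel(eq5d: pd.DataFrame, histories: list[EventHistory],
                        profiles: pd.DataFrame,
                        tariff: TariffTable | None = None,
                        schedule: VisitSchedule | None = None) -> pd.DataFrame:
    """Score responses and lay them on the full protocol visit grid.

    One row per (patient, scheduled visit) while the patient is alive and in
    follow-up; ``utility`` is NaN where the questionnaire was skipped or
    partial.  Health state at the visit and the model covariates are
    attached.
    """
    tariff = tariff or TariffTable.uk_default()
    schedule = schedule or VisitSchedule.protocol()
    scored = eq5d.copy()
    dims = scored[list(DIMENSIONS)].to_numpy(float)
    scored["utility"] = [
        np.nan if np.isnan(row).any() else tariff.score(row) for row in dims
    ]
    obs = scored.set_index(["patient_id", "visit_day"])["utility"]
    pmap = {str(r["patient_id"]): dict(r) for _, r in profiles.iterrows()}
    rows = []
    for h in histories:
        prof = pmap[h.patient_id]
        died = h.death_day is not None
        for day in schedule.visit_times:
            if day > h.end_day:
                break
            state = h.state_at(day)
            if state in DEAD_STATES:
                break
            u = obs.get((h.patient_id, day), np.nan)
            rows.append(
                dict(
                    patient_id=h.patient_id,
                    visit_day=day,
                    visit_year=day / DAYS_PER_YEAR,
                    state=state.name,
                    arm=prof["arm"],
                    died_in_trial=int(died),
                    utility=u,
                )
                | utility_design_row(prof, state.name, day < DAYS_PER_YEAR)
            )
    return pd.DataFrame(rows)


def impute_utilities(panel: pd.DataFrame, predictors: list[str] | None = None,
                     n_imputations: int = 5, n_iterations: int = 30,
                     seed: int = 0) -> list[pd.DataFrame]:
    """Multiple imputation of missing utilities by chained equations with
    predictive mean matching, run separately by randomised arm.

    Observed utilities are untouched; imputed values are donor values so
    they stay within the observed range.  Returns ``n_imputations``
    completed copies of the panel.
    """
    predictors = predictors or (
        ["visit_year", "died_in_trial"] + UTILITY_COVARIATES
    )
    if panel["utility"].notna().sum() == 0:
        raise ValueError("no observed utilities — cannot impute")
    for arm, sub in panel.groupby("arm"):
        if sub["utility"].notna().sum() == 0:
            raise ValueError(f"arm {arm}: all utilities missing — cannot impute")
    np.random.seed(seed % (2**32 - 1))  # MICEData uses the global numpy state
    completed = [panel.copy() for _ in range(n_imputations)]
    for arm in sorted(panel["arm"].unique()):
        mask = panel["arm"] == arm
        sub = panel.loc[mask, ["utility"] + predictors].reset_index(drop=True)
        if sub["utility"].isna().sum() == 0:
            continue
        # drop constant predictors (would make the chained regression singular)
        use = [p for p in predictors if sub[p].nunique() > 1]
        imp = MICEData(sub[["utility"] + use])
        for k in range(n_imputations):
            imp.update_all(n_iterations)
            completed[k].loc[mask, "utility"] = imp.data["utility"].to_numpy()
    return completed


@dataclass
class TwoPartUtilityModel:
    """Fitted two-part utility regression.

    part1: logit (or log-link binomial) for P(utility = 1);
    part2: gamma regression, identity link, for disutility 1 - utility
    given utility < 1.  The predicted mean is p * 1 + (1 - p) * (1 - m).
    """

    covariates: list[str]
    part1_params: np.ndarray
    part1_vcov: np.ndarray
    part2_params: np.ndarray
    part2_vcov: np.ndarray
    qic: float
    link: str = "logit"
    min_utility: float = -0.594
    meta: dict = field(default_factory=dict)

    def _xrow(self, row: dict) -> np.ndarray:
        return np.r_[1.0, [float(row.get(c, 0.0)) for c in self.covariates]]

    def p_full(self, row: dict, params: np.ndarray | None = None) -> float:
        b = self.part1_params if params is None else params
        eta = float(self._xrow(row) @ b)
        if self.link == "log":
            return float(min(np.exp(eta), 1.0))
        return float(1.0 / (1.0 + np.exp(-eta)))

    def mean_disutility(self, row: dict, params: np.ndarray | None = None) -> float:
        b = self.part2_params if params is None else params
        m = float(self._xrow(row) @ b)  # identity link
        return float(np.clip(m, 1e-9, 1.0 - self.min_utility))

    def predict_mean(self, row: dict, part1: np.ndarray | None = None,
                     part2: np.ndarray | None = None) -> float:
        p = self.p_full(row, part1)
        m = self.mean_disutility(row, part2)
        return p * 1.0 + (1.0 - p) * (1.0 - m)

    def to_dict(self) -> dict:
        return dict(
            covariates=list(self.covariates),
            part1_params=self.part1_params.tolist(),
            part1_vcov=self.part1_vcov.tolist(),
            part2_params=self.part2_params.tolist(),
            part2_vcov=self.part2_vcov.tolist(),
            qic=self.qic,
            link=self.link,
            min_utility=self.min_utility,
            meta=self.meta,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "TwoPartUtilityModel":
        return cls(
            covariates=list(d["covariates"]),
            part1_params=np.asarray(d["part1_params"], float),
            part1_vcov=np.asarray(d["part1_vcov"], float),
            part2_params=np.asarray(d["part2_params"], float),
            part2_vcov=np.asarray(d["part2_vcov"], float),
            qic=float(d["qic"]),
            link=d.get("link", "logit"),
            min_utility=float(d.get("min_utility", -0.594)),
            meta=dict(d.get("meta", {})),
        )


def fit_two_part_utility(completed_panel: pd.DataFrame,
                         covariates: list[str] | None = None,
                         link: str = "logit") -> TwoPartUtilityModel:
    """Fit the two-part utility regression on one completed panel.

    Estimating equations with a working-independence correlation and robust
    cluster errors (cluster = patient).  Raises if the outcome is
    degenerate (all utilities 1, or none).
    """
    covariates = list(covariates or UTILITY_COVARIATES)
    df = completed_panel.dropna(subset=["utility"]).copy()
    full = (df["utility"] >= 1.0 - 1e-12).astype(float)
    if full.sum() == 0 or full.sum() == len(full):
        raise ValueError(
            "degenerate utility outcome: need both ceiling and below-ceiling values"
        )
    X = sm.add_constant(df[covariates].to_numpy(float), has_constant="add")
    groups = df["patient_id"].to_numpy()
    binom_link = sm.families.links.Log() if link == "log" else sm.families.links.Logit()
    gee1 = sm.GEE(full.to_numpy(), X, groups=groups,
                  family=sm.families.Binomial(link=binom_link),
                  cov_struct=Independence())
    res1 = gee1.fit(maxiter=100)
    below = df.loc[full == 0.0]
    disutil = (1.0 - below["utility"]).clip(lower=1e-6).to_numpy()
    Xb = sm.add_constant(below[covariates].to_numpy(float), has_constant="add")
    gee2 = sm.GEE(disutil, Xb, groups=below["patient_id"].to_numpy(),
                  family=sm.families.Gamma(link=sm.families.links.Identity()),
                  cov_struct=Independence())
    res2 = gee2.fit(maxiter=200)
    qic = float(res1.qic()[0] + res2.qic()[0])
    return TwoPartUtilityModel(
        covariates=covariates,
        part1_params=np.asarray(res1.params, float),
        part1_vcov=np.asarray(res1.cov_params(), float),
        part2_params=np.asarray(res2.params, float),
        part2_vcov=np.asarray(res2.cov_params(), float),
        qic=qic,
        link=link,
        meta=dict(n_rows=len(df), n_full=int(full.sum())),
    )


def fit_best_imputation(completed_panels: list[pd.DataFrame],
                        covariates: list[str] | None = None,
                        link: str = "logit") -> TwoPartUtilityModel:
    """Fit the two-part model on each imputed panel and keep the best QIC.

    Mirrors using the single best-fitting imputation for the simulator; the
    chosen imputation index is recorded in ``meta``.
    """
    fits = [fit_two_part_utility(p, covariates, link) for p in completed_panels]
    best = int(np.argmin([f.qic for f in fits]))
    model = fits[best]
    model.meta["imputation_mode"] = "best_fit"
    model.meta["imputation_index"] = best
    model.meta["qic_all"] = [f.qic for f in fits]
    return model


def pool_imputations(completed_panels: list[pd.DataFrame],
                     covariates: list[str] | None = None,
                     link: str = "logit") -> TwoPartUtilityModel:
    """Pool the two-part fits across imputations by combination rules.

    Pooled estimate = mean of the per-imputation estimates; pooled
    covariance = within-imputation mean plus (1 + 1/m) times the
    between-imputation covariance, so pooled standard errors are never
    smaller than the average single-imputation ones.
    """
    fits = [fit_two_part_utility(p, covariates, link) for p in completed_panels]
    m = len(fits)

    def pool(params_list, vcov_list):
        P = np.stack(params_list)
        qbar = P.mean(axis=0)
        W = np.mean(np.stack(vcov_list), axis=0)
        dev = P - qbar
        B = (dev.T @ dev) / max(m - 1, 1)
        return qbar, W + (1.0 + 1.0 / m) * B

    p1, v1 = pool([f.part1_params for f in fits], [f.part1_vcov for f in fits])
    p2, v2 = pool([f.part2_params for f in fits], [f.part2_vcov for f in fits])
    model = TwoPartUtilityModel(
        covariates=fits[0].covariates, part1_params=p1, part1_vcov=v1,
        part2_params=p2, part2_vcov=v2,
        qic=float(np.mean([f.qic for f in fits])), link=link,
    )
    model.meta["imputation_mode"] = "pooled"
    model.meta["n_imputations"] = m
    return model


def predict_state_utility(model: TwoPartUtilityModel, profile: dict,
                          state: str, in_first_year: bool,
                          arm: str | None = None) -> float:
    """Deterministic mean utility for a covariate combination; 0 when dead."""
    hs = HealthState[state] if isinstance(state, str) else state
    if hs in DEAD_STATES:
        return 0.0
    row = utility_design_row(profile, hs.name, in_first_year, arm)
    return model.predict_mean(row)
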