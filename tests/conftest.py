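"""Shared fixtures: one moderately sized synthetic cohort and the models
fitted from it, built once per session (several downstream suites reuse
them), plus helpers for constructing degenerate model suites with known
closed-form behaviour."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import cuapath as cp
from cuapath.costs import (
    SpecificMedCostTable,
    UnitCostTable,
    build_general_cycle_table,
    cost_records,
    fit_two_part_cost,
    impute_doses,
)
from cuapath.survival import (
    DestinationModel,
    MODEL_GROUP_PLAN,
    ModelSuite,
    TransitionModel,
    fit_model_suite,
)
from cuapath.utility import build_utility_panel, fit_best_imputation, impute_utilities

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def cohort300():
    return cp.generate_cohort(cp.GroundTruthConfig(n_patients=300, seed=3))


@pytest.fixture(scope="session")
def suite300(cohort300):
    return fit_model_suite(cohort300.histories, cohort300.profiles)


@pytest.fixture(scope="session")
def utility_model300(cohort300):
    panel = build_utility_panel(
        cohort300.eq5d, cohort300.histories, cohort300.profiles
    )
    completed = impute_utilities(panel, seed=11)
    return fit_best_imputation(completed)


@pytest.fixture(scope="session")
def cost_artifacts300(cohort300):
    uc = UnitCostTable()
    records, _ = impute_doses(cohort300.resource_use, uc)
    cycles = cost_records(records, uc, cohort300.histories)
    gen = build_general_cycle_table(cycles, cohort300.histories, cohort300.profiles)
    cost_model = fit_two_part_cost(gen)
    med_table = SpecificMedCostTable.build(
        cycles, records, cohort300.histories, cohort300.profiles, uc
    )
    return dict(unit_costs=uc, records=records, cycles=cycles, gen=gen,
                cost_model=cost_model, med_table=med_table)


# ---------------------------------------------------------------------------
# constructed (non-fitted) models with known behaviour
# ---------------------------------------------------------------------------

def make_exp_model(rate_per_year: float, covariates=()) -> TransitionModel:
    """Exponential transition model with a fixed hazard (per year)."""
    cov = list(covariates)
    log_rate = np.log(rate_per_year) if rate_per_year > 0 else -60.0
    k = 1 + len(cov)
    return TransitionModel(
        family="exponential", covariates=cov,
        param_names=["log_rate", "intercept"] + [f"b_{c}" for c in cov],
        params=np.r_[log_rate, np.zeros(len(cov))],
        vcov=np.zeros((k, k)), loglik=0.0, aic=0.0, n_obs=0, n_events=1,
    )


def make_exp_suite(first_rate: float = 0.0, other_cause_rate: float = 0.0,
                   crpc_death_rate: float = 0.0,
                   crpc_prog_rate: float = 0.0) -> ModelSuite:
    """Suite of constant exponential models: the joint first-event hazard,
    the other-cause hazard, CRPC death and CRPC progression hazards; all
    first events land in the matching CRPC state."""
    models = {}
    for group in MODEL_GROUP_PLAN:
        if group == "first_event":
            r = first_rate
        elif group == "other_cause":
            r = other_cause_rate
        elif group in ("to_hs7", "hs4_hs5", "hs5_hs6"):
            r = crpc_prog_rate
        else:
            r = crpc_death_rate
        models[group] = make_exp_model(r)
    dest = DestinationModel(probs={
        (b, arm): {d: 1.0 if d == main else 0.0
                   for d in DestinationModel._STRUCTURAL[b]}
        for b, main in (("HS1", "HS4"), ("HS2", "HS5"), ("HS3", "HS7"))
        for arm in ("AAP_SOC", "SOC")
    })
    return ModelSuite(models=models, destination=dest)


@pytest.fixture
def profile_m0():
    return dict(patient_id="T0", arm="SOC", baseline_state="HS1",
                age_group="60-69", who_status="0", nodal_stage="N0",
                england=1, era_post2013=0, subgroup="M0")


@pytest.fixture
def profile_m1():
    return dict(patient_id="T1", arm="AAP_SOC", baseline_state="HS2",
                age_group="<60", who_status="1-2", nodal_stage="N+",
                england=1, era_post2013=1, subgroup="M1")
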