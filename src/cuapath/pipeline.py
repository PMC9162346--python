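"""End-to-end pipeline: generate -> classify -> fit -> model -> simulate ->
evaluate, with all tables and figures written to an output directory.

The configuration is a flat-ish dictionary (loadable from YAML) with
sections mirroring the stages; every value has a default, so
``run_pipeline({}, outdir)`` runs the whole analysis on a synthetic cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, GroundTruthConfig, Missingness, generate_cohort
from .costs import (
    SpecificMedCostTable,
    UnitCostTable,
    build_general_cycle_table,
    cost_records,
    fit_two_part_cost,
    impute_doses,
)
from .econ import (
    DEFAULT_LAMBDAS,
    ceac,
    incrementals,
    make_plane,
    plot_ceac,
    plot_plane,
    run_psa,
    threshold_price,
)
from .simulate import (
    CYCLE_DAYS,
    MortalitySplice,
    SimulationSettings,
    make_utility_fn,
    run_deterministic,
)
from .states import tabulate_transitions, write_histories, write_transition_counts
from .survival import ModelSuite, fit_model_suite
from .utility import build_utility_panel, fit_best_imputation, impute_utilities

log = logging.getLogger("cuapath")

__all__ = ["run_pipeline", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "cohort": {"n_patients": 1000, "follow_up_years": 5.0},
    "survival": {"families": ["exponential", "weibull"], "first_event_spline_df": 5},
    "utility": {"n_imputations": 5, "n_iterations": 30, "link": "logit"},
    "costs": {"boundary": 1500.0, "abiraterone_daily": 97.68},
    "simulation": {
        "horizon_years": 45.0,
        "cycle_days": CYCLE_DAYS,
        "discount_rate": 0.035,
        "n_sims_deterministic": 40,
        "n_sims_psa": 25,
        "psa_iterations": 500,
    },
    "econ": {"lambdas": list(DEFAULT_LAMBDAS), "price_fractions": [0.75, 0.5, 0.25, 0.10]},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULTS
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


class StageError(RuntimeError):
    """A pipeline stage failed; message carries stage name and cause."""


def run_pipeline(config: dict | None = None, outdir="results", seed: int | None = None,
                 run_psa_stage: bool = True) -> dict:
    """Execute the full analysis and write every artifact under ``outdir``.

    Returns a dict with the in-memory results (cohort, fitted models,
    summaries).  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    cfg = _merge(DEFAULTS, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg}

    def stage(name, fn):
        log.info("stage %s ...", name)
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - report stage and re-raise
            raise StageError(f"stage {name!r} failed: {e}") from e

    # 1. synthetic cohort ---------------------------------------------------
    def _generate() -> Cohort:
        ck = dict(cfg["cohort"])
        fu_years = ck.pop("follow_up_years", 5.0)
        miss = ck.pop("missingness", None)
        gt = GroundTruthConfig(
            seed=cfg["seed"], follow_up_days=fu_years * 365.25,
            **({"missingness": Missingness(**miss)} if miss else {}), **ck,
        )
        cohort = generate_cohort(gt)
        cohort.write(outdir / "cohort")
        log.info("generated %d patients, %d EQ-5D rows, %d resource records",
                 len(cohort.profiles), len(cohort.eq5d), len(cohort.resource_use))
        return cohort

    cohort = stage("generate", _generate)
    results["cohort"] = cohort

    # 2. state histories and transition counts ------------------------------
    def _classify():
        write_histories(cohort.histories, outdir / "histories.csv")
        counts = tabulate_transitions(cohort.histories)
        write_transition_counts(counts, outdir / "transition_counts.csv")
        return counts

    results["transition_counts"] = stage("classify", _classify)

    # 3. survival models -----------------------------------------------------
    def _fit_survival() -> ModelSuite:
        sv = cfg["survival"]
        suite = fit_model_suite(
            cohort.histories, cohort.profiles,
            families=tuple(sv["families"]),
            first_event_spline_df=sv.get("first_event_spline_df"),
        )
        suite.to_json(outdir / "transition_models.json")
        for name, m in suite.models.items():
            log.info("model %s: %s (AIC %.1f, %d events)", name, m.family,
                     m.aic, m.n_events)
        return suite

    suite = stage("fit_survival", _fit_survival)
    results["suite"] = suite

    # 4. utility pipeline ----------------------------------------------------
    def _utility():
        uk = cfg["utility"]
        panel = build_utility_panel(cohort.eq5d, cohort.histories, cohort.profiles)
        completed = impute_utilities(
            panel, n_imputations=uk["n_imputations"],
            n_iterations=uk["n_iterations"], seed=cfg["seed"] + 1,
        )
        for k, p in enumerate(completed):
            p.to_csv(outdir / f"utilities_imputed_{k}.csv", index=False)
        model = fit_best_imputation(completed, link=uk["link"])
        (outdir / "utility_model.json").write_text(json.dumps(model.to_dict(), indent=1))
        return model

    utility_model = stage("utility", _utility)
    results["utility_model"] = utility_model

    # 5. cost pipeline -------------------------------------------------------
    def _costs():
        ck = cfg["costs"]
        unit_costs = UnitCostTable().with_abiraterone_price(ck["abiraterone_daily"])
        records, imp_log = impute_doses(cohort.resource_use, unit_costs)
        imp_log.to_csv(outdir / "dose_imputation_log.csv", index=False)
        cycles = cost_records(records, unit_costs, cohort.histories)
        cycles.to_csv(outdir / "cycle_costs.csv", index=False)
        gen = build_general_cycle_table(cycles, cohort.histories, cohort.profiles)
        cost_model = fit_two_part_cost(gen, boundary=ck["boundary"])
        med_table = SpecificMedCostTable.build(
            cycles, records, cohort.histories, cohort.profiles, unit_costs
        )
        n_sae = int((cohort.resource_use["item"] == "sae").sum())
        alive_cycles = sum(np.ceil(h.end_day / CYCLE_DAYS) for h in cohort.histories)
        sae_rate = n_sae / max(alive_cycles, 1.0)
        return unit_costs, cost_model, med_table, float(sae_rate)

    unit_costs, cost_model, med_table, sae_rate = stage("costs", _costs)
    results.update(unit_costs=unit_costs, cost_model=cost_model,
                   med_table=med_table, sae_rate_per_cycle=sae_rate)

    # 6. lifetime simulation -------------------------------------------------
    def _simulate():
        sk = cfg["simulation"]
        settings = SimulationSettings(
            cycle_days=sk["cycle_days"], horizon_years=sk["horizon_years"],
            discount_rate=sk["discount_rate"],
            n_sims_deterministic=sk["n_sims_deterministic"],
            n_sims_psa=sk["n_sims_psa"], psa_iterations=sk["psa_iterations"],
            seed=cfg["seed"] + 2,
        )
        splice = MortalitySplice(splice_day=cfg["cohort"].get("follow_up_years", 5.0) * 365.25)
        summary, lifetimes = run_deterministic(
            cohort.profiles, suite, make_utility_fn(utility_model), cost_model,
            med_table, unit_costs, settings, splice,
            sae_rate_per_cycle=sae_rate, collect_lifetimes=True,
        )
        lifetimes.to_csv(outdir / "lifetimes.csv", index=False)
        summary.to_csv(outdir / "arm_summary.csv", index=False)
        return settings, splice, summary

    settings, splice, summary = stage("simulate", _simulate)
    results.update(settings=settings, arm_summary=summary)

    # 7. economic evaluation -------------------------------------------------
    def _evaluate():
        ek = cfg["econ"]
        inc = incrementals(summary)
        inc.to_csv(outdir / "icer_table.csv", index=False)
        base_price = unit_costs.abiraterone_daily
        th_rows = []
        for rec in inc.to_dict("records"):
            if rec["aap_days_disc_incr"] <= 0:
                continue
            for lam in ek["lambdas"]:
                th = threshold_price(rec["delta_cost"], rec["delta_qalys"],
                                     rec["aap_days_disc_incr"], lam, base_price)
                th_rows.append(dict(subgroup=rec["subgroup"]) | th)
        pd.DataFrame(th_rows).to_csv(outdir / "threshold.csv", index=False)
        psa_out = None
        if run_psa_stage:
            psa_out = run_psa(
                cohort.profiles, suite, utility_model, cost_model, med_table,
                unit_costs, replace(settings, seed=cfg["seed"] + 3), splice,
                sae_rate_per_cycle=sae_rate,
            )
            psa_out.iterations.to_csv(outdir / "psa_iterations.csv", index=False)
            ceac_df = ceac(psa_out)
            ceac_df.to_csv(outdir / "ceac.csv", index=False)
            plane = make_plane(psa_out)
            plane["points"].to_csv(outdir / "plane.csv", index=False)
            for sg in plane["points"].subgroup.unique():
                plot_plane(plane, sg, outdir / f"plane_{sg}.png")
                plot_ceac(ceac_df, sg, outdir / f"ceac_{sg}.png")
        return inc, pd.DataFrame(th_rows), psa_out

    inc, thresholds, psa_out = stage("evaluate", _evaluate)
    results.update(incrementals=inc, thresholds=thresholds, psa=psa_out)

    # 8. metadata ------------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    meta = dict(
        seed=cfg["seed"], config_hash=cfg_hash, version=__version__,
        python=platform.python_version(), numpy=np.__version__,
        pandas=pd.__version__,
    )
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    results["metadata"] = meta
    return results
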