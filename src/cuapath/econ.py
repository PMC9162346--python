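"""Economic evaluation: ICERs, price-threshold analysis, PSA, CEAC, plane.

The incremental cost-effectiveness ratio is dC/dQ for the AAP+SOC pathway
versus SOC alone, reported per subgroup.  Because lifetime incremental cost
is exactly linear in the abiraterone daily price p —
dC(p) = dC(p0) - (p0 - p) * D with D the discounted incremental
AAP-treated days — the price at which the ICER meets a willingness-to-pay
threshold, and the break-even (dominance) price, have closed forms that the
simulator's recorded exposure makes available without re-simulation.
Probabilistic sensitivity analysis redraws the utility and cost regression
coefficients from multivariate normals and the unit-cost items from gamma
distributions, reruns the simulation, and summarises the (dQ, dC) cloud as
a cost-effectiveness plane and acceptability curve (net-monetary-benefit
definition: CEAC(lambda) = P(lambda*dQ - dC > 0)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costs import SpecificMedCostTable, TwoPartCostModel, UnitCostTable, _psd
from .simulate import (
    MortalitySplice,
    SimulationSettings,
    make_utility_fn,
    run_deterministic,
)
from .survival import ModelSuite
from .utility import TwoPartUtilityModel

__all__ = [
    "compute_icer",
    "incrementals",
    "threshold_price",
    "price_at_fraction",
    "run_psa",
    "ceac",
    "make_plane",
    "PsaResult",
]

DEFAULT_LAMBDAS = (13_000.0, 20_000.0, 30_000.0)


def compute_icer(delta_cost: float, delta_qaly: float) -> float | str:
    """dC/dQ in GBP/QALY, or a dominance label.

    'dominant' when cheaper and more effective; 'dominated' when more
    expensive and less effective; 'undefined' at dQ = 0 (no division error).
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("ICER inputs must be finite")
    if delta_qaly == 0.0:
        return "undefined"
    if delta_qaly > 0.0:
        return "dominant" if delta_cost < 0.0 else delta_cost / delta_qaly
    return "dominated" if delta_cost > 0.0 else delta_cost / delta_qaly


def incrementals(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup incrementals (AAP_SOC minus SOC) from an arm summary."""
    rows = []
    for sg, sub in summary.groupby("subgroup"):
        aap = sub[sub.arm == "AAP_SOC"].iloc[0]
        soc = sub[sub.arm == "SOC"].iloc[0]
        dc = float(aap.cost_total - soc.cost_total)
        dq = float(aap.qalys - soc.qalys)
        rows.append(
            dict(
                subgroup=sg,
                cost_aap=float(aap.cost_total),
                cost_soc=float(soc.cost_total),
                qalys_aap=float(aap.qalys),
                qalys_soc=float(soc.qalys),
                delta_cost=dc,
                delta_qalys=dq,
                icer=compute_icer(dc, dq),
                aap_days_disc_incr=float(aap.aap_days_disc - soc.aap_days_disc),
            )
        )
    return pd.DataFrame(rows)


def price_at_fraction(fraction: float, base_price: float = 97.68) -> float:
    """Daily price at a fraction of the base list price, to the nearest pound
    (the convention threshold results are reported in)."""
    return float(np.round(fraction * base_price))


def threshold_price(delta_cost_base: float, delta_qaly: float,
                    aap_days_disc_incr: float, lam: float,
                    base_price: float = 97.68) -> dict:
    """Abiraterone daily price solving ICER(p) = lambda, plus the break-even
    price at which the incremental cost vanishes.

    Uses dC(p) = dC(p0) - (p0 - p) * D, D = discounted incremental
    AAP-treated days per patient.  Break-even below zero is reported as
    undefined (a negative price).
    """
    d = float(aap_days_disc_incr)
    if d <= 0:
        raise ValueError("no AAP price sensitivity: incremental exposure <= 0")
    p_thresh = base_price - (delta_cost_base - lam * delta_qaly) / d
    p_even = base_price - delta_cost_base / d
    return dict(
        lam=lam,
        threshold_price=float(p_thresh),
        threshold_fraction=float(p_thresh / base_price),
        breakeven_price=float(p_even) if p_even >= 0 else None,
        breakeven_undefined_negative=bool(p_even < 0),
    )


def delta_cost_at_price(delta_cost_base: float, aap_days_disc_incr: float,
                        price: float, base_price: float = 97.68) -> float:
    """Closed-form incremental cost at another abiraterone daily price."""
    return float(delta_cost_base - (base_price - price) * aap_days_disc_incr)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaResult:
    """PSA cloud: one (delta_cost, delta_qalys) per iteration per subgroup."""

    iterations: pd.DataFrame  # columns: iteration, subgroup, delta_cost, delta_qalys

    def mean_point(self, subgroup: str) -> tuple[float, float]:
        sub = self.iterations[self.iterations.subgroup == subgroup]
        return float(sub.delta_qalys.mean()), float(sub.delta_cost.mean())

    def percentile_ci(self, subgroup: str, level: float = 0.95) -> dict:
        sub = self.iterations[self.iterations.subgroup == subgroup]
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return dict(
            delta_cost=(float(sub.delta_cost.quantile(lo)),
                        float(sub.delta_cost.quantile(hi))),
            delta_qalys=(float(sub.delta_qalys.quantile(lo)),
                         float(sub.delta_qalys.quantile(hi))),
        )


def _draw_utility(model: TwoPartUtilityModel,
                  rng: np.random.Generator) -> TwoPartUtilityModel:
    p1 = rng.multivariate_normal(model.part1_params, _psd(model.part1_vcov))
    p2 = rng.multivariate_normal(model.part2_params, _psd(model.part2_vcov))
    return replace(model, part1_params=p1, part2_params=p2)


def _draw_unit_costs(uc: UnitCostTable, rng: np.random.Generator,
                     cv: float = 0.2) -> UnitCostTable:
    def gdraw(mean):
        if mean <= 0 or cv <= 0:
            return mean
        shape = 1.0 / cv**2
        return float(rng.gamma(shape, mean / shape))
    return replace(
        uc,
        end_of_life=gdraw(uc.end_of_life),
        sae_flat=gdraw(uc.sae_flat),
        monitoring_per_cycle=gdraw(uc.monitoring_per_cycle),
    )


def run_psa(profiles: pd.DataFrame, suite: ModelSuite,
            utility_model: TwoPartUtilityModel,
            cost_model: TwoPartCostModel | None,
            med_table: SpecificMedCostTable | None,
            unit_costs: UnitCostTable, settings: SimulationSettings,
            splice: MortalitySplice | None = None,
            n_iterations: int | None = None,
            sae_rate_per_cycle: float = 0.0,
            cost_cv: float = 0.2) -> PsaResult:
    """Joint probabilistic sensitivity analysis.

    Per iteration: regression coefficient vectors (two-part utility, every
    stratum of the two-part cost model) are drawn from multivariate normals
    with the fitted covariances; unit-cost items and the specific-medication
    cells from gamma distributions preserving their means; then the cohort
    is re-simulated with ``settings.n_sims_psa`` replicates per profile and
    the per-subgroup incrementals recorded.  One coherent parameter set is
    used across all stages within an iteration.
    """
    n_iterations = n_iterations or settings.psa_iterations
    master = np.random.SeedSequence(settings.seed)
    rows = []
    for it, ss in enumerate(master.spawn(n_iterations)):
        rng = np.random.default_rng(ss)
        u_draw = _draw_utility(utility_model, rng)
        c_draw = cost_model.draw(rng) if cost_model is not None else None
        m_draw = med_table.gamma_draw(rng, cost_cv) if med_table is not None else None
        uc_draw = _draw_unit_costs(unit_costs, rng, cost_cv)
        it_settings = replace(settings, seed=int(rng.integers(2**31 - 1)))
        summary = run_deterministic(
            profiles, suite, make_utility_fn(u_draw), c_draw, m_draw, uc_draw,
            it_settings, splice, n_sims=settings.n_sims_psa,
            sae_rate_per_cycle=sae_rate_per_cycle,
        )
        for rec in incrementals(summary).to_dict("records"):
            rows.append(
                dict(iteration=it, subgroup=rec["subgroup"],
                     delta_cost=rec["delta_cost"],
                     delta_qalys=rec["delta_qalys"])
            )
    return PsaResult(iterations=pd.DataFrame(rows))


def ceac(psa: PsaResult, thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve per subgroup.

    CEAC(lambda) = fraction of PSA iterations with positive net monetary
    benefit lambda * dQ - dC.  Monotone non-decreasing in lambda whenever
    all dQ share a sign; always bounded in [0, 1].
    """
    if len(psa.iterations) == 0:
        raise ValueError("CEAC needs at least one PSA iteration")
    thresholds = (
        np.linspace(0.0, 150_000.0, 151) if thresholds is None
        else np.asarray(thresholds, float)
    )
    rows = []
    for sg, sub in psa.iterations.groupby("subgroup"):
        dq = sub.delta_qalys.to_numpy()
        dc = sub.delta_cost.to_numpy()
        for lam in thresholds:
            nmb = lam * dq - dc
            rows.append(
                dict(subgroup=sg, threshold=float(lam),
                     probability=float((nmb > 0).mean()))
            )
    return pd.DataFrame(rows)


def make_plane(psa: PsaResult, lam: float = 30_000.0) -> dict:
    """Cost-effectiveness plane dataset: the (dQ, dC) scatter per subgroup
    with its mean point and the threshold line slope."""
    if len(psa.iterations) == 0:
        raise ValueError("plane needs at least one PSA iteration")
    points = psa.iterations[["subgroup", "delta_qalys", "delta_cost"]].copy()
    means = (
        points.groupby("subgroup", as_index=False)[["delta_qalys", "delta_cost"]]
        .mean()
    )
    return dict(points=points, means=means, threshold=float(lam))


def plot_plane(plane: dict, subgroup: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = plane["points"]
    pts = pts[pts.subgroup == subgroup]
    mean = plane["means"]
    mean = mean[mean.subgroup == subgroup].iloc[0]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pts.delta_qalys, pts.delta_cost, s=8, alpha=0.5, label="PSA draws")
    ax.scatter([mean.delta_qalys], [mean.delta_cost], color="red", zorder=3,
               label="mean")
    xs = np.array(ax.get_xlim())
    ax.plot(xs, plane["threshold"] * xs, "b:", label=f"£{plane['threshold']:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title(f"Cost-effectiveness plane — {subgroup}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(ceac_df: pd.DataFrame, subgroup: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ceac_df[ceac_df.subgroup == subgroup]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sub.threshold, sub.probability)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("P(AAP+SOC cost-effective)")
    ax.set_title(f"Cost-effectiveness acceptability curve — {subgroup}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
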