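"""Parametric time-to-event models for the multistate transitions.

A single maximum-likelihood engine covers exponential, Weibull (AFT),
lognormal and generalised-gamma families plus the flexible parametric
(Royston–Parmar type) spline model on the log cumulative-odds scale.  All
families share one surface: a linear predictor eta = b0 + x'b enters the
family's location (or log hazard for the exponential), right-censored
log-likelihoods are maximised with scipy, the observed-information vcov is
computed numerically, and models are compared by AIC = 2k - 2 logL.

Nine model groups cover the 25 transitions: one joint first-event model
(all exits from the naive states HS1-3 to HS4/5/7/8, the trial's
failure-free-survival event), one joint other-cause death model (HS1-7 to
HS9, age-dependent), one joint model for moves into the worst CRPC state
(HS4/5/6 to HS7), and six singly-modelled transitions (HS4->HS5, HS5->HS6,
HS4->HS8, HS5->HS8, HS6->HS8, HS7->HS8).  Destinations within the joint
first-event model are allocated by a saturated multinomial model on
baseline state and randomised arm.

All durations in this module are in **years**.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess2

from .states import (
    CRPC_STATES,
    NAIVE_STATES,
    EventHistory,
    HealthState,
)

DAYS_PER_YEAR = 365.25

FAMILY_ORDER = ("exponential", "weibull", "lognormal", "generalized_gamma", "spline_odds")

__all__ = [
    "TransitionModel",
    "FitError",
    "fit_parametric",
    "fit_spline_odds",
    "select_model",
    "sample_event_time",
    "build_first_event_dataset",
    "build_transition_dataset",
    "build_other_cause_dataset",
    "DestinationModel",
    "ModelSuite",
    "fit_model_suite",
    "MODEL_GROUP_PLAN",
]


class FitError(RuntimeError):
    """Model fitting failed; carries the family and optimiser diagnostics."""


# ---------------------------------------------------------------------------
# family log-likelihood kernels: each maps (t, eta, shapes) -> (log S, log f)
# ---------------------------------------------------------------------------

_TINY = 1e-300


def _exp_logsf_logpdf(t, eta, shapes):
    lam = np.exp(eta)
    return -lam * t, eta - lam * t


def _weib_logsf_logpdf(t, eta, shapes):
    k = np.exp(shapes[0])
    z = np.log(t) - eta
    kz = k * z
    return -np.exp(kz), shapes[0] - eta + (k - 1.0) * z - np.exp(kz)


def _lnorm_logsf_logpdf(t, eta, shapes):
    sigma = np.exp(shapes[0])
    z = (np.log(t) - eta) / sigma
    return stats.norm.logsf(z), stats.norm.logpdf(z) - shapes[0] - np.log(t)


def _gengamma_logsf_logpdf(t, eta, shapes):
    """Generalised gamma, (location mu, scale sigma, shape Q) convention.

    Q -> 0 recovers the lognormal; Q = 1 the Weibull.  Implemented with the
    lognormal branch for |Q| < 1e-5.
    """
    log_sigma, q = shapes
    if abs(q) < 1e-5:
        return _lnorm_logsf_logpdf(t, eta, [log_sigma])
    sigma = np.exp(log_sigma)
    w = (np.log(t) - eta) / sigma
    gam = q ** -2.0
    u = gam * np.exp(q * w)
    if q > 0:
        logsf = np.log(np.clip(special.gammaincc(gam, u), _TINY, None))
    else:
        logsf = np.log(np.clip(special.gammainc(gam, u), _TINY, None))
    logpdf = (
        np.log(abs(q))
        - log_sigma
        - np.log(t)
        + gam * np.log(gam)
        - special.gammaln(gam)
        + gam * (q * w - np.exp(q * w))
    )
    return logsf, logpdf


_KERNELS = {
    "exponential": (_exp_logsf_logpdf, 0, ["log_rate"]),
    "weibull": (_weib_logsf_logpdf, 1, ["log_shape"]),
    "lognormal": (_lnorm_logsf_logpdf, 1, ["log_sigma"]),
    "generalized_gamma": (_gengamma_logsf_logpdf, 2, ["log_sigma", "shape_q"]),
}


# ---------------------------------------------------------------------------
# natural cubic spline basis (log-time), Royston-Parmar style
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, knots: np.ndarray, deriv: bool = False) -> np.ndarray:
    """Basis [x, v_1..v_{m}] (without intercept) or its derivative in x.

    knots = [k_min, internal..., k_max]; the restricted-cubic construction is
    linear beyond the boundary knots.
    """
    x = np.asarray(x, float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x) if deriv else x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        if deriv:
            v = (
                3.0 * np.clip(x - kj, 0, None) ** 2
                - 3.0 * lam * np.clip(x - kmin, 0, None) ** 2
                - 3.0 * (1 - lam) * np.clip(x - kmax, 0, None) ** 2
            )
        else:
            v = (
                np.clip(x - kj, 0, None) ** 3
                - lam * np.clip(x - kmin, 0, None) ** 3
                - (1 - lam) * np.clip(x - kmax, 0, None) ** 3
            )
        cols.append(v)
    return np.column_stack(cols)


def _spline_knots(times: np.ndarray, events: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at min/max uncensored log time, df-1 internal knots at
    equally spaced quantiles of the uncensored log event times."""
    ev = np.log(times[events.astype(bool)])
    uniq = np.unique(ev)
    if len(uniq) < df + 1:
        raise FitError(
            f"spline_odds: only {len(uniq)} distinct event times; "
            f"need > df ({df}) — reduce df"
        )
    qs = np.linspace(0, 1, df + 1)
    return np.quantile(ev, qs)


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """One fitted parametric time-to-event model (durations in years)."""

    family: str
    covariates: list[str]
    param_names: list[str]
    params: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_events: int
    knots: np.ndarray | None = None  # spline_odds only
    transition_group: list[str] = field(default_factory=list)

    # -- internals ---------------------------------------------------------
    def _split(self, params=None):
        p = self.params if params is None else np.asarray(params, float)
        if self.family == "spline_odds":
            ng = len(self.knots)  # gamma0 + [x + internal] coefficients
            return p[:ng], 0.0, p[ng:]
        nshape = _KERNELS[self.family][1]
        return p[:nshape], p[nshape], p[nshape + 1:]

    def _eta(self, covariates: dict, params=None) -> float:
        shapes, b0, betas = self._split(params)
        eta = b0
        for name, b in zip(self.covariates, betas):
            eta += b * float(covariates.get(name, 0.0))
        return eta

    def log_sf(self, t, covariates: dict | None = None, params=None) -> np.ndarray:
        """log S(t | x); t in years."""
        t_in = np.asarray(t, float)
        scalar = t_in.ndim == 0
        t_arr = np.clip(np.atleast_1d(t_in), 1e-12, None)
        covariates = covariates or {}
        if self.family == "spline_odds":
            gam, _, _ = self._split(params)
            # for spline, eta enters the odds linearly: gamma0 absorbs b0
            shift = self._spline_shift(covariates, params)
            x = np.log(t_arr)
            s = gam[0] + _spline_basis(x, self.knots) @ gam[1:] + shift
            out = -np.logaddexp(0.0, s)  # log expit(-s)
        else:
            kernel = _KERNELS[self.family][0]
            shapes, _, _ = self._split(params)
            out, _ = kernel(t_arr, self._eta(covariates, params), shapes)
        return float(out[0]) if scalar else out

    def _spline_shift(self, covariates: dict, params=None) -> float:
        _, _, betas = self._split(params)
        return sum(
            b * float(covariates.get(n, 0.0))
            for n, b in zip(self.covariates, betas)
        )

    def sf(self, t, covariates: dict | None = None) -> np.ndarray:
        return np.exp(self.log_sf(t, covariates))

    def sample(self, rng: np.random.Generator, covariates: dict | None = None,
               conditional_on: float = 0.0) -> float:
        """Inverse-CDF draw of the event time (years), conditional on having
        survived ``conditional_on`` years."""
        covariates = covariates or {}
        u = rng.uniform()
        log_target = np.log(u)
        if conditional_on > 0:
            log_target += float(self.log_sf(conditional_on, covariates))
        return self._invert_log_sf(log_target, covariates)

    def _invert_log_sf(self, log_target: float, covariates: dict) -> float:
        shapes, _, _ = self._split()
        if self.family == "exponential":
            lam = np.exp(self._eta(covariates))
            return -log_target / lam
        if self.family == "weibull":
            k = np.exp(shapes[0])
            return np.exp(self._eta(covariates)) * (-log_target) ** (1.0 / k)
        if self.family == "lognormal":
            sigma = np.exp(shapes[0])
            z = stats.norm.isf(np.exp(log_target))
            return np.exp(self._eta(covariates) + sigma * z)
        # numeric inversion on log time for generalised gamma / spline
        f = lambda logt: (
            float(np.asarray(self.log_sf(np.exp(logt), covariates)).ravel()[0])
            - log_target
        )
        lo, hi = -10.0, 1.0
        while f(hi) > 0 and hi < 40:
            hi += 2.0
        while f(lo) < 0 and lo > -40:
            lo -= 2.0
        if f(hi) > 0:  # survival never reaches the target within e^40 years
            return np.exp(hi)
        return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-10)))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return dict(
            family=self.family,
            covariates=list(self.covariates),
            param_names=list(self.param_names),
            params=self.params.tolist(),
            vcov=self.vcov.tolist(),
            loglik=self.loglik,
            aic=self.aic,
            n_obs=self.n_obs,
            n_events=self.n_events,
            knots=None if self.knots is None else self.knots.tolist(),
            transition_group=list(self.transition_group),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(
            family=d["family"],
            covariates=list(d["covariates"]),
            param_names=list(d["param_names"]),
            params=np.asarray(d["params"], float),
            vcov=np.asarray(d["vcov"], float),
            loglik=float(d["loglik"]),
            aic=float(d["aic"]),
            n_obs=int(d["n_obs"]),
            n_events=int(d["n_events"]),
            knots=None if d.get("knots") is None else np.asarray(d["knots"], float),
            transition_group=list(d.get("transition_group", [])),
        )


def sample_event_time(model: TransitionModel, covariates: dict | None,
                      rng: np.random.Generator, conditional_on: float = 0.0) -> float:
    """Module-level alias for :meth:`TransitionModel.sample`."""
    return model.sample(rng, covariates, conditional_on)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design(dataset: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    missing = [c for c in covariates if c not in dataset.columns]
    if missing:
        raise ValueError(f"covariates not in dataset: {missing}")
    return dataset[list(covariates)].to_numpy(float) if covariates else np.zeros((len(dataset), 0))


def _neg_loglik_family(kernel, params, t, event, X, nshape):
    shapes = params[:nshape]
    eta = params[nshape] + X @ params[nshape + 1:]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        logsf, logpdf = kernel(t, eta, shapes)
        ll = np.where(event, logpdf, logsf)
    if not np.all(np.isfinite(ll)):
        return 1e10
    return -float(ll.sum())


def _fit(nll, x0, family) -> tuple[np.ndarray, float, np.ndarray]:
    best = optimize.minimize(nll, x0, method="BFGS",
                             options=dict(maxiter=500, gtol=1e-7))
    if not best.success or best.fun >= 1e9:
        # fall back to a derivative-free search, then polish
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options=dict(maxiter=4000, xatol=1e-8, fatol=1e-8))
        res2 = optimize.minimize(nll, res.x, method="BFGS",
                                 options=dict(maxiter=500, gtol=1e-7))
        cand = res2 if res2.fun <= res.fun else res
        if cand.fun < best.fun:
            best = cand
    if not np.isfinite(best.fun) or best.fun >= 1e9:
        raise FitError(f"{family}: optimiser failed to find a finite optimum "
                       f"({best.message})")
    try:
        hess = approx_hess2(best.x, nll)
        vcov = np.linalg.pinv(hess)
    except Exception:  # pragma: no cover - degenerate Hessian
        vcov = np.full((len(best.x), len(best.x)), np.nan)
    return np.asarray(best.x, float), -float(best.fun), vcov


def fit_parametric(dataset: pd.DataFrame, family: str,
                   covariates: list[str] | None = None) -> TransitionModel:
    """Fit a right-censored parametric model of one of the standard families.

    ``dataset`` needs columns ``time`` (years), ``event`` (0/1) and any
    covariates.  Refuses to fit with zero events.
    """
    if family not in _KERNELS:
        raise ValueError(f"unknown family {family!r}; choose from {list(_KERNELS)}")
    covariates = list(covariates or [])
    t = np.clip(dataset["time"].to_numpy(float), 1e-6, None)
    event = dataset["event"].to_numpy(float).astype(bool)
    if event.sum() == 0:
        raise FitError(f"{family}: no events in dataset — refusing to fit")
    X = _design(dataset, covariates)
    kernel, nshape, shape_names = _KERNELS[family]

    # moment-based starting values on log time
    logt_ev = np.log(t[event])
    mu0, sd0 = float(logt_ev.mean()), float(max(logt_ev.std(), 0.2))
    if family == "exponential":
        rate0 = event.sum() / t.sum()
        x0 = np.r_[np.log(rate0), np.zeros(len(covariates))]
    elif family == "weibull":
        x0 = np.r_[np.log(1.0 / max(sd0, 0.3)), mu0, np.zeros(len(covariates))]
    elif family == "lognormal":
        x0 = np.r_[np.log(sd0), mu0, np.zeros(len(covariates))]
    else:  # generalized gamma: start at the lognormal interior point
        x0 = np.r_[np.log(sd0), 0.3, mu0, np.zeros(len(covariates))]

    nll = lambda p: _neg_loglik_family(kernel, p, t, event, X, nshape)
    params, loglik, vcov = _fit(nll, x0, family)
    k = len(params)
    return TransitionModel(
        family=family,
        covariates=covariates,
        param_names=shape_names + ["intercept"] + [f"b_{c}" for c in covariates],
        params=params,
        vcov=vcov,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_obs=len(t),
        n_events=int(event.sum()),
    )


def fit_spline_odds(dataset: pd.DataFrame, df: int = 5,
                    covariates: list[str] | None = None) -> TransitionModel:
    """Flexible parametric model on the log cumulative-odds scale.

    log((1-S)/S) is a restricted (natural) cubic spline in log time with
    ``df`` degrees of freedom plus linear covariate effects; df=1 is the
    log-logistic (proportional-odds) model.  Knots sit at quantiles of the
    uncensored log event times.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    covariates = list(covariates or [])
    t = np.clip(dataset["time"].to_numpy(float), 1e-6, None)
    event = dataset["event"].to_numpy(float).astype(bool)
    if event.sum() == 0:
        raise FitError("spline_odds: no events in dataset — refusing to fit")
    knots = _spline_knots(t, event, df)
    X = _design(dataset, covariates)
    x = np.log(t)
    B = _spline_basis(x, knots)
    dB = _spline_basis(x, knots, deriv=True)
    ncoef = B.shape[1]  # df columns (x + df-1 internal-knot terms)

    def nll(p):
        gam0, gam, beta = p[0], p[1:1 + ncoef], p[1 + ncoef:]
        s = gam0 + B @ gam + X @ beta
        ds = dB @ gam  # d/d log t of the spline part
        if np.any(ds[event] <= 1e-10):
            return 1e10 + float(np.sum(np.clip(1e-6 - ds[event], 0, None)))
        with np.errstate(over="ignore"):
            # log S = -log(1+e^s); log f = log ds - log t + log F + log S
            log_s_surv = -np.logaddexp(0.0, s)
            log_f = np.log(np.clip(ds, 1e-300, None)) - x + s + 2.0 * log_s_surv
            ll = np.where(event, log_f, log_s_surv)
        if not np.all(np.isfinite(ll)):
            return 1e10
        return -float(ll.sum())

    # start from the log-logistic fit mapped onto the basis: odds linear in x
    mu0 = float(np.log(t[event]).mean())
    slope0 = 1.0 / max(float(np.log(t[event]).std()), 0.2)
    x0 = np.r_[-slope0 * mu0, slope0, np.zeros(ncoef - 1), np.zeros(len(covariates))]
    params, loglik, vcov = _fit(nll, x0, "spline_odds")
    k = len(params)
    return TransitionModel(
        family="spline_odds",
        covariates=covariates,
        param_names=[f"gamma_{i}" for i in range(ncoef + 1)] + [f"b_{c}" for c in covariates],
        params=params,
        vcov=vcov,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_obs=len(t),
        n_events=int(event.sum()),
        knots=knots,
    )


def select_model(fits: list[TransitionModel]) -> TransitionModel:
    """Minimum-AIC model; ties broken by fewer parameters, then the fixed
    family order exponential < weibull < lognormal < generalised gamma <
    spline."""
    if not fits:
        raise ValueError("select_model: empty list of fits")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    return min(
        fits,
        key=lambda m: (round(m.aic, 9), len(m.params), order.get(m.family, 99)),
    )


# ---------------------------------------------------------------------------
# risk-set dataset builders (durations converted days -> years)
# ---------------------------------------------------------------------------

def _profile_map(profiles: pd.DataFrame) -> dict[str, dict]:
    return {str(r["patient_id"]): dict(r) for _, r in profiles.iterrows()}


def encode_covariates(profile: dict) -> dict:
    """Numeric covariate encoding shared by all transition models."""
    return {
        "arm_aap": 1.0 if profile.get("arm") == "AAP_SOC" else 0.0,
        "base_hs2": 1.0 if profile.get("baseline_state") == "HS2" else 0.0,
        "base_hs3": 1.0 if profile.get("baseline_state") == "HS3" else 0.0,
        "age_60_69": 1.0 if profile.get("age_group") == "60-69" else 0.0,
        "age_70plus": 1.0 if profile.get("age_group") == ">=70" else 0.0,
        "who_1_2": 1.0 if profile.get("who_status") == "1-2" else 0.0,
        "nodal_pos": 1.0 if profile.get("nodal_stage") == "N+" else 0.0,
        "england": float(profile.get("england", 0)),
        "era_post2013": float(profile.get("era_post2013", 0)),
    }


def build_first_event_dataset(histories: list[EventHistory],
                              profiles: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: time (years) to first exit from the naive state
    (failure-free survival event, destinations HS4/5/7/8), censored at
    other-cause death or end of follow-up."""
    pmap = _profile_map(profiles)
    rows = []
    for h in histories:
        prof = pmap[h.patient_id]
        if len(h.records) > 1:
            dest, day = h.records[1]
            if dest is HealthState.HS9:
                event, dest_name, time = 0, None, day
            else:
                event, dest_name, time = 1, dest.name, day
        else:
            event, dest_name, time = 0, None, h.censor_day
        rows.append(
            dict(
                patient_id=h.patient_id,
                time=time / DAYS_PER_YEAR,
                event=event,
                dest=dest_name,
            )
            | encode_covariates(prof)
        )
    return pd.DataFrame(rows)


def build_transition_dataset(histories: list[EventHistory],
                             profiles: pd.DataFrame,
                             sources: set[HealthState],
                             targets: set[HealthState]) -> pd.DataFrame:
    """Clock-reset risk sets: one row per stay in a source state, event = 1
    when the stay ends in a target state, competing exits censor.  Adds the
    post-failure covariate ``failure_years`` (time from randomisation to
    first castration resistance)."""
    pmap = _profile_map(profiles)
    rows = []
    for h in histories:
        prof = pmap[h.patient_id]
        fail_day = None
        for i, (s, d) in enumerate(h.records):
            if fail_day is None and s in CRPC_STATES:
                fail_day = d
            if s not in sources:
                continue
            if i + 1 < len(h.records):
                nxt, nxt_day = h.records[i + 1]
                event = 1 if nxt in targets else 0
                stop = nxt_day
            else:
                event, stop = 0, h.censor_day
            rows.append(
                dict(
                    patient_id=h.patient_id,
                    from_state=s.name,
                    time=max(stop - d, 0.25) / DAYS_PER_YEAR,
                    event=event,
                    failure_years=(fail_day or d) / DAYS_PER_YEAR,
                )
                | encode_covariates(prof)
            )
    return pd.DataFrame(rows)


def build_other_cause_dataset(histories: list[EventHistory],
                              profiles: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: time to other-cause death (HS9), censored at
    prostate-cancer death or end of follow-up."""
    pmap = _profile_map(profiles)
    rows = []
    for h in histories:
        prof = pmap[h.patient_id]
        last, last_day = h.records[-1]
        event = 1 if last is HealthState.HS9 else 0
        time = last_day if last.is_dead else h.censor_day
        rows.append(
            dict(patient_id=h.patient_id, time=max(time, 0.25) / DAYS_PER_YEAR,
                 event=event)
            | encode_covariates(prof)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# first-event destination allocation
# ---------------------------------------------------------------------------

@dataclass
class DestinationModel:
    """Saturated multinomial model for the first-event destination given
    baseline state and randomised arm (Laplace-smoothed frequencies)."""

    probs: dict  # (baseline_state, arm) -> {dest: prob}

    _STRUCTURAL = {
        "HS1": ("HS4", "HS5", "HS7", "HS8"),
        "HS2": ("HS5", "HS7", "HS8"),
        "HS3": ("HS7", "HS8"),
    }

    @classmethod
    def fit(cls, first_event: pd.DataFrame, profiles: pd.DataFrame,
            alpha: float = 0.5) -> "DestinationModel":
        df = first_event.merge(
            profiles[["patient_id", "baseline_state", "arm"]], on="patient_id"
        )
        ev = df[df.event == 1]
        probs = {}
        for base, dests in cls._STRUCTURAL.items():
            for arm in ("AAP_SOC", "SOC"):
                sub = ev[(ev.baseline_state == base) & (ev.arm == arm)]
                counts = np.array(
                    [float((sub.dest == d).sum()) + alpha for d in dests]
                )
                probs[(base, arm)] = dict(zip(dests, counts / counts.sum()))
        return cls(probs=probs)

    def sample(self, baseline_state: str, arm: str,
               rng: np.random.Generator) -> HealthState:
        table = self.probs[(baseline_state, arm)]
        dests = list(table)
        return HealthState[rng.choice(dests, p=[table[d] for d in dests])]

    def to_dict(self) -> dict:
        return {"|".join(k): v for k, v in self.probs.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "DestinationModel":
        return cls(probs={tuple(k.split("|")): v for k, v in d.items()})


# ---------------------------------------------------------------------------
# the nine-model plan
# ---------------------------------------------------------------------------

MODEL_GROUP_PLAN = {
    "first_event": ["HS1->HS4", "HS1->HS5", "HS1->HS7", "HS1->HS8",
                    "HS2->HS5", "HS2->HS7", "HS2->HS8",
                    "HS3->HS7", "HS3->HS8"],
    "other_cause": [f"HS{i}->HS9" for i in range(1, 8)],
    "to_hs7": ["HS4->HS7", "HS5->HS7", "HS6->HS7"],
    "hs4_hs5": ["HS4->HS5"],
    "hs5_hs6": ["HS5->HS6"],
    "hs4_hs8": ["HS4->HS8"],
    "hs5_hs8": ["HS5->HS8"],
    "hs6_hs8": ["HS6->HS8"],
    "hs7_hs8": ["HS7->HS8"],
}

_FIRST_EVENT_COVS = ["arm_aap", "base_hs2", "base_hs3", "who_1_2", "nodal_pos",
                     "england", "era_post2013"]
_OTHER_CAUSE_COVS = ["age_60_69", "age_70plus"]
_POST_COVS = ["arm_aap", "failure_years"]


@dataclass
class ModelSuite:
    """The nine fitted transition models plus the destination allocator."""

    models: dict[str, TransitionModel]
    destination: DestinationModel

    def __post_init__(self):
        missing = set(MODEL_GROUP_PLAN) - set(self.models)
        if missing:
            raise ValueError(f"ModelSuite missing model groups: {sorted(missing)}")

    def to_json(self, path) -> None:
        payload = dict(
            models={k: m.to_dict() for k, m in self.models.items()},
            destination=self.destination.to_dict(),
        )
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ModelSuite":
        d = json.loads(Path(path).read_text())
        return cls(
            models={k: TransitionModel.from_dict(v) for k, v in d["models"].items()},
            destination=DestinationModel.from_dict(d["destination"]),
        )


def _fit_group(dataset: pd.DataFrame, covariates: list[str],
               families: tuple[str, ...], spline_df: int | None,
               group: str) -> TransitionModel:
    fits, errors = [], []
    for fam in families:
        try:
            fits.append(fit_parametric(dataset, fam, covariates))
        except FitError as e:
            errors.append(str(e))
    if spline_df is not None:
        try:
            fits.append(fit_spline_odds(dataset, df=spline_df, covariates=covariates))
        except FitError as e:
            errors.append(str(e))
    if not fits:
        raise FitError(f"group {group}: no family converged ({errors})")
    best = select_model(fits)
    best.transition_group = MODEL_GROUP_PLAN[group]
    return best


def fit_model_suite(histories: list[EventHistory], profiles: pd.DataFrame,
                    families: tuple[str, ...] = ("exponential", "weibull"),
                    first_event_spline_df: int | None = 5) -> ModelSuite:
    """Fit the nine model groups and the destination allocator.

    The joint first-event model additionally offers the 5-df spline on the
    log cumulative-odds scale (the scale on which flexible parametric fits
    of failure-free survival are usually best); every group is selected by
    AIC over the candidate families.
    """
    hs = HealthState
    first = build_first_event_dataset(histories, profiles)
    models = {
        "first_event": _fit_group(first, _FIRST_EVENT_COVS, families,
                                  first_event_spline_df, "first_event"),
        "other_cause": _fit_group(
            build_other_cause_dataset(histories, profiles),
            _OTHER_CAUSE_COVS, families, None, "other_cause"),
        "to_hs7": _fit_group(
            build_transition_dataset(histories, profiles,
                                     {hs.HS4, hs.HS5, hs.HS6}, {hs.HS7}),
            _POST_COVS, families, None, "to_hs7"),
    }
    singles = {
        "hs4_hs5": ({hs.HS4}, {hs.HS5}),
        "hs5_hs6": ({hs.HS5}, {hs.HS6}),
        "hs4_hs8": ({hs.HS4}, {hs.HS8}),
        "hs5_hs8": ({hs.HS5}, {hs.HS8}),
        "hs6_hs8": ({hs.HS6}, {hs.HS8}),
        "hs7_hs8": ({hs.HS7}, {hs.HS8}),
    }
    for name, (src, dst) in singles.items():
        ds = build_transition_dataset(histories, profiles, src, dst)
        models[name] = _fit_group(ds, _POST_COVS, families, None, name)
    return ModelSuite(
        models=models,
        destination=DestinationModel.fit(first, profiles),
    )
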