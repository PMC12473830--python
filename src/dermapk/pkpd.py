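"""Population pharmacodynamics: sigmoid Emax with log-normal BSV.

Structural model (direct response, exposure C from the PBPK simulation):

    Effect = E0 + Emax * C^n / (EC50^n + C^n)

Residual variability is proportional, y = f * (1 + b * eps) with
eps ~ N(0, 1), i.e. y | f ~ N(f, (b f)^2).  Between-subject variability is
multiplicative log-normal, theta_i = theta_pop * exp(eta_i) with
eta_i ~ N(0, omega^2) per parameter.

Estimation is a deterministic nested optimisation: for candidate
population parameters each subject's empirical Bayes estimate (EBE,
posterior mode of eta) is found, and the marginal -2 log-likelihood (OFV)
is formed by the Laplace approximation around that mode; a Nelder-Mead
search then minimises the OFV over (theta_pop, omega^2, b).  The
contract — monotone OFV, EBE definition, information criteria — does not
depend on the optimiser choice.

Diagnostics: individual weighted residuals IWRES = (y - f_i)/(b f_i),
simulation-based normalized prediction distribution errors (NPDE), visual
predictive checks (VPC) and EBE summaries by formulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import InvalidInputError, ModelConfigError

__all__ = [
    "EmaxParams",
    "ErrorModel",
    "PopulationModel",
    "SubjectRecord",
    "ModelSelectionReport",
    "emax_effect",
    "individual_neg2ll",
    "estimate_ebes",
    "fit_population",
    "information_criteria",
    "vpc",
    "band_coverage",
    "residual_diagnostics",
    "ebe_by_formulation",
]

STRUCTURAL_PARAMS = ("emax", "ec50", "e0", "n")


@dataclass(frozen=True)
class EmaxParams:
    """Structural Emax parameters; Emax may be negative (responses that shrink)."""

    emax: float
    ec50: float
    e0: float
    n: float = 1.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ModelConfigError("ec50 must be > 0")
        if self.n <= 0:
            raise ModelConfigError("Hill coefficient n must be > 0")

    def with_eta(self, eta: Mapping[str, float]) -> "EmaxParams":
        """Individual parameters theta_i = theta_pop * exp(eta)."""
        kwargs = {}
        for name in STRUCTURAL_PARAMS:
            v = getattr(self, name)
            kwargs[name] = v * math.exp(eta.get(name, 0.0))
        return EmaxParams(**kwargs)


@dataclass(frozen=True)
class ErrorModel:
    """Proportional residual error y = f + b * f^c * eps with c fixed at 1."""

    b: float
    c: float = 1.0

    def __post_init__(self):
        if self.b <= 0:
            raise ModelConfigError("proportional error parameter b must be > 0")
        if self.c != 1.0:
            raise ModelConfigError("exponent c is fixed at 1")


@dataclass(frozen=True)
class PopulationModel:
    """Population fixed effects, BSV variances (log scale) and error model."""

    theta_pop: EmaxParams
    omega2: Mapping[str, float]
    error: ErrorModel
    sigmoidicity: bool = True

    def __post_init__(self):
        bad = set(self.omega2) - set(STRUCTURAL_PARAMS)
        if bad:
            raise ModelConfigError(f"unknown BSV parameters {sorted(bad)}")
        if any(v < 0 for v in self.omega2.values()):
            raise ModelConfigError("omega2 entries must be >= 0")
        if not self.sigmoidicity and self.theta_pop.n != 1.0:
            raise ModelConfigError("sigmoidicity off requires n = 1")
        object.__setattr__(self, "omega2", dict(self.omega2))

    @property
    def bsv_params(self) -> tuple[str, ...]:
        return tuple(p for p in STRUCTURAL_PARAMS if self.omega2.get(p, 0.0) > 0)


@dataclass
class SubjectRecord:
    """One subject's observations with the exposure series driving them."""

    subject_id: str
    formulation: str
    times: np.ndarray
    observations: np.ndarray
    exposure: np.ndarray  # ug/mL, aligned with times
    eta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.observations = np.asarray(self.observations, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if not (self.times.shape == self.observations.shape == self.exposure.shape):
            raise ModelConfigError("times, observations and exposure must align")
        if np.any(self.observations <= 0):
            raise ModelConfigError("observations must be > 0 under proportional error")
        if np.any(self.exposure < 0):
            raise ModelConfigError("exposure must be >= 0")


@dataclass
class ModelSelectionReport:
    """OFV and information criteria; AIC = OFV + 2P exactly."""

    ofv: float
    aic: float
    bic: float
    bicc: float
    n_parameters: int
    n_subjects: int
    n_observations: int

    def to_dict(self) -> dict:
        return {
            "ofv": self.ofv,
            "aic": self.aic,
            "bic": self.bic,
            "bicc": self.bicc,
            "n_parameters": self.n_parameters,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
        }


def emax_effect(params: EmaxParams, c) -> np.ndarray | float:
    """Sigmoid Emax effect at concentration(s) c (>= 0)."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise InvalidInputError("concentration must be finite and >= 0")
    with np.errstate(over="ignore", invalid="ignore"):
        cn = arr ** params.n
        out = params.e0 + params.emax * cn / (params.ec50 ** params.n + cn)
        # saturated limit where c^n overflows
        out = np.where(np.isfinite(cn), out, params.e0 + params.emax)
    return float(out) if np.isscalar(c) else out


def individual_neg2ll(record: SubjectRecord, params: EmaxParams, error: ErrorModel) -> float:
    """-2 log-likelihood of one subject's data under y ~ N(f, (b f)^2)."""
    f = emax_effect(params, record.exposure)
    if np.any(f <= 0):
        raise InvalidInputError("model prediction f <= 0: proportional error undefined")
    sd = error.b * f
    with np.errstate(over="ignore", divide="ignore"):
        z = (record.observations - f) / sd
        return float(np.sum(np.log(2.0 * np.pi) + 2.0 * np.log(sd) + z * z))


def _eta_objective(record, pop, names):
    """Joint -2 log posterior (up to a constant): neg2ll + sum eta^2/omega^2."""
    om2 = np.array([pop.omega2[n] for n in names])

    def g(eta_vec):
        eta = dict(zip(names, eta_vec))
        try:
            n2 = individual_neg2ll(record, pop.theta_pop.with_eta(eta), pop.error)
        except (InvalidInputError, OverflowError):
            return 1e12
        return n2 + float(np.sum(np.asarray(eta_vec) ** 2 / om2))

    return g


def estimate_ebes(
    record: SubjectRecord, pop: PopulationModel, x0: Sequence[float] | None = None
) -> tuple[dict, EmaxParams]:
    """Empirical Bayes (post hoc) estimate of a subject's random effects.

    Maximises the individual posterior, i.e. minimises
    ``individual_neg2ll(theta_pop * e^eta) + sum(eta^2 / omega^2)``.
    Parameters with omega^2 = 0 are pinned at eta = 0 (complete shrinkage).
    """
    names = pop.bsv_params
    if not names:
        return {}, pop.theta_pop
    g = _eta_objective(record, pop, names)
    start = np.zeros(len(names)) if x0 is None else np.asarray(x0, dtype=float)
    res = optimize.minimize(
        g, start, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000}
    )
    x = res.x if res.fun <= g(start) else start
    if not res.success and res.fun > g(start):
        warnings.warn(f"EBE optimisation failed for {record.subject_id}; using eta = 0")
        x = np.zeros(len(names))
    eta = dict(zip(names, (float(v) for v in x)))
    return eta, pop.theta_pop.with_eta(eta)


def _newton_mode(g, x0, max_iter=12, tol=1e-8, fd_h=1e-4):
    """Damped Newton search for the mode of a smooth low-dimensional objective.

    Returns (x, hessian_at_x).  Finite-difference derivatives; steps that
    do not decrease g are halved (up to 8 times) before giving up.
    """
    x = np.asarray(x0, dtype=float).copy()
    k = len(x)
    f = g(x)
    hess = np.eye(k)
    for _ in range(max_iter):
        grad = np.empty(k)
        for i in range(k):
            xp, xm = x.copy(), x.copy()
            xp[i] += fd_h
            xm[i] -= fd_h
            grad[i] = (g(xp) - g(xm)) / (2 * fd_h)
        hess = _numeric_hessian(g, x, h=fd_h)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(k), -grad)
        except np.linalg.LinAlgError:
            step = -grad
        if not np.all(np.isfinite(step)):
            step = -grad
        scale = 1.0
        for _ in range(10):
            f_new = g(x + scale * step)
            if f_new < f:
                break
            scale *= 0.5
        else:
            # Newton direction failed: backtrack along the (normalised)
            # steepest-descent direction before giving up
            gn = np.linalg.norm(grad)
            if gn == 0:
                break
            step = -grad / gn
            scale = 1.0
            for _ in range(20):
                f_new = g(x + scale * step)
                if f_new < f:
                    break
                scale *= 0.5
            else:
                break
        x = x + scale * step
        if abs(f - f_new) < tol * (1.0 + abs(f)):
            f = f_new
            break
        f = f_new
    return x, _numeric_hessian(g, x, h=fd_h)


def _laplace_subject_ofv(record, pop, eta_start=None):
    """Laplace-approximated -2 log marginal likelihood of one subject."""
    names = pop.bsv_params
    if not names:
        return individual_neg2ll(record, pop.theta_pop, pop.error), {}
    g = _eta_objective(record, pop, names)
    k = len(names)
    x, h = _newton_mode(g, np.zeros(k))
    if eta_start is not None and np.any(np.asarray(eta_start) != 0.0):
        x2, h2 = _newton_mode(g, np.asarray(eta_start, dtype=float))
        if g(x2) < g(x):
            x, h = x2, h2
    eta = dict(zip(names, (float(v) for v in x)))
    # -2 log marg ~= g(eta_hat) + sum log(2 pi w^2) - k log(2 pi) + log|H|
    # with H the Hessian of g/2; derived for g = neg2ll + eta' Om^-1 eta:
    #   -2 log L = g(x) + sum_j log(2 pi w_j^2) - k log(2 pi) + log det(0.5 * H_g)
    hh = 0.5 * h
    sign, logdet = np.linalg.slogdet(hh)
    if sign <= 0:
        # fall back to a diagonal-regularised Hessian
        hh = hh + np.eye(k) * (1e-8 + abs(hh.diagonal().min()))
        sign, logdet = np.linalg.slogdet(hh)
    const = sum(math.log(2.0 * math.pi * pop.omega2[n]) for n in names) - k * math.log(2.0 * math.pi)
    return float(g(x) + const + logdet), eta


def _numeric_hessian(func, x, h=1e-4):
    k = len(x)
    hess = np.zeros((k, k))
    f0 = func(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                hess[i, i] = (func(xp) - 2 * f0 + func(xm)) / h**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += h
                xmm[[i, j]] -= h
                xpm[i] += h
                xpm[j] -= h
                xmp[i] -= h
                xmp[j] += h
                hess[i, j] = hess[j, i] = (func(xpp) - func(xpm) - func(xmp) + func(xmm)) / (4 * h**2)
    return hess


def total_ofv(data: Sequence[SubjectRecord], pop: PopulationModel, eta_cache: dict | None = None) -> float:
    """Laplace marginal OFV summed over subjects."""
    total = 0.0
    for rec in data:
        start = None
        if eta_cache is not None and rec.subject_id in eta_cache:
            start = [eta_cache[rec.subject_id].get(n, 0.0) for n in pop.bsv_params]
        ofv_i, eta = _laplace_subject_ofv(rec, pop, eta_start=start)
        if eta_cache is not None:
            eta_cache[rec.subject_id] = eta
        total += ofv_i
    return total


def information_criteria(
    ofv: float,
    n_parameters: int,
    n_subjects: int,
    n_observations: int,
    n_obs_level_parameters: int = 1,
) -> ModelSelectionReport:
    """AIC/BIC/BICc from the OFV.

    BICc splits the penalty: subject-level parameters (fixed effects and
    omega^2) are penalised by ln(n_subjects), observation-level parameters
    (the residual-error parameter) by ln(n_observations).
    """
    if n_parameters < 0 or n_subjects <= 0 or n_observations <= 0:
        raise InvalidInputError("counts must be positive")
    n_obs_level = min(n_obs_level_parameters, n_parameters)
    n_subj_level = n_parameters - n_obs_level
    aic = ofv + 2.0 * n_parameters
    bic = ofv + n_parameters * math.log(n_subjects)
    bicc = ofv + n_subj_level * math.log(n_subjects) + n_obs_level * math.log(n_observations)
    return ModelSelectionReport(
        ofv=ofv,
        aic=aic,
        bic=bic,
        bicc=bicc,
        n_parameters=n_parameters,
        n_subjects=n_subjects,
        n_observations=n_observations,
    )


def _pack(pop: PopulationModel, fit_omega: tuple[str, ...]):
    """Transform population parameters to an unconstrained vector."""
    th = pop.theta_pop
    signs = {"emax": math.copysign(1.0, th.emax)}
    x = [math.log(abs(th.emax)), math.log(th.ec50), math.log(th.e0)]
    names = ["emax", "ec50", "e0"]
    if pop.sigmoidicity:
        x.append(math.log(th.n))
        names.append("n")
    for p in fit_omega:
        x.append(math.log(pop.omega2[p]))
        names.append(f"omega2_{p}")
    x.append(math.log(pop.error.b))
    names.append("b")
    return np.array(x), names, signs


def _unpack(x, names, signs, template: PopulationModel) -> PopulationModel:
    vals = dict(zip(names, x))
    th = {
        "emax": signs["emax"] * math.exp(vals["emax"]),
        "ec50": math.exp(vals["ec50"]),
        "e0": math.exp(vals["e0"]),
        "n": math.exp(vals["n"]) if "n" in vals else 1.0,
    }
    omega2 = dict(template.omega2)
    for key, v in vals.items():
        if key.startswith("omega2_"):
            omega2[key[len("omega2_"):]] = math.exp(v)
    return PopulationModel(
        theta_pop=EmaxParams(**th),
        omega2=omega2,
        error=ErrorModel(b=math.exp(vals["b"])),
        sigmoidicity=template.sigmoidicity,
    )


def fit_population(
    data: Sequence[SubjectRecord],
    init: PopulationModel,
    seed: int | None = None,
    max_iter: int = 400,
    n_starts: int = 1,
) -> dict:
    """Estimate population parameters by minimising the Laplace OFV.

    Returns a dict with keys ``model`` (fitted PopulationModel), ``ebes``
    (subject_id -> {"eta": ..., "params": EmaxParams}), ``report``
    (ModelSelectionReport), ``converged`` and ``ofv_trace`` (best-so-far,
    monotone non-increasing).
    """
    if len(data) < 2:
        raise ModelConfigError("at least two subjects are required")
    for rec in data:
        if len(rec.times) < 2:
            raise ModelConfigError(f"subject {rec.subject_id} needs >= 2 observations")

    fit_omega = init.bsv_params
    x0, names, signs = _pack(init, fit_omega)
    eta_cache: dict = {}
    trace: list[float] = []

    def objective(x):
        try:
            pop = _unpack(x, names, signs, init)
            val = total_ofv(data, pop, eta_cache)
        except (ModelConfigError, InvalidInputError, OverflowError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [x0 + rng.normal(0.0, 0.3, size=len(x0)) for _ in range(n_starts - 1)]
    best = None
    for s in starts:
        res = optimize.minimize(
            objective,
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": max_iter, "maxfev": 4 * max_iter,
                     "adaptive": True},
        )
        # restart the simplex at the incumbent: plain Nelder-Mead is prone
        # to premature collapse in >4 dimensions
        for _ in range(4):
            res2 = optimize.minimize(
                objective,
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": max_iter,
                         "maxfev": 4 * max_iter, "adaptive": True},
            )
            improved = res.fun - res2.fun
            res = res2 if res2.fun < res.fun else res
            if improved < 0.1:
                break
        if best is None or res.fun < best.fun:
            best = res

    pop = _unpack(best.x, names, signs, init)
    ebes = {}
    for rec in data:
        eta, params = estimate_ebes(
            rec, pop, x0=[eta_cache.get(rec.subject_id, {}).get(n, 0.0) for n in pop.bsv_params]
        )
        rec.eta = eta
        ebes[rec.subject_id] = {"eta": eta, "params": params, "formulation": rec.formulation}
    ofv = total_ofv(data, pop, eta_cache)
    n_obs = int(sum(len(r.times) for r in data))
    n_fixed = 4 if pop.sigmoidicity else 3
    n_params = n_fixed + len(fit_omega) + 1
    report = information_criteria(ofv, n_params, len(data), n_obs)
    return {
        "model": pop,
        "ebes": ebes,
        "report": report,
        "converged": bool(best.success),
        "ofv_trace": trace,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Simulation-based diagnostics
# ---------------------------------------------------------------------------


def _simulate_observations(pop, exposure, rng, n_subjects, resample_counter=None):
    """Simulate one replicate dataset: (n_subjects, n_times) responses.

    Random-effect draws whose predicted response is non-positive anywhere
    are resampled (the model is only meaningful for positive responses);
    ``resample_counter`` (a one-element list) accumulates how often.
    """
    names = pop.bsv_params
    c = np.asarray(exposure, dtype=float)
    out = np.empty((n_subjects, len(c)))
    for i in range(n_subjects):
        for _ in range(1000):
            eta = {p: rng.normal(0.0, math.sqrt(pop.omega2[p])) for p in names}
            f = emax_effect(pop.theta_pop.with_eta(eta), c)
            if np.all(f > 0):
                break
            if resample_counter is not None:
                resample_counter[0] += 1
        else:
            raise InvalidInputError("predicted response non-positive for every eta draw")
        y = f * (1.0 + pop.error.b * rng.standard_normal(len(c)))
        bad = y <= 0
        n_guard = 0
        while np.any(bad):
            y[bad] = f[bad] * (1.0 + pop.error.b * rng.standard_normal(bad.sum()))
            bad = y <= 0
            n_guard += 1
            if n_guard > 1000:
                raise InvalidInputError("cannot simulate positive observations")
        out[i] = y
    return out


def vpc(
    pop: PopulationModel,
    times: Sequence[float],
    exposure: Sequence[float],
    n_subjects: int,
    n_replicates: int = 1000,
    percentiles: tuple[float, ...] = (10.0, 50.0, 90.0),
    ci: float = 0.90,
    seed: int | None = None,
) -> pd.DataFrame:
    """Visual predictive check: percentile trajectories with confidence bands.

    Simulates ``n_replicates`` datasets of ``n_subjects`` under the model;
    for each time point returns each requested percentile of the simulated
    observations (point estimate = median across replicates) and its
    ``ci`` confidence interval across replicates.
    """
    if n_replicates < 100:
        raise ModelConfigError("n_replicates must be >= 100")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    counter = [0]
    # replicate x subject x time
    sims = np.stack(
        [_simulate_observations(pop, exposure, rng, n_subjects, counter) for _ in range(n_replicates)]
    )
    if counter[0]:
        warnings.warn(f"vpc: resampled {counter[0]} random-effect draws with non-positive response")
    lo_q, hi_q = 50.0 * (1.0 - ci), 50.0 * (1.0 + ci)
    rows = []
    for pct in percentiles:
        per_rep = np.percentile(sims, pct, axis=1)  # replicate x time
        rows.append(
            pd.DataFrame(
                {
                    "time_h": t,
                    "percentile": pct,
                    "value": np.median(per_rep, axis=0),
                    "ci_lower": np.percentile(per_rep, lo_q, axis=0),
                    "ci_upper": np.percentile(per_rep, hi_q, axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulated_band(
    pop: PopulationModel,
    exposure: Sequence[float],
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    n_replicates: int = 1000,
    n_subjects: int = 20,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted observation band between two percentiles, per time point."""
    rng = np.random.default_rng(seed)
    counter = [0]
    sims = np.stack(
        [_simulate_observations(pop, exposure, rng, n_subjects, counter) for _ in range(n_replicates)]
    ).reshape(-1, len(exposure))
    if counter[0]:
        warnings.warn(
            f"simulated_band: resampled {counter[0]} random-effect draws with non-positive response"
        )
    return np.percentile(sims, lower_pct, axis=0), np.percentile(sims, upper_pct, axis=0)


def band_coverage(data: Sequence[SubjectRecord], lower: np.ndarray, upper: np.ndarray) -> float:
    """Fraction of observations inside a per-time band (all subjects share times)."""
    inside = total = 0
    for rec in data:
        inside += int(np.sum((rec.observations >= lower) & (rec.observations <= upper)))
        total += len(rec.observations)
    return inside / total


def residual_diagnostics(
    data: Sequence[SubjectRecord],
    pop: PopulationModel,
    ebes: Mapping[str, dict],
    seed: int | None = None,
    n_sim: int = 500,
) -> pd.DataFrame:
    """IWRES and NPDE series with population and individual predictions.

    NPDE uses the simulation rank transform: each observation's rank among
    ``n_sim`` model-simulated counterparts, mapped through the inverse
    normal CDF ((r + 0.5)/(K + 1)); approximately N(0,1) under the model.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for rec in data:
        params_i = ebes[rec.subject_id]["params"]
        f_ind = emax_effect(params_i, rec.exposure)
        f_pop = emax_effect(pop.theta_pop, rec.exposure)
        iwres = (rec.observations - f_ind) / (pop.error.b * f_ind)
        sims = _simulate_observations(pop, rec.exposure, rng, n_sim)  # n_sim x n_times
        rank = (sims < rec.observations[None, :]).sum(axis=0)
        npde = stats.norm.ppf((rank + 0.5) / (n_sim + 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "formulation": rec.formulation,
                    "time_h": rec.times,
                    "observation": rec.observations,
                    "pred_population": f_pop,
                    "pred_individual": f_ind,
                    "iwres": iwres,
                    "npde": npde,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def ebe_by_formulation(ebes: Mapping[str, dict], parameter_name: str) -> pd.DataFrame:
    """Median and IQR of individual parameter values, grouped by formulation."""
    if parameter_name not in STRUCTURAL_PARAMS:
        raise ModelConfigError(f"unknown parameter {parameter_name!r}")
    rows: dict[str, list[float]] = {}
    for info in ebes.values():
        rows.setdefault(info["formulation"], []).append(getattr(info["params"], parameter_name))
    records = []
    for form, vals in sorted(rows.items()):
        if not vals:
            warnings.warn(f"formulation {form!r} has no subjects; omitted")
            continue
        v = np.asarray(vals)
        records.append(
            {
                "formulation": form,
                "parameter": parameter_name,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(records)
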