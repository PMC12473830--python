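"""Stepwise calibration and goodness-of-fit for the IVRT/IVPT models.

Stage 1 ("release") fits only the formulation release parameters
(DP/CP partition coefficient, DP/CP permeability, release lag) against
IVRT cumulative-release data, per formulation.  Stage 2 ("skin") fits
only the gel/SC partition coefficient and the dermis-involving partition
coefficients against IVPT tissue accumulations, pooled across
formulations, while the stage-1 results are used as-is.  This stepwise
separation keeps the number of tuned parameters minimal and prevents the
skin fit from absorbing formulation effects.

Model agreement is scored by a six-metric battery: RMSE, MAPE, average
fold error (AFE, geometric-mean fold), bias, R^2 (against the mean of the
observations; may be negative) and Pearson r.  Because below-LOQ
observations are stored as zero, MAPE and AFE are computed only over
pairs whose denominator is positive; ``n_points`` records how many pairs
each metric actually used.

Morris elementary-effects screening ranks parameter influence on a scalar
model output (mu* = mean absolute elementary effect, sigma = EE spread,
which flags nonlinearity/interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .core import ModelConfigError, InvalidInputError

__all__ = [
    "MetricsReport",
    "CalibrationSpec",
    "FitResult",
    "MorrisResult",
    "compute_metrics",
    "calibrate",
    "morris_screen",
    "RELEASE_PARAMS",
    "SKIN_PARAMS",
]

RELEASE_PARAMS = ("kp_dp_cp", "p_dp_cp", "release_lag")
SKIN_PARAMS = ("kp_cp_sc", "kp_ve_dm", "kp_sb_dm", "kp_dm_rec")


@dataclass
class MetricsReport:
    """Six-metric goodness-of-fit battery (plus the absolute AFE variant)."""

    rmse: float
    mape: float  # percent
    afe: float  # geometric-mean fold error, ideal 1
    aafe: float  # absolute average fold error, ideal 1
    bias: float
    r_squared: float
    pearson_r: float
    n_points: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mape_pct": self.mape,
            "afe": self.afe,
            "aafe": self.aafe,
            "bias": self.bias,
            "r_squared": self.r_squared,
            "pearson_r": self.pearson_r,
            "n_points": dict(self.n_points),
        }


def compute_metrics(pred: Sequence[float], obs: Sequence[float]) -> MetricsReport:
    """Score predictions against observations paired by time.

    MAPE uses pairs with obs > 0; AFE/AAFE use pairs with both values > 0
    (zeros arise from below-LOQ substitution and would blow up the ratio).
    A metric with fewer than two valid pairs is reported as NaN, never 0.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise InvalidInputError("pred and obs must be 1-D and equally long")
    if len(p) < 2:
        raise InvalidInputError("at least two pairs are required")
    if np.any(~np.isfinite(p)) or np.any(~np.isfinite(o)):
        raise InvalidInputError("pred and obs must be finite")

    n_all = len(p)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    bias = float(np.mean(p - o))

    mask_mape = o > 0
    mape = (
        float(100.0 * np.mean(np.abs(p[mask_mape] - o[mask_mape]) / o[mask_mape]))
        if mask_mape.sum() >= 2
        else float("nan")
    )
    mask_fold = (o > 0) & (p > 0)
    if mask_fold.sum() >= 2:
        logf = np.log10(p[mask_fold] / o[mask_fold])
        afe = float(10.0 ** np.mean(logf))
        aafe = float(10.0 ** np.mean(np.abs(logf)))
    else:
        afe = aafe = float("nan")

    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if np.std(p) > 0 and np.std(o) > 0:
        pearson_r = float(stats.pearsonr(p, o)[0])
    else:
        pearson_r = float("nan")

    return MetricsReport(
        rmse=rmse,
        mape=mape,
        afe=afe,
        aafe=aafe,
        bias=bias,
        r_squared=r_squared,
        pearson_r=pearson_r,
        n_points={
            "rmse": n_all,
            "bias": n_all,
            "r_squared": n_all,
            "pearson_r": n_all,
            "mape": int(mask_mape.sum()),
            "afe": int(mask_fold.sum()),
        },
    )


@dataclass
class CalibrationSpec:
    """What a calibration stage may touch and what it fits against.

    ``free_parameters`` maps name -> (lower, upper, start).  The release
    stage may free only the formulation release parameters; the skin
    stage only the CP->SC and dermis-involving partition coefficients.
    """

    stage: str  # "release" | "skin"
    free_parameters: Mapping[str, tuple[float, float, float]]
    fixed_parameters: Mapping[str, float] = field(default_factory=dict)
    objective: str = "sse"  # "sse" | "weighted_sse" (weights 1/obs^2 over obs>0)
    log_scale: tuple[str, ...] = ()  # parameters searched on log10 scale

    def __post_init__(self):
        allowed = {"release": set(RELEASE_PARAMS), "skin": set(SKIN_PARAMS)}
        if self.stage not in allowed:
            raise ModelConfigError("stage must be 'release' or 'skin'")
        bad = set(self.free_parameters) - allowed[self.stage]
        if bad:
            raise ModelConfigError(
                f"stage={self.stage!r} may not free {sorted(bad)}; "
                f"allowed: {sorted(allowed[self.stage])}"
            )
        if self.objective not in ("sse", "weighted_sse"):
            raise ModelConfigError("objective must be 'sse' or 'weighted_sse'")
        for name, (lo, hi, x0) in self.free_parameters.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and np.isfinite(x0)):
                raise ModelConfigError(f"bounds/start for {name!r} must be finite")
            if not lo <= x0 <= hi:
                raise ModelConfigError(f"start for {name!r} must lie within its bounds")


@dataclass
class FitResult:
    """Calibrated parameters with diagnostics and per-dataset metrics."""

    stage: str
    values: dict
    fixed: dict
    objective_value: float
    objective_initial: float
    bounds_hit: dict
    metrics: MetricsReport | None
    converged: bool
    n_evaluations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "values": dict(self.values),
            "fixed": dict(self.fixed),
            "objective_value": self.objective_value,
            "objective_initial": self.objective_initial,
            "bounds_hit": dict(self.bounds_hit),
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }


def calibrate(
    spec: CalibrationSpec,
    predictor: Callable[[dict], np.ndarray],
    observations: Sequence[float],
    seed: int | None = None,
    n_starts: int = 1,
    xatol: float = 1e-6,
    fatol: float = 1e-12,
    max_iter: int = 2000,
) -> FitResult:
    """Bounded derivative-free minimisation of the stage objective.

    ``predictor`` maps a full parameter dict (free, on natural scale,
    merged over the fixed ones) to a prediction vector aligned with
    ``observations``.  Nelder-Mead with box bounds; optional seeded
    multi-start samples extra starting points uniformly within bounds
    (log-uniform for log-scale parameters).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ModelConfigError("observations must be non-empty")
    names = list(spec.free_parameters)
    lo = np.array([spec.free_parameters[n][0] for n in names])
    hi = np.array([spec.free_parameters[n][1] for n in names])
    x0 = np.array([spec.free_parameters[n][2] for n in names])
    is_log = np.array([n in spec.log_scale for n in names])
    if np.any(is_log & (lo <= 0)):
        raise ModelConfigError("log-scale parameters need positive lower bounds")

    def to_internal(x):
        z = x.copy()
        z[is_log] = np.log10(z[is_log])
        return z

    def to_natural(z):
        x = z.copy()
        x[is_log] = 10.0 ** x[is_log]
        return x

    if spec.objective == "weighted_sse":
        w = np.where(obs > 0, 1.0 / np.maximum(obs, 1e-300) ** 2, 0.0)
    else:
        w = np.ones_like(obs)

    n_eval = 0

    def objective(z):
        nonlocal n_eval
        n_eval += 1
        params = dict(spec.fixed_parameters)
        params.update(dict(zip(names, to_natural(np.asarray(z)))))
        pred = np.asarray(predictor(params), dtype=float)
        if pred.shape != obs.shape:
            raise ModelConfigError("predictor output must align with observations")
        return float(np.sum(w * (pred - obs) ** 2))

    z_lo, z_hi = to_internal(lo), to_internal(hi)
    f0 = objective(to_internal(x0))
    if not np.isfinite(f0):
        raise ModelConfigError("objective is non-finite at the starting point")

    starts = [to_internal(x0)]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [rng.uniform(z_lo, z_hi) for _ in range(n_starts - 1)]

    best = None
    for z_start in starts:
        res = optimize.minimize(
            objective,
            z_start,
            method="Nelder-Mead",
            bounds=list(zip(z_lo, z_hi)),
            options={"xatol": xatol, "fatol": fatol, "maxiter": max_iter, "maxfev": 4 * max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    # never report worse than the start
    if f0 < best.fun:
        z_best, f_best, ok = to_internal(x0), f0, True
    else:
        z_best, f_best, ok = np.asarray(best.x), float(best.fun), bool(best.success)

    x_best = to_natural(z_best)
    values = dict(zip(names, (float(v) for v in x_best)))
    span = np.maximum(hi - lo, 1e-300)
    bounds_hit = {
        n: bool((x_best[i] - lo[i]) / span[i] < 1e-3 or (hi[i] - x_best[i]) / span[i] < 1e-3)
        for i, n in enumerate(names)
    }
    final_params = dict(spec.fixed_parameters)
    final_params.update(values)
    pred = np.asarray(predictor(final_params), dtype=float)
    return FitResult(
        stage=spec.stage,
        values=values,
        fixed=dict(spec.fixed_parameters),
        objective_value=f_best,
        objective_initial=f0,
        bounds_hit=bounds_hit,
        metrics=compute_metrics(pred, obs) if len(obs) >= 2 else None,
        converged=ok,
        n_evaluations=n_eval,
        seed=seed,
    )


@dataclass
class MorrisResult:
    """Elementary-effects screening summary, one row per parameter."""

    parameters: tuple[str, ...]
    mu_star: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    n_trajectories: int
    levels: int
    seed: int | None
    n_dropped: int = 0

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mu_star)
        return [self.parameters[i] for i in order]

    def to_dict(self) -> dict:
        return {
            "parameters": list(self.parameters),
            "mu_star": [float(v) for v in self.mu_star],
            "sigma": [float(v) for v in self.sigma],
            "mu": [float(v) for v in self.mu],
            "n_trajectories": self.n_trajectories,
            "levels": self.levels,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
        }


def morris_screen(
    func: Callable[[dict], float],
    parameter_ranges: Mapping[str, tuple[float, float]],
    n_trajectories: int = 8,
    levels: int = 4,
    seed: int | None = None,
) -> MorrisResult:
    """Morris one-at-a-time screening on the unit hypercube.

    Parameters are scaled to [0, 1]; elementary effects are differences
    per unit step Delta = levels / (2 (levels - 1)), so an additive linear
    function f = a x (on its unit range) yields mu* = |a| and sigma ~ 0.
    Trajectories whose output is non-finite are dropped with a warning
    counter in the result.
    """
    if n_trajectories < 4:
        raise ModelConfigError("n_trajectories must be >= 4")
    if levels < 2 or levels % 2:
        raise ModelConfigError("levels must be an even integer >= 2")
    names = list(parameter_ranges)
    k = len(names)
    lo = np.array([parameter_ranges[n][0] for n in names], dtype=float)
    hi = np.array([parameter_ranges[n][1] for n in names], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
        raise ModelConfigError("parameter ranges must be finite with hi > lo")

    delta = levels / (2.0 * (levels - 1))
    base_levels = np.arange(levels // 2) / (levels - 1)  # values with x + delta <= 1
    rng = np.random.default_rng(seed)

    def evaluate(x_unit):
        params = dict(zip(names, lo + x_unit * (hi - lo)))
        return float(func(params))

    effects = [[] for _ in range(k)]
    n_dropped = 0
    for _ in range(n_trajectories):
        x = rng.choice(base_levels, size=k)
        direction = rng.choice([-1.0, 1.0], size=k)
        # mirror so every step stays inside [0, 1]
        x = np.where(direction < 0, x + delta, x)
        order = rng.permutation(k)
        traj_effects = {}
        y_prev = evaluate(x)
        ok = np.isfinite(y_prev)
        for idx in order:
            x_new = x.copy()
            x_new[idx] += direction[idx] * delta
            y_new = evaluate(x_new)
            if not np.isfinite(y_new):
                ok = False
                break
            traj_effects[idx] = (y_new - y_prev) / (direction[idx] * delta)
            x, y_prev = x_new, y_new
        if ok and len(traj_effects) == k:
            for idx, ee in traj_effects.items():
                effects[idx].append(ee)
        else:
            n_dropped += 1

    if n_dropped:
        import warnings

        warnings.warn(f"morris_screen: dropped {n_dropped} trajectories with non-finite output")
    if not all(effects):
        raise ModelConfigError("all trajectories dropped; cannot compute elementary effects")

    ee = np.array([np.asarray(e) for e in effects])
    return MorrisResult(
        parameters=tuple(names),
        mu_star=np.abs(ee).mean(axis=1),
        sigma=ee.std(axis=1, ddof=1) if ee.shape[1] > 1 else np.zeros(k),
        mu=ee.mean(axis=1),
        n_trajectories=n_trajectories,
        levels=levels,
        seed=seed,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Stage wiring: release fit per formulation, pooled skin fit across them.
# ---------------------------------------------------------------------------


def fit_release_parameters(
    profiles,
    form,
    cell,
    free: Mapping[str, tuple[float, float, float]] | None = None,
    objective: str = "sse",
    seed: int | None = None,
    n_starts: int = 1,
) -> FitResult:
    """Stage 1: fit (kp_dp_cp, p_dp_cp, release_lag) to IVRT release data.

    Replicate profiles are averaged point-wise (they must share a time
    grid); the simulation is evaluated on that grid.
    """
    from .ivrt import build_ivrt_system, simulate_release

    times = np.asarray(profiles[0].times, dtype=float)
    for p in profiles[1:]:
        if not np.allclose(p.times, times):
            raise ModelConfigError("replicate profiles must share a sampling grid")
    obs = np.mean([p.cumulative_amount_per_area for p in profiles], axis=0)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    take = np.searchsorted(t_grid, times)

    if free is None:
        free = {
            "kp_dp_cp": (1e-7, 1e-2, form.kp_dp_cp),
            "p_dp_cp": (1e-9, 1e-4, form.p_dp_cp),
            "release_lag": (0.0, 12.0, form.release_lag),
        }
    spec = CalibrationSpec(
        stage="release",
        free_parameters=free,
        fixed_parameters={},
        objective=objective,
        log_scale=tuple(n for n in free if n in ("kp_dp_cp", "p_dp_cp")),
    )

    def predictor(params):
        f = form.with_params(**{k: params[k] for k in free})
        prof = simulate_release(build_ivrt_system(f, cell), t_grid)
        return prof.cumulative_amount_per_area[take]

    return calibrate(spec, predictor, obs, seed=seed, n_starts=n_starts)


def fit_skin_parameters(
    accumulations: Mapping[str, Sequence],
    forms: Mapping[str, object],
    skin,
    transport,
    receptor_volume: float = 4.9,
    free: Mapping[str, tuple[float, float, float]] | None = None,
    objective: str = "sse",
    seed: int | None = None,
    n_starts: int = 1,
) -> FitResult:
    """Stage 2: fit the CP->SC and dermis partition coefficients.

    ``accumulations`` maps formulation name -> replicate TissueAccumulation
    collections; ``forms`` carries the stage-1-calibrated FormulationParams,
    which are consumed unchanged (the same skin parameter set is fitted
    once, pooled across all formulations).
    """
    from .ivpt import build_ivpt_system, layer_accumulation
    from .core import simulate

    if set(accumulations) - set(forms):
        raise ModelConfigError("every dataset needs its formulation parameters")

    if free is None:
        free = {
            "kp_cp_sc": (1.0, 1e4, transport.kp_cp_sc),
            "kp_ve_dm": (1e-3, 10.0, transport.kp_ve_dm),
            "kp_dm_rec": (1e-5, 1.0, transport.kp_dm_rec),
        }
    spec = CalibrationSpec(
        stage="skin",
        free_parameters=free,
        fixed_parameters={},
        objective=objective,
        log_scale=tuple(free),
    )

    form_names = sorted(accumulations)
    obs_blocks, grids, takes = [], {}, {}
    for name in form_names:
        reps = accumulations[name]
        times = np.asarray(reps[0].times, dtype=float)
        for r in reps[1:]:
            if not np.allclose(r.times, times):
                raise ModelConfigError("replicates must share a sampling grid")
        epi = np.mean([r.epidermis_amount_per_weight for r in reps], axis=0)
        dm = np.mean([r.dermis_amount_per_weight for r in reps], axis=0)
        obs_blocks.append(np.concatenate([epi, dm]))
        grid = np.unique(np.concatenate([[0.0], times]))
        grids[name] = grid
        takes[name] = np.searchsorted(grid, times)
    obs = np.concatenate(obs_blocks)

    def predictor(params):
        tr = transport.with_params(**{k: params[k] for k in free})
        blocks = []
        for name in form_names:
            system = build_ivpt_system(forms[name], skin, tr, receptor_volume)
            res = simulate(system, grids[name])
            acc = layer_accumulation(res, skin)
            take = takes[name]
            blocks.append(
                np.concatenate(
                    [acc.epidermis_amount_per_weight[take], acc.dermis_amount_per_weight[take]]
                )
            )
        return np.concatenate(blocks)

    return calibrate(spec, predictor, obs, seed=seed, n_starts=n_starts)
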