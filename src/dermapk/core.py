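"""General compartmental mass-transport engine.

Drug movement between well-mixed compartments follows the linear flux law

    J(1->2) = P * A * (C1 - C2 / Kp)

where ``P`` is a permeability coefficient (cm/h), ``A`` the exchange area
(cm^2), ``C`` concentrations (ug/mL) and ``Kp`` the steady-state partition
coefficient ``C2/C1``.  Each compartment obeys ``V dC/dt = J_in - J_out``.
The state variable is *amount* (ug), not concentration, so that mass
balance on a closed system is a plain sum.

Internal units are fixed: hours, mL (= cm^3), cm^2, cm/h, ug, ug/mL and
g/cm^3.  Converters belong at I/O boundaries, never inside the engine.

An interface may carry a lag time: its flux is identically zero for
``t < lag``.  The integrator is restarted at every lag boundary so the
discontinuity never degrades step-size control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Compartment",
    "Interface",
    "CompartmentSystem",
    "SimulationResult",
    "ModelConfigError",
    "InvalidInputError",
    "IntegrationError",
    "flux",
    "build_rhs",
    "simulate",
    "total_mass",
]


class ModelConfigError(ValueError):
    """A system or parameter set is structurally invalid."""


class InvalidInputError(ValueError):
    """A numeric input is out of range or non-finite."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Compartment:
    """A well-mixed compartment with volume in mL and initial amount in ug."""

    name: str
    volume: float
    initial_amount: float = 0.0
    density: float | None = None  # g/cm^3, used for tissue-weight normalisation

    def __post_init__(self):
        if not np.isfinite(self.volume) or self.volume <= 0:
            raise ModelConfigError(f"compartment {self.name!r}: volume must be > 0")
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise ModelConfigError(f"compartment {self.name!r}: initial_amount must be >= 0")
        if self.density is not None and self.density <= 0:
            raise ModelConfigError(f"compartment {self.name!r}: density must be > 0")


@dataclass(frozen=True)
class Interface:
    """A directional bookkeeping record of a physically bidirectional exchange.

    The driving force ``C_source - C_target/Kp`` already covers back-flux, so
    only one interface per compartment pair is allowed.
    """

    source: str
    target: str
    permeability: float  # cm/h
    area: float  # cm^2
    partition_coefficient: float  # dimensionless, C_target/C_source at steady state
    lag_time: float = 0.0  # h; flux gated to zero for t < lag_time

    def __post_init__(self):
        if not np.isfinite(self.permeability) or self.permeability < 0:
            raise ModelConfigError(f"interface {self.source}->{self.target}: P must be >= 0")
        if not np.isfinite(self.area) or self.area <= 0:
            raise ModelConfigError(f"interface {self.source}->{self.target}: area must be > 0")
        if not np.isfinite(self.partition_coefficient) or self.partition_coefficient <= 0:
            raise ModelConfigError(f"interface {self.source}->{self.target}: Kp must be > 0")
        if not np.isfinite(self.lag_time) or self.lag_time < 0:
            raise ModelConfigError(f"interface {self.source}->{self.target}: lag_time must be >= 0")


def flux(interface: Interface, c_source: float, c_target: float, t: float) -> float:
    """Instantaneous flux (ug/h) across one interface; positive = source -> target."""
    for v in (c_source, c_target, t):
        if not np.isfinite(v):
            raise InvalidInputError("flux inputs must be finite")
    if t < interface.lag_time:
        return 0.0
    return interface.permeability * interface.area * (
        c_source - c_target / interface.partition_coefficient
    )


class CompartmentSystem:
    """An ordered set of compartments joined by flux interfaces."""

    def __init__(
        self,
        compartments: Sequence[Compartment],
        interfaces: Sequence[Interface],
        closed: bool = True,
        metadata: dict | None = None,
    ):
        names = [c.name for c in compartments]
        if len(set(names)) != len(names):
            raise ModelConfigError("compartment names must be unique")
        name_set = set(names)
        pairs = set()
        for itf in interfaces:
            if itf.source not in name_set or itf.target not in name_set:
                raise ModelConfigError(
                    f"interface {itf.source}->{itf.target} references an unknown compartment"
                )
            if itf.source == itf.target:
                raise ModelConfigError(f"self-interface on {itf.source!r}")
            key = frozenset((itf.source, itf.target))
            if key in pairs:
                raise ModelConfigError(
                    f"duplicate interface between {itf.source!r} and {itf.target!r}: "
                    "the flux law is already bidirectional"
                )
            pairs.add(key)
        self.compartments = tuple(compartments)
        self.interfaces = tuple(interfaces)
        self.closed = bool(closed)
        self.metadata = dict(metadata or {})
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([c.volume for c in self.compartments])

    @property
    def initial_amounts(self) -> np.ndarray:
        return np.array([c.initial_amount for c in self.compartments])

    def index(self, name: str) -> int:
        return self._index[name]

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "compartments": [
                {
                    "name": c.name,
                    "volume_mL": c.volume,
                    "initial_amount_ug": c.initial_amount,
                    "density_g_cm3": c.density,
                }
                for c in self.compartments
            ],
            "interfaces": [
                {
                    "source": i.source,
                    "target": i.target,
                    "P_cm_h": i.permeability,
                    "A_cm2": i.area,
                    "Kp": i.partition_coefficient,
                    "lag_h": i.lag_time,
                }
                for i in self.interfaces
            ],
            "closed": self.closed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentSystem":
        comps = [
            Compartment(
                name=c["name"],
                volume=c["volume_mL"],
                initial_amount=c.get("initial_amount_ug", 0.0),
                density=c.get("density_g_cm3"),
            )
            for c in d["compartments"]
        ]
        itfs = [
            Interface(
                source=i["source"],
                target=i["target"],
                permeability=i["P_cm_h"],
                area=i["A_cm2"],
                partition_coefficient=i["Kp"],
                lag_time=i.get("lag_h", 0.0),
            )
            for i in d["interfaces"]
        ]
        return cls(comps, itfs, closed=d.get("closed", True))

    @classmethod
    def from_json(cls, text_or_path) -> "CompartmentSystem":
        try:
            d = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def build_rhs(system: CompartmentSystem) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return ``f(t, amounts) -> d(amounts)/dt`` for the system.

    For every compartment the derivative is the sum of incoming minus
    outgoing fluxes, so a closed system's derivatives sum to exactly zero
    at every state.
    """
    inv_vol = 1.0 / system.volumes
    n = len(system.compartments)
    src = np.array([system.index(i.source) for i in system.interfaces], dtype=int)
    tgt = np.array([system.index(i.target) for i in system.interfaces], dtype=int)
    pa = np.array([i.permeability * i.area for i in system.interfaces])
    inv_kp = np.array([1.0 / i.partition_coefficient for i in system.interfaces])
    lag = np.array([i.lag_time for i in system.interfaces])

    def rhs(t: float, amounts: np.ndarray) -> np.ndarray:
        dy = np.zeros(n)
        if len(src) == 0:
            return dy
        conc = amounts * inv_vol
        j = pa * (conc[src] - conc[tgt] * inv_kp)
        j[t < lag] = 0.0
        np.subtract.at(dy, src, j)
        np.add.at(dy, tgt, j)
        return dy

    return rhs


def system_matrix(system: CompartmentSystem, active_lags_at: float = np.inf) -> np.ndarray:
    """Coefficient matrix M with dA/dt = M A for interfaces active at a time.

    Only valid between lag boundaries; used for stiffness-aware Jacobians.
    """
    n = len(system.compartments)
    m = np.zeros((n, n))
    inv_vol = 1.0 / system.volumes
    for itf in system.interfaces:
        if itf.lag_time > active_lags_at:
            continue
        s, t = system.index(itf.source), system.index(itf.target)
        pa = itf.permeability * itf.area
        m[s, s] -= pa * inv_vol[s]
        m[s, t] += pa * inv_vol[t] / itf.partition_coefficient
        m[t, s] += pa * inv_vol[s]
        m[t, t] -= pa * inv_vol[t] / itf.partition_coefficient
    return m


@dataclass
class SimulationResult:
    """Time grid x compartment amounts (ug), plus solver diagnostics."""

    times: np.ndarray
    amounts: np.ndarray  # shape (n_times, n_compartments), clipped at 0
    names: tuple[str, ...]
    volumes: np.ndarray
    units: dict = field(default_factory=lambda: {"time": "h", "amount": "ug", "concentration": "ug/mL"})
    diagnostics: dict = field(default_factory=dict)

    def amount(self, name: str) -> np.ndarray:
        return self.amounts[:, self.names.index(name)]

    def concentration(self, name: str) -> np.ndarray:
        i = self.names.index(name)
        return self.amounts[:, i] / self.volumes[i]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_h, compartment, amount_ug, concentration_ug_mL."""
        rows = []
        for i, name in enumerate(self.names):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "compartment": name,
                        "amount_ug": self.amounts[:, i],
                        "concentration_ug_mL": self.amounts[:, i] / self.volumes[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def simulate(
    system: CompartmentSystem,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the system over ``t_grid`` (hours, starting at 0).

    Integration proceeds segment-by-segment between lag boundaries with a
    stiff-capable solver, restarting cleanly at each boundary.  For a
    closed system the total mass at every output time is checked against
    ``max(atol * n_compartments, 1e-6 * initial total)``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise InvalidInputError("t_grid must be a 1-D grid with at least two points")
    if t[0] != 0.0:
        raise InvalidInputError("t_grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("t_grid must be strictly increasing")

    y0 = system.initial_amounts.astype(float)
    t_end = t[-1]
    lags = sorted({i.lag_time for i in system.interfaces if 0.0 < i.lag_time < t_end})
    boundaries = [0.0, *lags, t_end]

    rhs = build_rhs(system)
    out = np.empty((len(t), len(y0)))
    out[0] = y0
    y = y0.copy()
    n_steps = 0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        inner = t[(t > a) & (t <= b)]
        t_eval = np.unique(np.concatenate([inner, [b]]))
        # midpoint decides which lags are active within this segment
        jac = system_matrix(system, active_lags_at=0.5 * (a + b))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            jac=lambda tt, yy, _m=jac: _m,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}]: {sol.message}",
                diagnostics={"segment": (a, b), "message": sol.message},
            )
        n_steps += sol.t.size
        for j, tv in enumerate(sol.t):
            idx = np.searchsorted(t, tv)
            if idx < len(t) and t[idx] == tv:
                out[idx] = sol.y[:, j]
        y = sol.y[:, -1]

    min_amount = float(out.min())
    diagnostics = {
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "success": True,
        "min_amount_before_clip": min_amount,
        "n_solver_points": n_steps,
    }
    if system.closed:
        total0 = float(y0.sum())
        totals = out.sum(axis=1)
        tol = max(atol * len(y0), 1e-6 * total0)
        err = float(np.abs(totals - total0).max())
        diagnostics["mass_balance_error_ug"] = err
        if err > tol:
            raise IntegrationError(
                f"mass balance violated: max |total(t) - total(0)| = {err:g} ug > {tol:g} ug",
                diagnostics=diagnostics,
            )
    return SimulationResult(
        times=t,
        amounts=np.clip(out, 0.0, None),
        names=system.names,
        volumes=system.volumes,
        diagnostics=diagnostics,
    )


def total_mass(result: SimulationResult, at_time: float) -> float:
    """Total drug amount (ug) at a time, linearly interpolated on the grid."""
    if at_time < result.times[0] or at_time > result.times[-1]:
        raise InvalidInputError(
            f"time {at_time} outside simulated range [{result.times[0]}, {result.times[-1]}]"
        )
    totals = result.amounts.sum(axis=1)
    return float(np.interp(at_time, result.times, totals))
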