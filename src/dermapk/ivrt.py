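"""In-silico in vitro release testing (IVRT) in a Franz diffusion cell.

The gel donor is a two-phase system: micronised drug particles (discrete
phase, DP) suspended in a polymer-like continuous phase (CP).  Release is
a sequential diffusion process DP -> CP -> synthetic membrane -> receptor,
each step following the generalized flux law of :mod:`dermapk.core`.  A
lag time on the DP->CP interface reproduces the delayed release onset
seen for some gel formulations.

Outputs are cumulative release per membrane area (ug/cm^2), the quantity
an IVRT experiment reports, including reconstruction of cumulative
release from sample-and-replace receptor concentration measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Compartment,
    CompartmentSystem,
    Interface,
    InvalidInputError,
    ModelConfigError,
    SimulationResult,
    simulate,
)

__all__ = [
    "FormulationParams",
    "FranzCellConfig",
    "ReleaseProfile",
    "initial_drug_mass",
    "build_ivrt_system",
    "simulate_release",
    "sampling_corrected_cumulative",
]


@dataclass(frozen=True)
class FormulationParams:
    """Formulation attributes of a two-phase gel.

    ``kp_dp_cp`` is the steady-state concentration ratio CP/DP.  For a
    highly lipophilic drug suspended as solid particles it is very small:
    almost all drug prefers the particle phase, which is what limits the
    released fraction.
    """

    name: str
    drug_mass_fraction: float  # e.g. 0.001 for 0.1% w/w
    applied_mass: float  # mg of gel dosed into the donor
    density_discrete: float = 1.3  # g/cm^3
    density_continuous: float = 1.0  # g/cm^3
    fraction_discrete: float = 0.01  # mass fraction of gel in the discrete phase
    kp_dp_cp: float = 1e-4
    p_dp_cp: float = 2e-7  # cm/h; effective particle-boundary permeability
    a_dp_cp: float = 50.0  # cm^2 total particle surface
    release_lag: float = 0.0  # h

    def __post_init__(self):
        if not 0 < self.drug_mass_fraction < 1:
            raise ModelConfigError("drug_mass_fraction must be in (0, 1)")
        if self.applied_mass < 0:
            raise ModelConfigError("applied_mass must be >= 0")
        if not 0 <= self.fraction_discrete <= 1:
            raise ModelConfigError("fraction_discrete must be in [0, 1]")
        if self.density_discrete <= 0 or self.density_continuous <= 0:
            raise ModelConfigError("phase densities must be > 0")

    def with_params(self, **kwargs) -> "FormulationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FranzCellConfig:
    """Franz-cell geometry, membrane properties and sampling schedule."""

    receptor_volume: float = 5.1  # mL
    orifice_area: float = 0.69  # cm^2
    membrane_thickness: float = 0.0025  # cm (25 um)
    membrane_porosity: float = 0.7
    sample_volume: float = 0.5  # mL withdrawn and replaced at each sampling time
    sampling_times: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)
    # inert cellulose membrane, assumed non-selective
    p_cp_mem: float = 0.05  # cm/h
    kp_cp_mem: float = 1.0
    p_mem_rec: float = 0.05  # cm/h
    kp_mem_rec: float = 1.0

    def __post_init__(self):
        if self.receptor_volume <= 0 or self.orifice_area <= 0:
            raise ModelConfigError("receptor_volume and orifice_area must be > 0")
        if not 0 < self.membrane_porosity <= 1:
            raise ModelConfigError("membrane_porosity must be in (0, 1]")
        if self.sample_volume < 0 or self.sample_volume > self.receptor_volume:
            raise ModelConfigError("sample_volume must be in [0, receptor_volume]")
        if any(np.diff(self.sampling_times) <= 0) or (self.sampling_times and self.sampling_times[0] <= 0):
            raise ModelConfigError("sampling_times must be positive and strictly increasing")

    @property
    def membrane_volume(self) -> float:
        """Accessible membrane volume: area x thickness x porosity (mL)."""
        return self.orifice_area * self.membrane_thickness * self.membrane_porosity


@dataclass
class ReleaseProfile:
    """Cumulative drug release per membrane area over time."""

    formulation: str
    times: np.ndarray
    cumulative_amount_per_area: np.ndarray  # ug/cm^2
    replicate: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative_amount_per_area = np.asarray(self.cumulative_amount_per_area, dtype=float)
        if self.times.shape != self.cumulative_amount_per_area.shape:
            raise ModelConfigError("times and cumulative amounts must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formulation": self.formulation,
                "replicate": self.replicate if self.replicate is not None else "",
                "time_h": self.times,
                "cumulative_ug_per_cm2": self.cumulative_amount_per_area,
            }
        )

    @staticmethod
    def collection_to_frame(profiles: Sequence["ReleaseProfile"]) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in profiles], ignore_index=True)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> list["ReleaseProfile"]:
        out = []
        rep = df["replicate"] if "replicate" in df else pd.Series("", index=df.index)
        for (form, r), g in df.assign(_rep=rep.fillna("")).groupby(["formulation", "_rep"], sort=False):
            g = g.sort_values("time_h")
            out.append(
                ReleaseProfile(
                    formulation=form,
                    replicate=(r or None),
                    times=g["time_h"].to_numpy(),
                    cumulative_amount_per_area=g["cumulative_ug_per_cm2"].to_numpy(),
                )
            )
        return out


def initial_drug_mass(applied_mass: float, drug_mass_fraction: float) -> float:
    """Drug loading in ug from applied gel mass (mg) and w/w drug fraction."""
    if applied_mass < 0 or drug_mass_fraction <= 0:
        raise InvalidInputError("applied_mass must be >= 0 and drug_mass_fraction > 0")
    if drug_mass_fraction >= 1:
        raise ModelConfigError("drug_mass_fraction must be < 1")
    return applied_mass * drug_mass_fraction * 1000.0  # mg -> ug


def build_ivrt_system(form: FormulationParams, cell: FranzCellConfig) -> CompartmentSystem:
    """Assemble the 4-compartment IVRT system DP -> CP -> MEM -> REC.

    The drug initially sits entirely in the discrete phase.  If a phase
    fraction is degenerate (0 or 1) the system collapses to a
    3-compartment variant with a warning.
    """
    dose = initial_drug_mass(form.applied_mass, form.drug_mass_fraction)
    gel_mass_g = form.applied_mass / 1000.0
    v_dp = gel_mass_g * form.fraction_discrete / form.density_discrete  # mL
    v_cp = gel_mass_g * (1.0 - form.fraction_discrete) / form.density_continuous
    mem = Compartment("MEM", volume=cell.membrane_volume)
    rec = Compartment("REC", volume=cell.receptor_volume)
    meta = {
        "kind": "ivrt",
        "formulation": form.name,
        "orifice_area_cm2": cell.orifice_area,
        "dose_ug": dose,
    }

    if form.fraction_discrete == 0.0:
        warnings.warn("fraction_discrete = 0: collapsing to CP/MEM/REC, drug starts in CP")
        cp = Compartment("CP", volume=v_cp, initial_amount=dose, density=form.density_continuous)
        interfaces = [
            Interface("CP", "MEM", cell.p_cp_mem, cell.orifice_area, cell.kp_cp_mem),
            Interface("MEM", "REC", cell.p_mem_rec, cell.orifice_area, cell.kp_mem_rec),
        ]
        return CompartmentSystem([cp, mem, rec], interfaces, closed=True, metadata=meta)
    if form.fraction_discrete == 1.0:
        warnings.warn("fraction_discrete = 1: collapsing to DP/MEM/REC (no continuous phase)")
        dp = Compartment("DP", volume=v_dp, initial_amount=dose, density=form.density_discrete)
        interfaces = [
            Interface("DP", "MEM", form.p_dp_cp, cell.orifice_area, form.kp_dp_cp, form.release_lag),
            Interface("MEM", "REC", cell.p_mem_rec, cell.orifice_area, cell.kp_mem_rec),
        ]
        return CompartmentSystem([dp, mem, rec], interfaces, closed=True, metadata=meta)

    dp = Compartment("DP", volume=v_dp, initial_amount=dose, density=form.density_discrete)
    cp = Compartment("CP", volume=v_cp, density=form.density_continuous)
    interfaces = [
        Interface("DP", "CP", form.p_dp_cp, form.a_dp_cp, form.kp_dp_cp, form.release_lag),
        Interface("CP", "MEM", cell.p_cp_mem, cell.orifice_area, cell.kp_cp_mem),
        Interface("MEM", "REC", cell.p_mem_rec, cell.orifice_area, cell.kp_mem_rec),
    ]
    return CompartmentSystem([dp, cp, mem, rec], interfaces, closed=True, metadata=meta)


def simulate_release(
    system: CompartmentSystem, t_grid: Sequence[float], rtol: float = 1e-8, atol: float = 1e-10
) -> ReleaseProfile:
    """Simulate an IVRT system and return cumulative receptor amount per area."""
    if system.metadata.get("kind") != "ivrt":
        raise ModelConfigError("system was not built by build_ivrt_system")
    res = simulate(system, t_grid, rtol=rtol, atol=atol)
    area = system.metadata["orifice_area_cm2"]
    return ReleaseProfile(
        formulation=system.metadata.get("formulation", ""),
        times=res.times,
        cumulative_amount_per_area=res.amount("REC") / area,
    )


def sampling_corrected_cumulative(
    concentrations: Sequence[float], cell: FranzCellConfig, formulation: str = "", replicate=None
) -> ReleaseProfile:
    """Reconstruct cumulative release from sampled receptor concentrations.

    Under sample-and-replace with withdrawal volume ``V_s``:

        Q(t_n) = ( C_n * V_receptor + sum_{i<n} C_i * V_s ) / A

    which adds back the drug removed in earlier samples.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(~np.isfinite(c)) or np.any(c < 0):
        raise InvalidInputError("concentrations must be finite and >= 0")
    if len(c) != len(cell.sampling_times):
        raise InvalidInputError("one concentration per sampling time is required")
    withdrawn = np.concatenate([[0.0], np.cumsum(c * cell.sample_volume)[:-1]])
    q = (c * cell.receptor_volume + withdrawn) / cell.orifice_area
    return ReleaseProfile(
        formulation=formulation,
        replicate=replicate,
        times=np.asarray(cell.sampling_times, dtype=float),
        cumulative_amount_per_area=q,
    )


def simulate_with_sampling(
    system: CompartmentSystem,
    cell: FranzCellConfig,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, SimulationResult]:
    """Simulate an IVRT run with explicit sample-and-replace withdrawals.

    At each sampling time the receptor concentration is recorded, then the
    drug contained in the withdrawn aliquot is removed from the receptor
    (the medium itself is replaced, keeping the volume constant).  Returns
    the measured concentrations (ug/mL) and the final-segment result.
    """
    if system.metadata.get("kind") != "ivrt":
        raise ModelConfigError("system was not built by build_ivrt_system")
    rec = system.index("REC")
    v_rec = system.compartments[rec].volume
    y = system.initial_amounts.astype(float)
    t_prev = 0.0
    measured = []
    res = None
    for t_s in cell.sampling_times:
        seg = np.linspace(0.0, t_s - t_prev, 25)
        shifted = _shifted_system(system, y, t_shift=t_prev)
        res = simulate(shifted, seg, rtol=rtol, atol=atol)
        y = res.amounts[-1].copy()
        c = y[rec] / v_rec
        measured.append(c)
        y[rec] -= c * cell.sample_volume  # aliquot removed, fresh medium replaces it
        t_prev = t_s
    return np.array(measured), res


def _shifted_system(system: CompartmentSystem, amounts: np.ndarray, t_shift: float) -> CompartmentSystem:
    """Clone a system with new initial amounts and lags re-expressed from t_shift."""
    comps = [
        Compartment(c.name, c.volume, initial_amount=max(float(a), 0.0), density=c.density)
        for c, a in zip(system.compartments, amounts)
    ]
    itfs = [
        Interface(
            i.source,
            i.target,
            i.permeability,
            i.area,
            i.partition_coefficient,
            lag_time=max(i.lag_time - t_shift, 0.0),
        )
        for i in system.interfaces
    ]
    return CompartmentSystem(comps, itfs, closed=True, metadata=dict(system.metadata))
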