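"""In-silico in vitro permeation testing (IVPT) through dermatomed skin.

The skin is an effective multi-layer compartment chain: gel discrete and
continuous phases (DP, CP), stratum corneum (SC), sebum / follicular
pathway (SB), viable epidermis (VE), dermis (DM) and the receptor chamber
(REC).  Fluxes:

    DP->CP, CP->SC, CP->SB, SB->SC, SB->VE, SB->DM, SC->VE, VE->DM, DM->REC

all governed by the same linear flux law.  The sebum compartment is fed
from the formulation (the only depot present) and exchanges with every
skin layer, representing the trans-appendageal route in parallel with the
trans-epidermal one.

Outputs are tissue accumulations normalised per tissue weight (ug/mg),
mirroring the mechanical separation of excised skin into epidermis
(SC + viable epidermis) and dermis, plus the mass-balance recovery check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    Compartment,
    CompartmentSystem,
    Interface,
    InvalidInputError,
    ModelConfigError,
    SimulationResult,
)
from .ivrt import FormulationParams, initial_drug_mass

__all__ = [
    "SkinConfig",
    "SkinTransportParams",
    "TissueAccumulation",
    "build_ivpt_system",
    "layer_accumulation",
    "percent_recovery",
    "sc_concentration",
    "infundibular_concentration",
    "SKIN_INTERFACES",
    "CALIBRATABLE_SKIN_PARAMS",
]

# fraction of skin surface occupied by follicular openings (<= 0.1%)
FOLLICLE_AREA_FRACTION = 0.001

SKIN_INTERFACES = ("cp_sc", "cp_sb", "sb_sc", "sb_ve", "sb_dm", "sc_ve", "ve_dm", "dm_rec")

# Stage-2 calibration touches only the gel/SC partition coefficient and the
# partition coefficients at dermis-involving interfaces; everything else is
# fixed by the stage-1 (release) fit or physiology.
CALIBRATABLE_SKIN_PARAMS = ("kp_cp_sc", "kp_ve_dm", "kp_sb_dm", "kp_dm_rec")


@dataclass(frozen=True)
class SkinConfig:
    """Layer geometry and densities of the dermatomed skin piece.

    Default thicknesses split the 800 um total so that
    thickness x area x density reproduces tissue weights of roughly
    1 mg (SC), 4.4 mg (VE) and 75 mg (DM).
    """

    sc_thickness: float = 12.0  # um
    ve_thickness: float = 53.0  # um
    dm_thickness: float = 735.0  # um
    epidermis_density: float = 1.2  # g/cm^3
    dermis_density: float = 1.5  # g/cm^3
    area: float = 0.69  # cm^2
    sebum_volume: float | None = None  # mL; default 0.1% of SC volume

    def __post_init__(self):
        for name in ("sc_thickness", "ve_thickness", "dm_thickness", "area"):
            if getattr(self, name) <= 0:
                raise ModelConfigError(f"{name} must be > 0")
        if self.epidermis_density <= 0 or self.dermis_density <= 0:
            raise ModelConfigError("densities must be > 0")
        if self.sebum_volume is not None and self.sebum_volume <= 0:
            raise ModelConfigError("sebum_volume must be > 0")

    @property
    def total_thickness(self) -> float:
        return self.sc_thickness + self.ve_thickness + self.dm_thickness

    # volumes in mL (1 um * 1 cm^2 = 1e-4 mL)
    @property
    def sc_volume(self) -> float:
        return self.sc_thickness * 1e-4 * self.area

    @property
    def ve_volume(self) -> float:
        return self.ve_thickness * 1e-4 * self.area

    @property
    def dm_volume(self) -> float:
        return self.dm_thickness * 1e-4 * self.area

    @property
    def sebum_volume_ml(self) -> float:
        return self.sebum_volume if self.sebum_volume is not None else 1e-3 * self.sc_volume

    # tissue weights in mg (volume mL * density g/cm^3 * 1000)
    @property
    def sc_mg(self) -> float:
        return self.sc_volume * self.epidermis_density * 1000.0

    @property
    def ve_mg(self) -> float:
        return self.ve_volume * self.epidermis_density * 1000.0

    @property
    def dm_mg(self) -> float:
        return self.dm_volume * self.dermis_density * 1000.0


@dataclass(frozen=True)
class SkinTransportParams:
    """Permeability (cm/h) and partition coefficient for each skin interface.

    Partition coefficients are steady-state target/source concentration
    ratios, e.g. ``kp_cp_sc`` = C_SC / C_CP: large for a lipophilic drug
    partitioning into SC lipids.
    """

    p_cp_sc: float = 2e-3
    kp_cp_sc: float = 300.0
    p_cp_sb: float = 2e-3
    kp_cp_sb: float = 300.0
    p_sb_sc: float = 1e-3
    kp_sb_sc: float = 1.0
    p_sb_ve: float = 1e-4
    kp_sb_ve: float = 0.05
    p_sb_dm: float = 1e-4
    kp_sb_dm: float = 0.02
    p_sc_ve: float = 5e-4
    kp_sc_ve: float = 0.05
    p_ve_dm: float = 2e-3
    kp_ve_dm: float = 0.5
    p_dm_rec: float = 5e-4
    kp_dm_rec: float = 0.002

    def __post_init__(self):
        for name in SKIN_INTERFACES:
            if getattr(self, f"p_{name}") < 0:
                raise ModelConfigError(f"p_{name} must be >= 0")
            if getattr(self, f"kp_{name}") <= 0:
                raise ModelConfigError(f"kp_{name} must be > 0")

    def with_params(self, **kwargs) -> "SkinTransportParams":
        for key in kwargs:
            if not hasattr(self, key):
                raise ModelConfigError(f"unknown transport parameter {key!r}")
        return replace(self, **kwargs)

    def calibratable(self) -> tuple[str, ...]:
        return CALIBRATABLE_SKIN_PARAMS


@dataclass
class TissueAccumulation:
    """Per-weight drug accumulation in epidermis and dermis over time."""

    formulation: str
    times: np.ndarray
    epidermis_amount_per_weight: np.ndarray  # ug/mg, SC + VE (+ sebum share)
    dermis_amount_per_weight: np.ndarray  # ug/mg
    receptor_amount: np.ndarray  # ug
    replicate: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("epidermis_amount_per_weight", "dermis_amount_per_weight", "receptor_amount"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.times.shape:
                raise ModelConfigError(f"{name} must align with times")
            if np.any(arr < 0):
                raise InvalidInputError(f"{name} must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formulation": self.formulation,
                "replicate": self.replicate if self.replicate is not None else "",
                "time_h": self.times,
                "epidermis_ug_per_mg": self.epidermis_amount_per_weight,
                "dermis_ug_per_mg": self.dermis_amount_per_weight,
                "receptor_ug": self.receptor_amount,
            }
        )

    @staticmethod
    def collection_to_frame(accs) -> pd.DataFrame:
        return pd.concat([a.to_frame() for a in accs], ignore_index=True)


def build_ivpt_system(
    form: FormulationParams,
    skin: SkinConfig,
    transport: SkinTransportParams,
    receptor_volume: float = 4.9,
) -> CompartmentSystem:
    """Assemble the 7-compartment IVPT system (DP, CP, SC, SB, VE, DM, REC)."""
    if receptor_volume <= 0:
        raise ModelConfigError("receptor_volume must be > 0")
    dose = initial_drug_mass(form.applied_mass, form.drug_mass_fraction)
    gel_mass_g = form.applied_mass / 1000.0
    if not 0 < form.fraction_discrete < 1:
        raise ModelConfigError("IVPT model requires a two-phase gel (0 < fraction_discrete < 1)")
    v_dp = gel_mass_g * form.fraction_discrete / form.density_discrete
    v_cp = gel_mass_g * (1.0 - form.fraction_discrete) / form.density_continuous

    comps = [
        Compartment("DP", v_dp, initial_amount=dose, density=form.density_discrete),
        Compartment("CP", v_cp, density=form.density_continuous),
        Compartment("SC", skin.sc_volume, density=skin.epidermis_density),
        Compartment("SB", skin.sebum_volume_ml),
        Compartment("VE", skin.ve_volume, density=skin.epidermis_density),
        Compartment("DM", skin.dm_volume, density=skin.dermis_density),
        Compartment("REC", receptor_volume),
    ]
    a_skin = skin.area
    a_foll = FOLLICLE_AREA_FRACTION * skin.area
    pairs = {
        "cp_sc": ("CP", "SC", a_skin * (1.0 - FOLLICLE_AREA_FRACTION)),
        "cp_sb": ("CP", "SB", a_foll),  # the depot -> sebum feed
        "sb_sc": ("SB", "SC", a_foll),
        "sb_ve": ("SB", "VE", a_foll),
        "sb_dm": ("SB", "DM", a_foll),
        "sc_ve": ("SC", "VE", a_skin),
        "ve_dm": ("VE", "DM", a_skin),
        "dm_rec": ("DM", "REC", a_skin),
    }
    interfaces = [
        Interface("DP", "CP", form.p_dp_cp, form.a_dp_cp, form.kp_dp_cp, form.release_lag)
    ]
    for key, (src, tgt, area) in pairs.items():
        p = getattr(transport, f"p_{key}")
        kp = getattr(transport, f"kp_{key}")
        interfaces.append(Interface(src, tgt, p, area, kp))
    meta = {
        "kind": "ivpt",
        "formulation": form.name,
        "dose_ug": dose,
        "skin_area_cm2": skin.area,
    }
    return CompartmentSystem(comps, interfaces, closed=True, metadata=meta)


def layer_accumulation(
    result: SimulationResult,
    skin: SkinConfig,
    sebum_assignment: str = "epidermis",
) -> TissueAccumulation:
    """Convert an IVPT simulation into per-weight tissue accumulations.

    ``sebum_assignment`` decides where the follicular content ends up after
    mechanical separation: "epidermis" (default; the infundibulum opens at
    the epidermal level), "dermis", or "excluded".
    """
    if sebum_assignment not in ("epidermis", "dermis", "excluded"):
        raise ModelConfigError("sebum_assignment must be epidermis|dermis|excluded")
    epi_mg = skin.sc_mg + skin.ve_mg
    dm_mg = skin.dm_mg
    if epi_mg <= 0 or dm_mg <= 0:
        raise ModelConfigError("tissue weights must be > 0")
    sb = result.amount("SB")
    epi = result.amount("SC") + result.amount("VE")
    dm = result.amount("DM")
    if sebum_assignment == "epidermis":
        epi = epi + sb
    elif sebum_assignment == "dermis":
        dm = dm + sb
    return TissueAccumulation(
        formulation="",
        times=result.times,
        epidermis_amount_per_weight=epi / epi_mg,
        dermis_amount_per_weight=dm / dm_mg,
        receptor_amount=result.amount("REC"),
    )


def percent_recovery(
    epidermis: float, dermis: float, remaining_donor: float, receptor: float, dose: float
) -> float:
    """Mass-balance recovery (%) of the applied dose across all fractions."""
    if dose <= 0:
        raise InvalidInputError("dose must be > 0")
    parts = np.asarray([epidermis, dermis, remaining_donor, receptor], dtype=float)
    if np.any(parts < 0) or np.any(~np.isfinite(parts)):
        raise InvalidInputError("recovery components must be finite and >= 0")
    return 100.0 * float(parts.sum()) / dose


def sc_concentration(result: SimulationResult, skin: SkinConfig) -> np.ndarray:
    """Stratum-corneum drug concentration (ug/mL) over the simulated grid."""
    return result.amount("SC") / skin.sc_volume


def infundibular_concentration(c_sc) -> np.ndarray | float:
    """Infundibular exposure: 0.1 percent of the SC concentration."""
    c = np.asarray(c_sc, dtype=float)
    if np.any(c < 0) or np.any(~np.isfinite(c)):
        raise InvalidInputError("SC concentration must be finite and >= 0")
    out = 0.001 * c
    return float(out) if np.isscalar(c_sc) else out
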