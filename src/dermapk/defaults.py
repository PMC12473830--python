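"""Shipped example study configuration.

Three 0.1% w/w adapalene gel example formulations are provided, ordered
fastest-to-slowest in release rate (Differin > AcneFree > Effaclar) with
release lags matching the qualitative onset order seen in release
experiments (immediate, ~4 h, ~6 h).  The numeric transport parameters
are synthetic package defaults, chosen once so that simulated behaviour
is realistic for a highly lipophilic drug: sub-microgram/cm^2 cumulative
release at 24 h, predominant epidermal accumulation, and negligible
receptor permeation through skin by 36 h.  They are placeholders meant to
be re-fit on real or synthetic data, not measured values.
"""

from __future__ import annotations

from .ivrt import FormulationParams, FranzCellConfig
from .ivpt import SkinConfig, SkinTransportParams

__all__ = ["example_formulations", "default_cell", "default_skin", "default_transport"]


def example_formulations() -> dict[str, FormulationParams]:
    common = dict(drug_mass_fraction=0.001, applied_mass=500.0)
    return {
        "Differin": FormulationParams(
            name="Differin", kp_dp_cp=1.2e-4, p_dp_cp=3.0e-7, release_lag=0.0, **common
        ),
        "AcneFree": FormulationParams(
            name="AcneFree", kp_dp_cp=1.0e-4, p_dp_cp=2.0e-7, release_lag=3.5, **common
        ),
        "Effaclar": FormulationParams(
            name="Effaclar", kp_dp_cp=1.0e-4, p_dp_cp=1.2e-7, release_lag=5.5, **common
        ),
    }


def default_cell() -> FranzCellConfig:
    return FranzCellConfig()


def default_skin() -> SkinConfig:
    return SkinConfig()


def default_transport() -> SkinTransportParams:
    return SkinTransportParams()
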