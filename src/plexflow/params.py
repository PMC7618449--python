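"""Validated physiological parameter records.

All constants that close the flow and oxygen models live here, in two
pydantic models whose defaults are literature-typical rodent values. Every
report and serialized output echoes these records in full, because several
of them (boundary pressures, viscosity closure, consumption rate, hypoxia
threshold) are modelling choices rather than measured quantities.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator


class HemoParams(BaseModel):
    """Blood-flow model constants.

    plasma_viscosity
        μ_p, mPa·s. Water at 37 °C is ~0.7; plasma ~1.2.
    discharge_hematocrit
        H_D, red-cell volume fraction of the flowing blood. Uniform across
        the network (no phase separation at bifurcations).
    p_in / p_out
        Default inlet/outlet pressures, mmHg — representative pre/
        post-capillary values. Per-node boundary pressures on the network
        override these.
    viscosity_law
        ``empirical_invitro``: the Pries et al. (1992) in-vitro
        diameter/hematocrit law (Fåhræus–Lindqvist effect);
        ``constant``: μ_eff = μ_p, for analytic tests.
    """

    plasma_viscosity: float = Field(default=1.2, gt=0)
    discharge_hematocrit: float = Field(default=0.45, gt=0, lt=1)
    p_in: float = 45.0
    p_out: float = 15.0
    viscosity_law: Literal["empirical_invitro", "constant"] = "empirical_invitro"

    @model_validator(mode="after")
    def _pressure_drop(self) -> "HemoParams":
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        return self


class OxyParams(BaseModel):
    """Oxygen transport constants and solver discretization.

    Physical constants (CGS-style units, pressures in mmHg):

    d_tissue
        Tissue O₂ diffusivity D, cm²/s.
    alpha_tissue / alpha_plasma
        O₂ solubilities α, cm³O₂·cm⁻³·mmHg⁻¹ (tissue and plasma).
    m0, p_m
        Michaelis–Menten consumption M(P) = M0·P/(P + P_m);
        M0 in cm³O₂·cm⁻³·s⁻¹, P_m in mmHg.
    c_hb
        O₂ binding capacity of red cells, cm³O₂ per cm³ RBC.
    p50, hill_n
        Oxyhemoglobin Hill curve parameters, mmHg / dimensionless.
    p_inlet
        Inlet blood PO₂, mmHg (used where a node carries no boundary_po2).

    Discretization / iteration:

    element_len
        Vessel discretization length, μm.
    tissue_spacing
        Tissue sample-lattice pitch, μm.
    tissue_margin
        Lattice inflation beyond the network bounding box, μm.
    tol / max_iter
        Fixed-point termination: max element-PO₂ change < tol·p_inlet.
    """

    d_tissue: float = Field(default=1.5e-5, gt=0)
    alpha_tissue: float = Field(default=3.1e-5, gt=0)
    alpha_plasma: float = Field(default=3.1e-5, gt=0)
    m0: float = Field(default=1.0e-4, ge=0)
    p_m: float = Field(default=1.0, gt=0)
    c_hb: float = Field(default=0.5, gt=0)
    p50: float = Field(default=38.0, gt=0)
    hill_n: float = Field(default=2.7, gt=0)
    p_inlet: float = Field(default=60.0, gt=0)
    element_len: float = Field(default=10.0, gt=0)
    tissue_spacing: float = Field(default=4.0, gt=0)
    tissue_margin: float = Field(default=10.0, ge=0)
    tol: float = Field(default=1e-6, gt=0, lt=1)
    max_iter: int = Field(default=200, ge=1)
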