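"""Scalar hydraulic relations: Darcy transmembrane pressure and Reynolds number.

SI units throughout this module (m, s, Pa, kg).  Fluid properties default to
0.1 M NaCl at 25 C treated as constant; the membrane defaults describe the
single-layer 5 um nylon disc used in the bench system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FluidProps",
    "MembraneSpec",
    "darcy_pressure_drop",
    "permeability_from_pressure_drop",
    "membrane_flux_from_inlet",
    "transmembrane_pressure",
    "reynolds",
]


@dataclass(frozen=True)
class FluidProps:
    """Constant working-fluid properties."""

    density: float = 997.5          # kg/m^3
    viscosity: float = 8.98e-4      # Pa s
    diffusivity: float = 1.68e-9    # m^2/s, NaCl (mean of Na+ and Cl-)

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "diffusivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MembraneSpec:
    """Flat-disc membrane parameters."""

    permeability: float = 1.27e-15  # m^2
    thickness: float = 1.40e-4      # m
    diameter: float = 2.4e-2        # m

    def __post_init__(self) -> None:
        for name in ("permeability", "thickness", "diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def area(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


def darcy_pressure_drop(u: float, props: FluidProps, mem: MembraneSpec) -> float:
    """Pressure drop (Pa) across the membrane at through-flux ``u`` (m/s).

    Darcy's law for a slab: dP = mu * u * h_m / kappa.
    """
    if u < 0:
        raise ValueError("membrane flux must be >= 0")
    return props.viscosity * u * mem.thickness / mem.permeability


def permeability_from_pressure_drop(
    dp: float, u: float, props: FluidProps, thickness: float
) -> float:
    """Invert Darcy's law for the permeability (m^2)."""
    if dp <= 0 or u <= 0:
        raise ValueError("pressure drop and flux must be > 0")
    return props.viscosity * u * thickness / dp


def membrane_flux_from_inlet(u_inlet: float, d_inlet: float, mem: MembraneSpec) -> float:
    """Uniform membrane flux (m/s) carrying the inlet volumetric flow.

    Spreads ``Q = u_inlet * pi (d_inlet/2)^2`` evenly over the membrane area.
    """
    if u_inlet < 0 or d_inlet <= 0:
        raise ValueError("inlet velocity must be >= 0 and diameter > 0")
    q = u_inlet * math.pi * (d_inlet / 2.0) ** 2
    return q / mem.area


def transmembrane_pressure(
    u_inlet: float, d_inlet: float, props: FluidProps, mem: MembraneSpec
) -> float:
    """Darcy TMP (Pa) under the uniform-membrane-flux approximation."""
    return darcy_pressure_drop(membrane_flux_from_inlet(u_inlet, d_inlet, mem), props, mem)


def reynolds(props: FluidProps, u: float, d: float) -> float:
    """Reynolds number rho * u * d / mu."""
    if u < 0 or d <= 0:
        raise ValueError("velocity must be >= 0 and diameter > 0")
    return props.density * u * d / props.viscosity
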