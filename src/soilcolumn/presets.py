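"""Preset configurations of the two gentamicin column experiments.

The two laboratory cases share one agricultural soil (bulk density
1.35 g/cm^3, hence porosity and saturated moisture 0.4906) and one geometry
(8 cm modelled depth under a 3.5 cm ponded head); they differ in the solute
and in the calibrated scaling parameters:

* ``pure`` — analytical-grade gentamicin at 150 mg/L
  (Ks = 0.9481 cm/h, psi_d = 92.8674 cm, D = 9.55e-3),
* ``sulfate`` — gentamicin sulfate at 300 mg/L
  (Ks = 1.4689 cm/h, psi_d = 47.0628 cm, D = 2.97e-2).

Dispersion coefficients are carried in the package's model units (cm^2/h);
see the methods note on the unit labelling of the printed values.

The initial column moisture was measured but never reported; the package
default is a uniform 0.10 cm^3/cm^3 and must be stated in every run config.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hydraulics import (
    SoilHydraulicModel,
    SoilPhysical,
    porosity_from_bulk_density,
    solve_fractal_dimension,
)
from .richards import ColumnSpec
from .transport import TransportParams

__all__ = ["CasePreset", "SOIL", "case_preset", "CASES"]

SOIL = SoilPhysical(
    sand_pct=15.23,
    clay_pct=61.43,
    silt_pct=23.34,
    bulk_density=1.35,
    particle_density=2.65,
    ph=6.05,
    organic_matter_pct=2.61,
    total_organic_carbon_pct=1.58,
)

# retention/grain-size shape parameters shared by both cases
SHAPE_M = 0.18609
SHAPE_N = 3.1784
DD_UM = 1136.6942

_SCALING = {
    "pure": {"Ks": 0.9481, "psi_d": 92.8674, "D": 9.55e-3, "C0": 150.0},
    "sulfate": {"Ks": 1.4689, "psi_d": 47.0628, "D": 2.97e-2, "C0": 300.0},
}

# scenario horizons, minutes
SCENARIO_MINUTES = {
    ("continuous", "pure"): 2000.0,
    ("continuous", "sulfate"): 360.0,
    ("flush", "pure"): 720.0,
    ("flush", "sulfate"): 180.0,
}


@dataclass(frozen=True)
class CasePreset:
    name: str
    model: SoilHydraulicModel
    column: ColumnSpec
    transport: TransportParams


def case_preset(name: str, theta_initial: float = 0.10, dz: float = 0.05) -> CasePreset:
    """Build the full parameterisation of one experiment case."""
    if name not in _SCALING:
        raise KeyError(f"unknown case {name!r}; choose from {sorted(_SCALING)}")
    phi = porosity_from_bulk_density(SOIL.bulk_density, SOIL.particle_density)
    model = SoilHydraulicModel(
        m=SHAPE_M,
        n=SHAPE_N,
        psi_d=_SCALING[name]["psi_d"],
        Ks=_SCALING[name]["Ks"],
        theta_s=phi,
        theta_r=0.0,
        porosity=phi,
        s=solve_fractal_dimension(phi),
        Dd=DD_UM,
    )
    column = ColumnSpec(
        length=8.0, ponded_head=3.5, theta_initial=theta_initial, dz=dz
    )
    transport = TransportParams(
        dispersion_coefficient=_SCALING[name]["D"],
        C0=_SCALING[name]["C0"],
        Kd=0.0,
        bulk_density=SOIL.bulk_density,
    )
    return CasePreset(name=name, model=model, column=column, transport=transport)


CASES = tuple(_SCALING)
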