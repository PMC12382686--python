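"""CSV readers/writers, run configuration, and provenance helpers.

Units are fixed package-wide: cm, hours, mg/L, micrometres; the CSV dialects
carry the unit in the column name.  All writers round-trip losslessly at ten
significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .hydraulics import GrainSizeCurve, SoilHydraulicModel, porosity_from_bulk_density, solve_fractal_dimension
from .richards import ColumnSpec, FlowField, TimeGrid
from .transport import ConcProfile, ScenarioSpec, TransportParams

__all__ = [
    "RunConfig",
    "load_config",
    "read_grain_size_csv",
    "write_grain_size_csv",
    "read_infiltration_csv",
    "write_infiltration_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_flow_field_csv",
    "provenance",
]

log = logging.getLogger("soilcolumn")

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_grain_size_csv(path) -> GrainSizeCurve:
    """Read ``diameter_um,cumulative_fraction`` (header required)."""
    df = pd.read_csv(path)
    expected = ["diameter_um", "cumulative_fraction"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return GrainSizeCurve(df["diameter_um"].to_numpy(), df["cumulative_fraction"].to_numpy())


def write_grain_size_csv(curve_or_df, path) -> None:
    if isinstance(curve_or_df, GrainSizeCurve):
        df = pd.DataFrame(
            {"diameter_um": curve_or_df.diameters_um,
             "cumulative_fraction": curve_or_df.cumulative_fraction}
        )
    else:
        df = curve_or_df
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_infiltration_csv(path) -> pd.DataFrame:
    """Read ``t_h,I_cm`` cumulative-infiltration series."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["t_h", "I_cm"]:
        raise ValueError(f"{path}: expected columns ['t_h', 'I_cm']")
    return df


def write_infiltration_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_profile_csv(profile: ConcProfile, path) -> None:
    """Write ``depth_cm,concentration_mg_L`` with a time_min comment header."""
    with open(path, "w") as fh:
        fh.write(f"# time_min = {profile.time_min:.10g}\n")
        profile.to_frame().to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_profile_csv(path) -> ConcProfile:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# time_min"):
            raise ValueError(f"{path}: missing '# time_min = <value>' header line")
        time_min = float(first.split("=")[1])
        df = pd.read_csv(fh)
    if list(df.columns[:2]) != ["depth_cm", "concentration_mg_L"]:
        raise ValueError(f"{path}: expected columns ['depth_cm', 'concentration_mg_L']")
    return ConcProfile(
        time_min=time_min,
        depths_cm=df["depth_cm"].to_numpy(),
        concentrations=df["concentration_mg_L"].to_numpy(),
    )


def write_flow_field_csv(flow: FlowField, path) -> None:
    """Long-format field export: ``t_h,z_cm,theta,psi_cm,q_cm_h``."""
    flow.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"soil", "column", "grid", "transport", "scenario", "run"}


@dataclass
class RunConfig:
    """Validated configuration of one simulation/calibration run."""

    model: SoilHydraulicModel
    column: ColumnSpec
    grid: TimeGrid
    transport: Optional[TransportParams] = None
    scenario: Optional[ScenarioSpec] = None
    seed: int = 0
    output_dir: Path = Path(".")
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _require(d: dict, key: str, section: str):
    if key not in d:
        raise KeyError(f"config section '{section}' is missing required key '{key}'")
    return d[key]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown sections or keys raise; every defaulted value is echoed to the
    ``soilcolumn`` logger so a run's provenance is complete (the initial
    moisture in particular is always reported).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise KeyError(f"unknown config sections: {sorted(unknown)}")

    soil = dict(raw.get("soil", {}))
    bulk_density = float(soil.pop("bulk_density", 1.35))
    particle_density = float(soil.pop("particle_density", 2.65))
    phi = porosity_from_bulk_density(bulk_density, particle_density)
    defaults_used = []
    model_kwargs = {
        "m": float(_require(soil, "m", "soil")),
        "n": float(_require(soil, "n", "soil")),
        "psi_d": float(_require(soil, "psi_d", "soil")),
        "Ks": float(_require(soil, "Ks", "soil")),
        "porosity": float(soil.pop("porosity", phi)),
    }
    model_kwargs["theta_s"] = float(soil.pop("theta_s", model_kwargs["porosity"]))
    model_kwargs["theta_r"] = float(soil.pop("theta_r", 0.0))
    if "s" in soil:
        model_kwargs["s"] = float(soil.pop("s"))
    else:
        model_kwargs["s"] = solve_fractal_dimension(model_kwargs["porosity"])
        defaults_used.append(("soil.s", model_kwargs["s"]))
    if "Dd" in soil:
        model_kwargs["Dd"] = float(soil.pop("Dd"))
    for k in ("m", "n", "psi_d", "Ks"):
        soil.pop(k, None)
    if soil:
        raise KeyError(f"unknown keys in 'soil' section: {sorted(soil)}")
    model = SoilHydraulicModel(**model_kwargs)

    col = dict(raw.get("column", {}))
    column = ColumnSpec(
        length=float(col.pop("length", 8.0)),
        ponded_head=float(col.pop("ponded_head", 3.5)),
        theta_initial=float(col.pop("theta_initial", 0.10)),
        dz=float(col.pop("dz", 0.05)),
        lower_bc=col.pop("lower_bc", "free_drainage"),
        lower_bc_value=float(col.pop("lower_bc_value", 0.0)),
    )
    if "theta_initial" not in raw.get("column", {}):
        defaults_used.append(("column.theta_initial", column.theta_initial))
    if col:
        raise KeyError(f"unknown keys in 'column' section: {sorted(col)}")

    g = dict(raw.get("grid", {}))
    grid = TimeGrid(
        dt=float(g.pop("dt", 1e-4)),
        t_end=float(g.pop("t_end", 1.0)),
        dt_init=float(g["dt_init"]) if "dt_init" in g else None,
        growth=float(g.pop("growth", 1.05)),
        save_interval=float(g["save_interval"]) if "save_interval" in g else None,
    )
    g.pop("dt_init", None)
    g.pop("save_interval", None)
    if g:
        raise KeyError(f"unknown keys in 'grid' section: {sorted(g)}")

    transport = None
    if "transport" in raw:
        tr = dict(raw["transport"])
        transport = TransportParams(
            dispersion_coefficient=float(_require(tr, "dispersion_coefficient", "transport")),
            C0=float(_require(tr, "C0", "transport")),
            Kd=float(tr.pop("Kd", 0.0)),
            inlet_bc_kind=tr.pop("inlet_bc_kind", "robin_flux"),
            bulk_density=float(tr.pop("bulk_density", bulk_density)),
        )
        tr.pop("dispersion_coefficient", None)
        tr.pop("C0", None)
        if tr:
            raise KeyError(f"unknown keys in 'transport' section: {sorted(tr)}")

    scenario = None
    if "scenario" in raw:
        sc = dict(raw["scenario"])
        scenario = ScenarioSpec(
            mode=sc.pop("mode", "continuous"),
            application_duration=sc.pop("application_duration", None),
            flush_duration=sc.pop("flush_duration", None),
        )
        if sc:
            raise KeyError(f"unknown keys in 'scenario' section: {sorted(sc)}")

    run = dict(raw.get("run", {}))
    seed = int(run.pop("seed", 0))
    output_dir = Path(run.pop("output_dir", "."))
    if run:
        raise KeyError(f"unknown keys in 'run' section: {sorted(run)}")

    for key, val in defaults_used:
        log.info("config default applied: %s = %s", key, val)
    log.info("initial moisture theta_initial = %s", column.theta_initial)

    return RunConfig(
        model=model, column=column, grid=grid, transport=transport,
        scenario=scenario, seed=seed, output_dir=output_dir, raw=raw,
    )


def provenance(config: Optional[RunConfig] = None, seed: Optional[int] = None) -> dict:
    """Machine-readable provenance block for run reports."""
    import numpy
    import scipy

    from . import __version__

    block = {
        "soilcolumn_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
    }
    if config is not None:
        block["config_hash"] = config.config_hash()
        block["seed"] = config.seed
    if seed is not None:
        block["seed"] = seed
    return block
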