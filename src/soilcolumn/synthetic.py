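"""Synthetic column-experiment data with known ground truth.

Every input the pipeline consumes can be generated here from a stated
parameter set: cumulative-infiltration readings, end-of-test
depth-concentration profiles, cumulative grain-size curves, and
spectrophotometric absorbance readings from the linear calibration
A = 0.0009 * C + 0.0992 (C in mg/L).

All generators are pure functions of (truth, seed): the same seed reproduces
the dataset bit for bit, and noise model "none" returns the forward-model
output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hydraulics import GrainSizeCurve, SoilHydraulicModel, grain_size_cdf
from .richards import ColumnSpec, FlowField, TimeGrid, solve_richards, time_to_saturation
from .transport import (
    ConcProfile,
    ScenarioSpec,
    TransportParams,
    sample_profile,
    solve_ade,
)

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "gen_infiltration",
    "gen_conc_profiles",
    "gen_grain_size",
    "absorbance_from_concentration",
    "concentration_from_absorbance",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
]

# spectrophotometric calibration line at 193 nm: A = slope * C + intercept
CALIBRATION_SLOPE = 0.0009
CALIBRATION_INTERCEPT = 0.0992


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description: none, additive or multiplicative Gaussian.

    ``sigma`` is in data units for 'additive' and a relative fraction for
    'multiplicative'.
    """

    kind: str = "none"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive", "multiplicative"):
            raise ValueError("kind must be 'none', 'additive' or 'multiplicative'")
        if self.kind != "none" and self.sigma <= 0:
            raise ValueError("sigma must be positive for a noisy model")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none":
            return values.copy()
        if self.kind == "additive":
            return values + rng.normal(0.0, self.sigma, values.shape)
        return values * (1.0 + rng.normal(0.0, self.sigma, values.shape))


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth that produced it."""

    truth: dict
    seed: int
    noise_model: NoiseModel
    payload: pd.DataFrame
    clean: pd.DataFrame = None
    extras: dict = field(default_factory=dict)

    def truth_sidecar(self) -> dict:
        """JSON-serialisable ground-truth record for recovery tests."""
        return {
            "truth": self.truth,
            "seed": self.seed,
            "noise": {"kind": self.noise_model.kind, "sigma": self.noise_model.sigma},
        }


def _model_truth_dict(model: SoilHydraulicModel) -> dict:
    return {
        "m": model.m, "n": model.n, "psi_d": model.psi_d, "Ks": model.Ks,
        "theta_s": model.theta_s, "theta_r": model.theta_r,
        "porosity": model.porosity, "s": model.s, "sm": model.sm,
    }


def gen_infiltration(
    truth: SoilHydraulicModel,
    column: ColumnSpec,
    grid: TimeGrid,
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
    cadence_min: float = 2.0,
    flow: Optional[FlowField] = None,
) -> SyntheticDataset:
    """Cumulative-infiltration readings from a forward flow run.

    Observation times are thinned to ``cadence_min`` (default 2 min, a
    realistic manual-reading cadence).  Pass a pre-solved ``flow`` to reuse a
    forward run.
    """
    if flow is None:
        flow = solve_richards(column, truth, grid)
    t_obs = np.arange(cadence_min / 60.0, grid.t_end + 1e-12, cadence_min / 60.0)
    I_clean = np.interp(t_obs, flow.t, flow.cumulative_infiltration)
    rng = np.random.default_rng(seed)
    I_noisy = noise_model.apply(I_clean, rng)
    if time_to_saturation(flow) == float("inf"):
        import warnings

        warnings.warn("column does not saturate within the simulated horizon", RuntimeWarning)
    clean = pd.DataFrame({"t_h": t_obs, "I_cm": I_clean})
    return SyntheticDataset(
        truth=_model_truth_dict(truth),
        seed=seed,
        noise_model=noise_model,
        payload=pd.DataFrame({"t_h": t_obs, "I_cm": I_noisy}),
        clean=clean,
        extras={"flow": flow},
    )


def gen_conc_profiles(
    truth: SoilHydraulicModel,
    transport: TransportParams,
    column: ColumnSpec,
    grid: TimeGrid,
    depths_cm: Sequence[float] = (1.0, 3.0, 5.0, 7.0),
    time_min: Optional[float] = None,
    scenario: ScenarioSpec = None,
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
    flow: Optional[FlowField] = None,
) -> SyntheticDataset:
    """Depth-concentration profile from a coupled flow + transport run.

    Default sampling depths 1/3/5/7 cm; the default sampling time is the
    simulated saturation time (the moment the laboratory columns were
    sectioned).
    """
    import warnings as _warnings

    scenario = scenario or ScenarioSpec(mode="continuous")
    if flow is None:
        flow = solve_richards(column, truth, grid)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        conc = solve_ade(flow, transport, scenario)
    if time_min is None:
        t_sat = time_to_saturation(flow)
        time_min = (t_sat if np.isfinite(t_sat) else flow.t[-1]) * 60.0
    profile = sample_profile(conc, depths_cm, time_min)
    rng = np.random.default_rng(seed)
    noisy = np.maximum(noise_model.apply(profile.concentrations, rng), 0.0)
    truth_dict = _model_truth_dict(truth)
    truth_dict.update(
        {"D": transport.dispersion_coefficient, "Kd": transport.Kd, "C0": transport.C0}
    )
    clean = profile.to_frame()
    payload = pd.DataFrame({"depth_cm": profile.depths_cm, "concentration_mg_L": noisy})
    return SyntheticDataset(
        truth=truth_dict,
        seed=seed,
        noise_model=noise_model,
        payload=payload,
        clean=clean,
        extras={"flow": flow, "conc": conc, "time_min": float(time_min)},
    )


def gen_grain_size(
    Dd: float,
    m: float,
    n: float,
    s: float,
    diameters_um: Sequence[float],
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> SyntheticDataset:
    """Cumulative grain-size readings from the fractal CDF model, clipped to [0, 1]."""
    d = np.asarray(diameters_um, dtype=float)
    F_clean = grain_size_cdf(d, Dd, m, n, s)
    rng = np.random.default_rng(seed)
    F_noisy = np.clip(noise_model.apply(F_clean, rng), 0.0, 1.0)
    return SyntheticDataset(
        truth={"Dd": Dd, "m": m, "n": n, "s": s},
        seed=seed,
        noise_model=noise_model,
        payload=pd.DataFrame({"diameter_um": d, "cumulative_fraction": F_noisy}),
        clean=pd.DataFrame({"diameter_um": d, "cumulative_fraction": F_clean}),
    )


def grain_curve_from_dataset(ds: SyntheticDataset) -> GrainSizeCurve:
    """Coerce a generated grain-size payload into a (monotone) GrainSizeCurve."""
    f = np.maximum.accumulate(ds.payload["cumulative_fraction"].to_numpy())
    return GrainSizeCurve(ds.payload["diameter_um"].to_numpy(), f)


def absorbance_from_concentration(
    C,
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
):
    """Absorbance reading(s) from concentration via the calibration line."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    A = CALIBRATION_SLOPE * C + CALIBRATION_INTERCEPT
    rng = np.random.default_rng(seed)
    A = noise_model.apply(A, rng)
    return A if A.ndim else float(A)


def concentration_from_absorbance(A, clip_negative: bool = False):
    """Invert the calibration line: C = (A - 0.0992) / 0.0009.

    Readings below the intercept imply a negative concentration; these raise
    by default, or are clipped to zero with ``clip_negative=True``.
    """
    A = np.asarray(A, dtype=float)
    C = (A - CALIBRATION_INTERCEPT) / CALIBRATION_SLOPE
    if np.any(C < -1e-9):
        if not clip_negative:
            raise ValueError(
                "absorbance below the calibration intercept implies a negative "
                "concentration; pass clip_negative=True to truncate"
            )
        C = np.maximum(C, 0.0)
    C = np.maximum(C, 0.0)
    return C if C.ndim else float(C)
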