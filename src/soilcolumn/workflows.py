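"""End-to-end calibration workflows on synthetic column experiments.

These functions chain generation and inverse estimation exactly the way the
laboratory study was analysed: a forward run at the stated truth produces the
observations, then the estimators recover the parameters from those
observations alone.  Generation and refitting share one grid, so for
noise-free data any residual error reflects the optimiser, not the
discretisation.

Problem sizes are desk-scale by design: 2-min infiltration readings over a
fraction-of-an-hour horizon and four sampling depths, matching the
laboratory cadence and the 8 cm column.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .inverse import DispersionFitter, FitResult, InfiltrationCurveFitter
from .presets import CasePreset, case_preset
from .richards import TimeGrid, solve_richards, time_to_saturation
from .synthetic import NoiseModel, gen_conc_profiles, gen_infiltration
from .transport import ScenarioSpec

__all__ = ["recover_flow_parameters", "recover_dispersion", "run_scenario"]

# generic (deliberately wrong) initial guesses for the inverse stage
START_KS = 0.3       # cm/h
START_PSI_D = 30.0   # cm
START_D = 1e-3       # cm^2/h


def _flow_grid(t_end: float, t_obs: np.ndarray, dt: float = 2e-3) -> TimeGrid:
    return TimeGrid(dt=dt, t_end=t_end, dt_init=1e-6, output_times=t_obs)


def recover_flow_parameters(
    case: CasePreset | str,
    t_end_h: float = 0.5,
    cadence_min: float = 2.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_starts: int = 3,
) -> tuple[FitResult, InfiltrationCurveFitter]:
    """Generate an infiltration series at the case truth and re-estimate (Ks, psi_d)."""
    if isinstance(case, str):
        case = case_preset(case)
    t_obs = np.arange(cadence_min / 60.0, t_end_h + 1e-12, cadence_min / 60.0)
    grid = _flow_grid(t_end_h, t_obs)
    ds = gen_infiltration(case.model, case.column, grid, noise_model=noise,
                          seed=seed, cadence_min=cadence_min)
    template = case.model.with_(Ks=START_KS, psi_d=START_PSI_D)
    est = InfiltrationCurveFitter(case.column, template, grid=grid, n_starts=n_starts)
    est.fit(ds.payload["t_h"].to_numpy(), ds.payload["I_cm"].to_numpy())
    return est.result_, est


def run_scenario(case: CasePreset | str, mode: str, minutes: Optional[float] = None):
    """Run a management scenario and return (flow, concentration field).

    ``mode='continuous'``: sustained application for ``minutes`` (defaults to
    the preset horizon).  ``mode='flush'``: solute application until the
    column saturates, then clean water for ``minutes``.
    """
    import warnings

    from .presets import SCENARIO_MINUTES
    from .transport import solve_ade

    if isinstance(case, str):
        case = case_preset(case)
    if minutes is None:
        minutes = SCENARIO_MINUTES[(mode, case.name)]
    if mode == "continuous":
        t_end = minutes / 60.0
        scenario = ScenarioSpec(mode="continuous")
    elif mode == "flush":
        probe = solve_richards(case.column, case.model,
                               TimeGrid(dt=2e-3, t_end=1.0, dt_init=1e-6))
        t_sat = time_to_saturation(probe)
        if not np.isfinite(t_sat):
            raise RuntimeError("column does not saturate within the 1 h probe horizon")
        t_end = t_sat + minutes / 60.0
        scenario = ScenarioSpec(mode="flush", application_duration=t_sat * 60.0,
                                flush_duration=minutes)
    else:
        raise ValueError("mode must be 'continuous' or 'flush'")
    grid = TimeGrid(dt=2e-3, t_end=t_end, dt_init=1e-6,
                    save_interval=max(t_end / 400.0, 2e-3))
    flow = solve_richards(case.column, case.model, grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conc = solve_ade(flow, case.transport, scenario)
    return flow, conc


def recover_dispersion(
    case: CasePreset | str,
    depths_cm=(1.0, 3.0, 5.0, 7.0),
    t_end_h: Optional[float] = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[FitResult, DispersionFitter]:
    """Generate a depth profile at the case truth and re-estimate D.

    The coupled forward model runs until column saturation (the sampling
    moment of the laboratory tests); the flow field is then frozen and the
    one-dimensional inverse search recovers the dispersion coefficient.
    """
    if isinstance(case, str):
        case = case_preset(case)
    if t_end_h is None:
        t_end_h = 0.5 if case.name == "pure" else 0.6
    grid = TimeGrid(dt=2e-3, t_end=t_end_h, dt_init=1e-6, save_interval=2e-3)
    flow = solve_richards(case.column, case.model, grid)
    t_sat = time_to_saturation(flow)
    if not np.isfinite(t_sat):
        raise RuntimeError(
            f"case {case.name}: column does not saturate within {t_end_h} h; "
            "extend t_end_h"
        )
    scenario = ScenarioSpec(mode="continuous")
    ds = gen_conc_profiles(
        case.model, case.transport, case.column, grid,
        depths_cm=depths_cm, time_min=t_sat * 60.0, scenario=scenario,
        noise_model=noise, seed=seed, flow=flow,
    )
    template = case.transport
    est = DispersionFitter(
        flow=flow,
        params_template=template,
        scenario=scenario,
        sample_time_min=t_sat * 60.0,
    )
    est.fit(ds.payload["depth_cm"].to_numpy(), ds.payload["concentration_mg_L"].to_numpy())
    return est.result_, est
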