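"""Inverse estimation of hydraulic and transport parameters.

Two-stage calibration, mirroring the column workflow: the flow scaling
parameters (Ks, psi_d) are estimated first from the cumulative-infiltration
curve, then the effective dispersion coefficient D from a depth-concentration
profile on the frozen flow field.

Both estimators follow the scikit-learn protocol (``fit``/``predict``/
``score``, parameters in ``__init__``, fitted attributes with a trailing
underscore) so they compose with sklearn model-selection tooling; the
module-level :func:`fit_infiltration` and :func:`fit_dispersion` are thin
functional wrappers.

Optimisation is bounded Levenberg-Marquardt-type least squares
(scipy ``least_squares``, 'trf') on log10-transformed parameters, with a
small deterministic multi-start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .hydraulics import SoilHydraulicModel
from .richards import ColumnSpec, FlowField, TimeGrid, solve_richards
from .transport import ConcProfile, ScenarioSpec, TransportParams, sample_profile, solve_ade

__all__ = [
    "FitResult",
    "rmse",
    "r2",
    "InfiltrationCurveFitter",
    "DispersionFitter",
    "fit_infiltration",
    "fit_dispersion",
]

R2_UNDEFINED = float("nan")

DEFAULT_KS_BOUNDS = (1e-3, 1e2)      # cm/h
DEFAULT_PSI_D_BOUNDS = (1.0, 1e3)    # cm
DEFAULT_D_BOUNDS = (1e-6, 10.0)      # cm^2/h


def rmse(observed, simulated) -> float:
    """Root-mean-square error sqrt(sum((o - s)^2) / N)."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size < 2:
        raise ValueError("observed and simulated must have equal length >= 2")
    return float(np.sqrt(np.mean((o - s) ** 2)))


def r2(observed, simulated) -> float:
    """Coefficient of determination about the observed mean.

    Returns NaN (sentinel) when the observations have zero variance.
    """
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size < 2:
        raise ValueError("observed and simulated must have equal length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        return R2_UNDEFINED
    return 1.0 - float(np.sum((o - s) ** 2)) / ss_tot


@dataclass(frozen=True)
class FitResult:
    """Outcome of an inverse fit: estimates plus goodness and diagnostics."""

    estimates: dict
    rmse: float
    r_squared: float
    n_obs: int
    converged: bool
    n_evals: int = 0
    bounds_hit: tuple = ()
    message: str = ""
    objective_trace: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and not (self.rmse >= 0.0):
            raise ValueError("rmse must be non-negative for a converged fit")

    def to_json(self, **extra) -> str:
        payload = {
            "estimates": self.estimates,
            "rmse": self.rmse,
            "r_squared": None if np.isnan(self.r_squared) else self.r_squared,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "bounds_hit": list(self.bounds_hit),
            "message": self.message,
            **extra,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def report(self) -> str:
        lines = [f"{k}: {v:.6g}" for k, v in self.estimates.items()]
        lines += [
            f"rmse: {self.rmse:.6g}",
            f"r_squared: {self.r_squared:.6g}",
            f"n_obs: {self.n_obs}",
            f"converged: {self.converged}",
            f"n_evals: {self.n_evals}",
        ]
        return "\n".join(lines)


class _TracedObjective:
    """Wraps a residual function, recording every evaluated objective value."""

    def __init__(self, fun):
        self.fun = fun
        self.trace: list[float] = []

    def __call__(self, x):
        res = self.fun(x)
        self.trace.append(float(np.sqrt(np.mean(np.asarray(res) ** 2))))
        return res


class InfiltrationCurveFitter(BaseEstimator, RegressorMixin):
    """Estimate (Ks, psi_d) from an observed cumulative-infiltration curve.

    The retention-curve shape (m, n, s, theta_s, theta_r) comes from the
    ``model_template`` and stays fixed; only the two scaling parameters are
    free, per the constant-head infiltration calibration.  ``fit`` expects
    ``X`` as observation times in hours (1-D or (n, 1)) and ``y`` as
    cumulative infiltrated depth in cm.

    Attributes after fitting: ``Ks_`` (cm/h), ``psi_d_`` (cm), ``model_``
    (template with the estimates substituted), ``result_`` (:class:`FitResult`).
    """

    def __init__(
        self,
        column: ColumnSpec,
        model_template: SoilHydraulicModel,
        grid: Optional[TimeGrid] = None,
        Ks_bounds: tuple = DEFAULT_KS_BOUNDS,
        psi_d_bounds: tuple = DEFAULT_PSI_D_BOUNDS,
        n_starts: int = 3,
        max_nfev: int = 60,
        diff_step: float = 1e-3,
    ):
        self.column = column
        self.model_template = model_template
        self.grid = grid
        self.Ks_bounds = Ks_bounds
        self.psi_d_bounds = psi_d_bounds
        self.n_starts = n_starts
        self.max_nfev = max_nfev
        self.diff_step = diff_step

    # -- internals ---------------------------------------------------------
    def _times(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D times or an (n, 1) column")
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValueError("times must be non-negative and strictly increasing")
        return t

    def _run_grid(self, t_obs) -> TimeGrid:
        if self.grid is not None:
            if self.grid.t_end < t_obs[-1] - 1e-12:
                raise ValueError("grid.t_end shorter than the last observation")
            return self.grid
        return TimeGrid(dt=2e-3, t_end=float(t_obs[-1]), dt_init=1e-6,
                        save_interval=max(float(t_obs[-1]) / 400.0, 2e-3))

    def simulate(self, Ks: float, psi_d: float, t_obs: np.ndarray) -> np.ndarray:
        """Forward-simulate and interpolate I(t) at the observation times."""
        model = self.model_template.with_(Ks=Ks, psi_d=psi_d)
        flow = solve_richards(self.column, model, self._run_grid(t_obs))
        return np.interp(t_obs, flow.t, flow.cumulative_infiltration)

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y):
        t_obs = self._times(X)
        I_obs = np.asarray(y, dtype=float)
        if I_obs.shape != t_obs.shape:
            raise ValueError("y must match X in length")
        if t_obs.size < 5:
            raise ValueError("need at least 5 observations")

        lb = np.log10([self.Ks_bounds[0], self.psi_d_bounds[0]])
        ub = np.log10([self.Ks_bounds[1], self.psi_d_bounds[1]])
        x0_base = np.log10([self.model_template.Ks, self.model_template.psi_d])
        start_factors = [(1.0, 1.0), (0.3, 3.0), (3.0, 0.3)]

        best = None
        best_traced = None
        total_evals = 0
        failures = []
        for fK, fP in start_factors[: max(1, self.n_starts)]:
            x0 = np.clip(x0_base + np.log10([fK, fP]), lb, ub)
            traced = _TracedObjective(
                lambda x: self.simulate(10.0 ** x[0], 10.0 ** x[1], t_obs) - I_obs
            )
            try:
                sol = least_squares(
                    traced, x0, bounds=(lb, ub), method="trf", x_scale="jac",
                    diff_step=self.diff_step, max_nfev=self.max_nfev,
                    xtol=1e-12, ftol=1e-14, gtol=1e-14,
                )
            except Exception as exc:  # solver blow-up for a pathological start
                failures.append(str(exc))
                continue
            total_evals += sol.nfev
            if best is None or sol.cost < best.cost:
                best, best_traced = sol, traced
        if best is None:
            self.result_ = FitResult(
                estimates={}, rmse=float("nan"), r_squared=float("nan"),
                n_obs=t_obs.size, converged=False, n_evals=total_evals,
                message="; ".join(failures) or "all starts failed",
            )
            raise RuntimeError(f"infiltration fit failed for all starts: {failures}")

        Ks, psi_d = 10.0 ** best.x
        I_sim = self.simulate(Ks, psi_d, t_obs)
        hit = []
        for name, xi, l, u in zip(("Ks", "psi_d"), best.x, lb, ub):
            if abs(xi - l) < 1e-9 or abs(xi - u) < 1e-9:
                hit.append(name)
        self.Ks_ = float(Ks)
        self.psi_d_ = float(psi_d)
        self.model_ = self.model_template.with_(Ks=self.Ks_, psi_d=self.psi_d_)
        self.result_ = FitResult(
            estimates={"Ks": self.Ks_, "psi_d": self.psi_d_},
            rmse=rmse(I_obs, I_sim),
            r_squared=r2(I_obs, I_sim),
            n_obs=int(t_obs.size),
            converged=bool(best.success),
            n_evals=int(total_evals),
            bounds_hit=tuple(hit),
            message=str(best.message),
            objective_trace=tuple(np.minimum.accumulate(best_traced.trace)),
            meta={"units": {"Ks": "cm/h", "psi_d": "cm"}},
        )
        return self

    def predict(self, X):
        t = self._times(X)
        return self.simulate(self.Ks_, self.psi_d_, t)


class DispersionFitter(BaseEstimator, RegressorMixin):
    """Estimate the effective dispersion coefficient D from a depth profile.

    Second calibration stage: the flow field is already solved and stays
    frozen.  ``fit`` expects ``X`` as sampling depths in cm (1-D or (n, 1))
    and ``y`` as concentrations in mg/L, all taken at ``sample_time_min``.

    The search is one-dimensional on log10 D: a coarse deterministic grid
    scan inside the bounds followed by bounded scalar minimisation around the
    best cell.  A flat objective (profile insensitive to D) is flagged via
    ``result_.converged = False`` and a warning.

    Attributes after fitting: ``D_`` (cm^2/h), ``result_``.
    """

    def __init__(
        self,
        flow: FlowField,
        params_template: TransportParams,
        scenario: ScenarioSpec,
        sample_time_min: float,
        D_bounds: tuple = DEFAULT_D_BOUNDS,
        n_grid: int = 25,
        xatol: float = 1e-5,
    ):
        self.flow = flow
        self.params_template = params_template
        self.scenario = scenario
        self.sample_time_min = sample_time_min
        self.D_bounds = D_bounds
        self.n_grid = n_grid
        self.xatol = xatol

    def _depths(self, X) -> np.ndarray:
        d = np.asarray(X, dtype=float)
        if d.ndim == 2 and d.shape[1] == 1:
            d = d[:, 0]
        if d.ndim != 1:
            raise ValueError("X must be 1-D depths or an (n, 1) column")
        return d

    def simulate(self, D: float, depths: np.ndarray) -> np.ndarray:
        params = TransportParams(
            dispersion_coefficient=float(D),
            C0=self.params_template.C0,
            Kd=self.params_template.Kd,
            inlet_bc_kind=self.params_template.inlet_bc_kind,
            bulk_density=self.params_template.bulk_density,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # Peclet warning would fire per eval
            conc = solve_ade(self.flow, params, self.scenario)
        return sample_profile(conc, depths, self.sample_time_min).concentrations

    def fit(self, X, y):
        depths = self._depths(X)
        c_obs = np.asarray(y, dtype=float)
        if c_obs.shape != depths.shape:
            raise ValueError("y must match X in length")
        evals = {"n": 0}
        trace: list[float] = []

        def objective(logD):
            evals["n"] += 1
            val = rmse(c_obs, self.simulate(10.0 ** logD, depths))
            trace.append(val)
            return val

        lo, hi = np.log10(self.D_bounds[0]), np.log10(self.D_bounds[1])
        grid = np.linspace(lo, hi, self.n_grid)
        vals = np.array([objective(g) for g in grid])
        k = int(np.argmin(vals))
        span = float(vals.max() - vals.min())
        scale = max(1.0, float(np.max(np.abs(c_obs))))
        # degenerate data (all depths equal) or an objective insensitive to D
        flat = span <= 1e-9 * scale or float(np.ptp(c_obs)) <= 1e-12 * scale
        if flat:
            warnings.warn(
                "objective is flat or the profile is zero-information "
                "(equal concentrations at all depths): D is unconstrained",
                RuntimeWarning,
                stacklevel=2,
            )
            logD_best = grid[k]
            success = False
        else:
            a = grid[max(k - 1, 0)]
            b = grid[min(k + 1, self.n_grid - 1)]
            sol = minimize_scalar(
                objective, bounds=(a, b), method="bounded",
                options={"xatol": self.xatol},
            )
            logD_best = float(sol.x)
            success = bool(sol.success)

        self.D_ = float(10.0 ** logD_best)
        c_sim = self.simulate(self.D_, depths)
        hit = ()
        if abs(logD_best - lo) < 1e-6 or abs(logD_best - hi) < 1e-6:
            hit = ("D",)
        self.result_ = FitResult(
            estimates={"D": self.D_},
            rmse=rmse(c_obs, c_sim),
            r_squared=r2(c_obs, c_sim),
            n_obs=int(depths.size),
            converged=success and not flat,
            n_evals=evals["n"],
            bounds_hit=hit,
            message="flat objective" if flat else "",
            objective_trace=tuple(np.minimum.accumulate(trace)),
            meta={"units": {"D": "cm^2/h"}, "sample_time_min": self.sample_time_min},
        )
        return self

    def predict(self, X):
        return self.simulate(self.D_, self._depths(X))


def fit_infiltration(
    observed_t_h: Sequence[float],
    observed_I_cm: Sequence[float],
    column: ColumnSpec,
    model_template: SoilHydraulicModel,
    bounds: Optional[dict] = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`InfiltrationCurveFitter`."""
    bounds = bounds or {}
    est = InfiltrationCurveFitter(
        column=column,
        model_template=model_template,
        Ks_bounds=bounds.get("Ks", DEFAULT_KS_BOUNDS),
        psi_d_bounds=bounds.get("psi_d", DEFAULT_PSI_D_BOUNDS),
        **kwargs,
    )
    est.fit(observed_t_h, observed_I_cm)
    return est.result_


def fit_dispersion(
    observed: ConcProfile,
    flow: FlowField,
    params_template: TransportParams,
    scenario: Optional[ScenarioSpec] = None,
    bounds: tuple = DEFAULT_D_BOUNDS,
    **kwargs,
) -> FitResult:
    """Functional wrapper over :class:`DispersionFitter`."""
    est = DispersionFitter(
        flow=flow,
        params_template=params_template,
        scenario=scenario or ScenarioSpec(mode="continuous"),
        sample_time_min=observed.time_min,
        D_bounds=bounds,
        **kwargs,
    )
    est.fit(observed.depths_cm, observed.concentrations)
    return est.result_
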