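"""Soil characterisation and constitutive closures.

Porosity from bulk density, the porosity/relative-fractal-dimension relation,
the van Genuchten water-retention curve, the fractal geometric-mean-pore
hydraulic-conductivity curve, and fitting of the cumulative grain-size
distribution.

Sign convention: suction ``psi`` is stored as a positive magnitude (cm of
water).  Saturated or ponded states map to ``psi <= 0`` and are treated as
fully saturated by the retention curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "SoilPhysical",
    "GrainSizeCurve",
    "SoilHydraulicModel",
    "porosity_from_bulk_density",
    "bulk_density_from_porosity",
    "solve_fractal_dimension",
    "effective_saturation",
    "moisture_content",
    "suction_from_saturation",
    "specific_capacity",
    "hydraulic_conductivity",
    "grain_size_cdf",
    "fit_grain_size_curve",
]


class InvalidSoilError(ValueError):
    """Raised when soil parameters violate physical invariants."""


@dataclass(frozen=True)
class SoilPhysical:
    """Measured physical/chemical descriptors of a soil sample.

    Texture percentages are mass fractions of the fine-earth fraction;
    densities in g/cm^3.
    """

    sand_pct: float = float("nan")
    clay_pct: float = float("nan")
    silt_pct: float = float("nan")
    bulk_density: float = 1.35
    particle_density: float = 2.65
    ph: float = float("nan")
    organic_matter_pct: float = float("nan")
    total_organic_carbon_pct: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 < self.bulk_density < self.particle_density):
            raise InvalidSoilError(
                f"bulk density {self.bulk_density} must lie in "
                f"(0, particle density = {self.particle_density})"
            )
        for name in ("sand_pct", "clay_pct", "silt_pct"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise InvalidSoilError(f"{name}={v} outside [0, 100]")

    @property
    def porosity(self) -> float:
        return porosity_from_bulk_density(self.bulk_density, self.particle_density)


@dataclass(frozen=True)
class GrainSizeCurve:
    """Cumulative particle-size distribution.

    ``diameters_um`` strictly increasing; ``cumulative_fraction[i]`` is the
    mass fraction of particles with diameter smaller than ``diameters_um[i]``.
    """

    diameters_um: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        f = np.asarray(self.cumulative_fraction, dtype=float)
        object.__setattr__(self, "diameters_um", d)
        object.__setattr__(self, "cumulative_fraction", f)
        if d.ndim != 1 or d.shape != f.shape:
            raise InvalidSoilError("diameter and fraction arrays must be 1-D and equal length")
        if not np.all(np.diff(d) > 0):
            raise InvalidSoilError("diameters must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            raise InvalidSoilError("cumulative fractions must lie in [0, 1]")
        if np.any(np.diff(f) < 0):
            raise InvalidSoilError("cumulative fractions must be non-decreasing")

    def __len__(self) -> int:
        return self.diameters_um.size


@dataclass(frozen=True)
class SoilHydraulicModel:
    """Complete parameter set of the constitutive closures.

    Attributes
    ----------
    m, n : shape parameters of the retention curve (dimensionless, > 0).
    psi_d : characteristic pressure scale, cm of suction (positive magnitude).
    Ks : saturated hydraulic conductivity, cm/h.
    theta_s, theta_r : saturated / residual volumetric moisture, cm^3/cm^3.
    porosity : total volumetric porosity phi, cm^3/cm^3.
    s : relative fractal dimension (soil fractal dimension over Euclidean 3).
    Dd : characteristic particle diameter of the grain-size curve, um.

    The conductivity exponent ``sm = 1 - 2 s / n`` is derived, never stored,
    so it can never fall out of sync with ``s`` and ``n``.
    """

    m: float
    n: float
    psi_d: float
    Ks: float
    theta_s: float
    porosity: float
    theta_r: float = 0.0
    s: float = field(default=float("nan"))
    Dd: float = float("nan")

    def __post_init__(self) -> None:
        if np.isnan(self.s):
            object.__setattr__(self, "s", solve_fractal_dimension(self.porosity))
        if self.m <= 0 or self.n <= 0:
            raise InvalidSoilError("shape parameters m, n must be positive")
        if self.psi_d <= 0:
            raise InvalidSoilError("psi_d must be a positive suction magnitude")
        if self.Ks <= 0:
            raise InvalidSoilError("Ks must be positive")
        if not (0.0 < self.s < 1.0):
            raise InvalidSoilError(f"relative fractal dimension s={self.s} outside (0, 1)")
        if not (0.0 <= self.theta_r < self.theta_s <= self.porosity <= 1.0):
            raise InvalidSoilError(
                "moisture ordering 0 <= theta_r < theta_s <= porosity <= 1 violated"
            )
        if not (0.0 < self.sm < 1.0):
            raise InvalidSoilError(
                f"conductivity exponent sm = 1 - 2s/n = {self.sm:.4f} outside (0, 1)"
            )

    @property
    def sm(self) -> float:
        """Conductivity-curve exponent, 1 - 2 s / n."""
        return 1.0 - 2.0 * self.s / self.n

    def with_(self, **kwargs) -> "SoilHydraulicModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def porosity_from_bulk_density(bulk_density: float, particle_density: float = 2.65) -> float:
    """Total porosity phi = 1 - rho_a / rho_s.

    Parameters are the dry bulk density and the particle (quartz) density,
    both in g/cm^3.
    """
    if particle_density <= 0 or bulk_density < 0:
        raise InvalidSoilError("densities must be positive")
    if bulk_density > particle_density:
        raise InvalidSoilError(
            f"bulk density {bulk_density} exceeds particle density {particle_density}"
        )
    return 1.0 - bulk_density / particle_density


def bulk_density_from_porosity(porosity: float, particle_density: float = 2.65) -> float:
    """Algebraic inverse of :func:`porosity_from_bulk_density`."""
    if not (0.0 <= porosity <= 1.0):
        raise InvalidSoilError("porosity outside [0, 1]")
    return (1.0 - porosity) * particle_density


def _fractal_residual(s: float, phi: float) -> float:
    return (1.0 - phi) ** s + phi ** (2.0 * s) - 1.0


def solve_fractal_dimension(
    phi: float, tol: float = 1e-12, s0: float = 0.7, max_iter: int = 100
) -> float:
    """Relative fractal dimension s from porosity.

    Solves (1 - phi)^s + phi^(2 s) = 1 for s in (0, 1) by Newton-Raphson
    started at ``s0``, with a bracketed bisection (Brent) fallback.
    """
    if not (0.0 < phi < 1.0):
        raise InvalidSoilError(f"porosity {phi} outside (0, 1)")
    if tol <= 0:
        raise InvalidSoilError("tol must be positive")
    la, lb = np.log(1.0 - phi), np.log(phi)
    s = s0
    for _ in range(max_iter):
        f = _fractal_residual(s, phi)
        df = la * (1.0 - phi) ** s + 2.0 * lb * phi ** (2.0 * s)
        if df == 0.0:
            break
        step = f / df
        s_new = s - step
        if not (0.0 < s_new < 1.0):
            break
        s = s_new
        if abs(_fractal_residual(s, phi)) < tol:
            return s
    # Newton left the unit interval or stalled: fall back to a bracketed search
    lo, hi = 1e-3, 1.0 - 1e-3
    flo, fhi = _fractal_residual(lo, phi), _fractal_residual(hi, phi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change for fractal-dimension root on [{lo}, {hi}] at phi={phi}"
        )
    return brentq(_fractal_residual, lo, hi, args=(phi,), xtol=1e-15, rtol=8.9e-16)


def effective_saturation(psi, model: SoilHydraulicModel):
    """van Genuchten effective saturation Theta(psi) = [1 + (psi/psi_d)^n]^(-m).

    ``psi`` is suction magnitude in cm; values <= 0 (ponded/saturated) give 1.
    """
    psi = np.asarray(psi, dtype=float)
    ratio = np.where(psi > 0, psi / model.psi_d, 0.0)
    theta_eff = (1.0 + ratio**model.n) ** (-model.m)
    return theta_eff if theta_eff.ndim else float(theta_eff)


def moisture_content(psi, model: SoilHydraulicModel):
    """Volumetric moisture theta = theta_r + (theta_s - theta_r) * Theta(psi)."""
    return model.theta_r + (model.theta_s - model.theta_r) * effective_saturation(psi, model)


def suction_from_saturation(theta_eff, model: SoilHydraulicModel):
    """Inverse retention curve: suction magnitude at a given effective saturation."""
    theta_eff = np.asarray(theta_eff, dtype=float)
    if np.any(theta_eff <= 0) or np.any(theta_eff > 1):
        raise InvalidSoilError("effective saturation must lie in (0, 1]")
    psi = model.psi_d * (theta_eff ** (-1.0 / model.m) - 1.0) ** (1.0 / model.n)
    return psi if psi.ndim else float(psi)


def specific_capacity(psi, model: SoilHydraulicModel):
    """Slope of the retention curve, |d theta / d psi|, in 1/cm.

    Returned as a positive magnitude (theta decreases with suction); zero on
    the saturated plateau psi <= 0.  The flow solver consumes this as
    d theta / d(pressure head), which carries the same positive sign.
    """
    psi = np.asarray(psi, dtype=float)
    ratio = np.where(psi > 0, psi / model.psi_d, 0.0)
    rn = ratio**model.n
    # dTheta/dpsi = -m*n/psi_d * ratio^(n-1) * (1+ratio^n)^(-m-1)
    with np.errstate(invalid="ignore"):
        dtheta = (
            (model.theta_s - model.theta_r)
            * model.m
            * model.n
            / model.psi_d
            * np.where(psi > 0, ratio ** (model.n - 1.0), 0.0)
            * (1.0 + rn) ** (-model.m - 1.0)
        )
    dtheta = np.where(psi > 0, dtheta, 0.0)
    return dtheta if dtheta.ndim else float(dtheta)


def hydraulic_conductivity(theta_eff, model: SoilHydraulicModel, form: str = "fractal"):
    """Unsaturated hydraulic conductivity from the geometric-mean pore model.

    K(Theta) = Ks * [1 - (1 - Theta^(1/m))^sm]^2 with sm = 1 - 2 s / n.

    ``form='fractal'`` is the printed reading of the model; the typographic
    alternative ``form='fractal-alt'`` swaps the inner exponents,
    K = Ks * [1 - (1 - Theta^(1/sm))^m]^2.
    """
    if not (0.0 < model.sm < 1.0):
        raise InvalidSoilError("sm outside (0,1)")
    theta_eff = np.asarray(theta_eff, dtype=float)
    if np.any(theta_eff < 0) or np.any(theta_eff > 1.0 + 1e-12):
        raise InvalidSoilError("effective saturation outside [0, 1]")
    theta_eff = np.clip(theta_eff, 0.0, 1.0)
    if form == "fractal":
        inner = (1.0 - theta_eff ** (1.0 / model.m)) ** model.sm
    elif form == "fractal-alt":
        inner = (1.0 - theta_eff ** (1.0 / model.sm)) ** model.m
    else:
        raise ValueError(f"unknown conductivity form {form!r}")
    K = model.Ks * (1.0 - inner) ** 2
    return K if K.ndim else float(K)


def grain_size_cdf(diameters_um, Dd: float, m: float, n: float, s: float):
    """Cumulative grain-size model F(D) = [1 + (Dd/D)^(n/(2(1-s)))]^(-m)."""
    d = np.asarray(diameters_um, dtype=float)
    p = n / (2.0 * (1.0 - s))
    F = (1.0 + (Dd / d) ** p) ** (-m)
    return F if F.ndim else float(F)


def _log_spacing_weights(diameters: np.ndarray) -> np.ndarray:
    """Weights proportional to local log-diameter spacing (trapezoid widths)."""
    logd = np.log(diameters)
    w = np.gradient(logd)
    w = w / w.mean()
    return np.sqrt(w)


def fit_grain_size_curve(data: GrainSizeCurve, s: float, n_starts: int = 3):
    """Fit (Dd, m, n) of the cumulative grain-size model to measured points.

    The relative fractal dimension ``s`` is held fixed (it is determined by
    porosity alone).  Least squares on log-spacing-weighted residuals with a
    small multi-start over the initial guess.  Returns a
    :class:`soilcolumn.inverse.FitResult` with estimates ``Dd``, ``m``, ``n``.
    """
    from .inverse import FitResult, r2, rmse  # local import to avoid a cycle

    if len(data) < 4:
        raise InvalidSoilError("need at least 4 grain-size points")
    d = data.diameters_um
    f_obs = data.cumulative_fraction
    w = _log_spacing_weights(d)

    def residual(x):
        Dd, m, n = np.exp(x)
        return w * (grain_size_cdf(d, Dd, m, n, s) - f_obs)

    # initial guesses: median diameter scale, generic shape values
    d_mid = float(np.interp(0.5, f_obs, d)) if f_obs[-1] > 0.5 else float(d[-1])
    starts = [(d_mid, 0.3, 2.0), (10.0 * d_mid, 0.15, 3.0), (0.3 * d_mid, 0.6, 1.5)]
    lb = np.log([1e-2, 1e-3, 2.0 * (1.0 - s) * 1e-3])
    ub = np.log([1e7, 10.0, 50.0])
    best = None
    n_evals = 0
    for Dd0, m0, n0 in starts[: max(1, n_starts)]:
        x0 = np.clip(np.log([Dd0, m0, n0]), lb, ub)
        try:
            sol = least_squares(residual, x0, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:  # pragma: no cover - optimizer hard failure
            continue
        n_evals += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(estimates={}, rmse=float("nan"), r_squared=float("nan"),
                         n_obs=len(data), converged=False, n_evals=n_evals,
                         message="all starts failed")
    Dd, m, n = np.exp(best.x)
    f_sim = grain_size_cdf(d, Dd, m, n, s)
    hit = [name for name, xi, l, u in zip(("Dd", "m", "n"), best.x, lb, ub)
           if abs(xi - l) < 1e-8 or abs(xi - u) < 1e-8]
    if not best.success:
        warnings.warn("grain-size fit did not meet convergence criteria", RuntimeWarning)
    return FitResult(
        estimates={"Dd": float(Dd), "m": float(m), "n": float(n)},
        rmse=rmse(f_obs, f_sim),
        r_squared=r2(f_obs, f_sim),
        n_obs=len(data),
        converged=bool(best.success),
        n_evals=n_evals,
        bounds_hit=hit,
        message=best.message,
        objective_trace=(float(np.sqrt(2.0 * best.cost / len(data))),),
    )
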