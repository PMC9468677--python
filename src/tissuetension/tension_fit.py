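"""Inverse problem: fit (b, c) to measured geometry and convert c to tension.

The measured quantities are the height ``h``, width ``w`` and volume ``V``
of the flattened aggregate.  Working in units of the equivalent radius
``R_eq = (3 V_obs / 4 pi)^(1/3)`` the model has two dimensionless unknowns
(apex curvature ``b~ = b R_eq`` and capillary constant ``c~ = c R_eq^2``)
and the fit minimises the sum of squared relative errors on h, w and V.
Relative errors make the three observables commensurable despite their
different dimensions.

The capillary constant maps to surface tension through the magnetic
calibration gamma = M_V * grad(B) / c, with M_V the magnetic moment per
unit volume (A/m) and grad(B) the field gradient (T/m).  As c -> 0 the drop
approaches a sphere and gamma is no longer identifiable: the data only
bound it from below.  Fits with c~ below FLAT_DETECTION_THRESHOLD therefore
report a lower bound instead of a value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares

from .laplace_shape import (
    GeometryObservables,
    ShapeParams,
    NonClosureError,
    equivalent_radius,
    shape_observables,
)

#: Dimensionless capillary constant below which the drop is treated as an
#: unflattened sphere: the objective is flat in c~ there and only a lower
#: bound on gamma can be reported.
FLAT_DETECTION_THRESHOLD = 1e-3

#: Relative tolerance allowed on h > w before declaring model mismatch
#: (the model cannot produce prolate shapes for c >= 0).
PROLATE_TOL = 5e-3

_VOLUME_TILDE = 4.0 * np.pi / 3.0  # model volume target in R_eq units


class ModelMismatchError(ValueError):
    """Observed geometry cannot be produced by the model (e.g. h > w)."""


class NotFlattenedError(ValueError):
    """Flattening below detection: only a lower bound on gamma exists."""

    def __init__(self, message: str, gamma_lower_bound: Optional[float] = None):
        super().__init__(message)
        self.gamma_lower_bound = gamma_lower_bound


@dataclass(frozen=True)
class MagneticContext:
    """Magnetic calibration of the tensiometer.

    Attributes
    ----------
    m_v : float
        Magnetic moment per unit volume of the labelled tissue, A/m
        (from vibrating-sample magnetometry).
    grad_b : float
        Magnetic field gradient at the sample, T/m.
    b_field_mt : float, optional
        Field magnitude in mT; informational only (the force depends on
        M_V and grad B).
    """

    m_v: float
    grad_b: float
    b_field_mt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m_v <= 0:
            raise ValueError(f"M_V must be positive, got {self.m_v}")
        if self.grad_b <= 0:
            raise ValueError(f"grad(B) must be positive, got {self.grad_b}")

    @property
    def force_density(self) -> float:
        """Magnetic body-force density M_V * grad(B), N/m^3."""
        return self.m_v * self.grad_b


@dataclass(frozen=True)
class FitDiagnostics:
    residual: float
    converged: bool
    n_evaluations: int
    grid_best: tuple[float, float]
    message: str = ""


@dataclass(frozen=True)
class TensionResult:
    """Outcome of a tensiometry fit.

    ``gamma`` (mN/m) is present only when the fit converged and the drop is
    measurably flattened; for sphere-like drops ``gamma_lower_bound``
    carries the bound implied by the flat-detection threshold.
    ``params`` is in physical units (1/um, 1/um^2 when observables are um).
    """

    params: ShapeParams
    gamma: Optional[float]
    residual: float
    converged: bool
    predicted: GeometryObservables
    flattened: bool
    gamma_lower_bound: Optional[float] = None
    diagnostics: Optional[FitDiagnostics] = None

    def to_dict(self) -> dict:
        return {
            "gamma_mn_per_m": None if self.gamma is None else float(self.gamma),
            "b_per_um": float(self.params.b),
            "c_per_um2": float(self.params.c),
            "residual": float(self.residual),
            "converged": bool(self.converged),
            "flattened": bool(self.flattened),
            "gamma_lower_bound_mn_per_m": None if self.gamma_lower_bound is None else float(self.gamma_lower_bound),
            "predicted": {"h": float(self.predicted.h), "w": float(self.predicted.w), "V": float(self.predicted.V)},
        }


def _solve_b_for_volume(c_tilde: float, rtol: float = 1e-8) -> float:
    """Find b~ such that the model volume equals 4 pi / 3 at the given c~.

    The volume decreases monotonically in b~ (larger curvature, smaller
    drop), so a bracketing root find is reliable.
    """

    def vol_err(b_tilde: float) -> float:
        return shape_observables(ShapeParams(b_tilde, c_tilde), rtol=rtol).V - _VOLUME_TILDE

    lo, hi = 0.2, 5.0
    flo, fhi = vol_err(lo), vol_err(hi)
    while flo < 0 and lo > 1e-8:
        lo /= 4.0
        flo = vol_err(lo)
    while fhi > 0 and hi < 1e4:
        hi *= 4.0
        fhi = vol_err(hi)
    if flo < 0 or fhi > 0:
        raise NonClosureError(f"no apex curvature matches the target volume at c~ = {c_tilde:g}")
    return brentq(vol_err, lo, hi, xtol=1e-9, rtol=4e-12)


def _residuals(theta: np.ndarray, obs_tilde: GeometryObservables, rtol: float) -> np.ndarray:
    """Relative residuals on (h, w, V) at log-parameters theta = (ln b~, ln c~)."""
    b_t, c_t = np.exp(np.clip(theta, -60.0, 60.0))
    try:
        pred = shape_observables(ShapeParams(b_t, max(c_t, 0.0)), rtol=rtol)
    except (NonClosureError, ValueError):
        return np.array([1e3, 1e3, 1e3])
    return np.array(
        [
            (pred.h - obs_tilde.h) / obs_tilde.h,
            (pred.w - obs_tilde.w) / obs_tilde.w,
            (pred.V - obs_tilde.V) / obs_tilde.V,
        ]
    )


def _objective(theta: np.ndarray, obs_tilde: GeometryObservables, rtol: float) -> float:
    return float(np.sum(_residuals(theta, obs_tilde, rtol) ** 2))


def fit_shape(
    obs: GeometryObservables,
    grid_points: int = 10,
    ode_rtol: float = 1e-8,
    grid_rtol: float = 1e-6,
) -> tuple[ShapeParams, FitDiagnostics]:
    """Fit the dimensionless shape parameters (b~, c~) to observed (h, w, V).

    Strategy: scale the observables by R_eq from the observed volume, scan a
    log-spaced grid of c~ in [1e-3, 1e2] with b~ chosen at each grid point to
    conserve the volume, then refine the best grid point by damped least
    squares on the three relative residuals in log-parameter space (the
    log transform enforces positivity).  The sphere (c~ at the
    flat-detection floor) is included as a grid candidate so unflattened
    drops converge there.

    Returns the fitted parameters in the *scaled* (R_eq) units together with
    diagnostics; use :func:`fit_tension` for physical units and gamma.

    Raises
    ------
    ModelMismatchError
        If h exceeds w beyond tolerance (prolate input).
    """
    if obs.h > obs.w * (1.0 + PROLATE_TOL):
        raise ModelMismatchError(
            f"h = {obs.h:g} > w = {obs.w:g}: the model cannot produce prolate shapes for c >= 0"
        )
    r_eq = equivalent_radius(obs.V)
    obs_t = GeometryObservables(h=obs.h / r_eq, w=obs.w / r_eq, V=obs.V / r_eq**3)

    # Coarse grid over c~, volume-conserving b~ at each point.
    c_grid = np.concatenate([[FLAT_DETECTION_THRESHOLD], np.logspace(-2, 2, grid_points)])
    best = (np.inf, None)
    n_eval = 0
    for c_t in c_grid:
        try:
            b_t = _solve_b_for_volume(c_t, rtol=grid_rtol)
            val = _objective(np.log([b_t, c_t]), obs_t, grid_rtol)
        except (NonClosureError, ValueError):
            continue
        n_eval += 1
        if val < best[0]:
            best = (val, (b_t, c_t))
    if best[1] is None:
        raise ModelMismatchError("no admissible model shape found on the search grid")

    b0, c0 = best[1]
    res = least_squares(
        _residuals,
        np.log([b0, c0]),
        args=(obs_t, ode_rtol),
        method="lm",
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
    )
    b_t, c_t = np.exp(res.x)
    diag = FitDiagnostics(
        residual=float(2.0 * res.cost),
        converged=bool(res.success),
        n_evaluations=n_eval + res.nfev,
        grid_best=(b0, c0),
        message=res.message,
    )
    return ShapeParams(b_t, max(c_t, 0.0)), diag


def gamma_from_c(c: float, ctx: MagneticContext, c_unit: str = "per_um2") -> float:
    """Surface tension gamma = M_V * grad(B) / c, returned in mN/m.

    Parameters
    ----------
    c : float
        Capillary constant, in 1/um^2 (default) or 1/m^2 (``c_unit='per_m2'``).
    ctx : MagneticContext
        Magnetic calibration supplying the body-force density in N/m^3.
    """
    if c <= 0:
        raise NotFlattenedError("capillary constant must be positive to infer gamma")
    if c_unit == "per_um2":
        c_si = c * 1e12
    elif c_unit == "per_m2":
        c_si = c
    else:
        raise ValueError(f"unknown c_unit {c_unit!r}")
    gamma_si = ctx.force_density / c_si  # N/m
    return gamma_si * 1e3  # mN/m


def fit_tension(
    obs: GeometryObservables,
    ctx: MagneticContext,
    grid_points: int = 10,
    ode_rtol: float = 1e-8,
) -> TensionResult:
    """Full inverse pipeline: fit (b, c) to (h, w, V) in um and report gamma.

    Observables must be in micrometres (h, w) and cubic micrometres (V).
    When the fitted flattening is below the detection threshold the result
    carries ``gamma=None``, ``flattened=False`` and the lower bound on gamma
    implied by the undetectably small c.
    """
    params_t, diag = fit_shape(obs, grid_points=grid_points, ode_rtol=ode_rtol)
    r_eq = equivalent_radius(obs.V)
    params = ShapeParams(b=params_t.b / r_eq, c=params_t.c / r_eq**2)
    pred_t = shape_observables(params_t, rtol=ode_rtol)
    predicted = GeometryObservables(h=pred_t.h * r_eq, w=pred_t.w * r_eq, V=pred_t.V * r_eq**3)

    flattened = params_t.c > FLAT_DETECTION_THRESHOLD
    gamma = None
    bound = None
    if flattened and diag.converged:
        gamma = gamma_from_c(params.c, ctx)
    else:
        c_floor = FLAT_DETECTION_THRESHOLD / r_eq**2
        bound = gamma_from_c(c_floor, ctx)
    return TensionResult(
        params=params,
        gamma=gamma,
        residual=diag.residual,
        converged=diag.converged,
        predicted=predicted,
        flattened=flattened,
        gamma_lower_bound=bound,
        diagnostics=diag,
    )
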