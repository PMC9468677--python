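"""Forward model: axisymmetric Young-Laplace profile under a uniform body force.

The meridional profile of a non-wetting sessile drop flattened by a uniform
downward body force is parametrised by arc length ``s`` from the apex and
obeys

    dx/ds   = cos(phi)
    dz/ds   = sin(phi)
    dphi/ds = 2*b + c*z - sin(phi)/x

where ``x`` is the radial distance to the symmetry axis, ``z`` the depth
below the apex (positive in the direction of the force), ``phi`` the
inclination of the profile, ``b`` the apex curvature and ``c`` the capillary
constant (body-force density over surface tension).  For ``c = 0`` the
solution is a sphere of radius ``1/b``; increasing ``c`` flattens the drop.

The drop sits on a non-adhesive substrate, so the profile is integrated from
the apex (``x = z = phi = 0``) down to the 180-degree contact point
``phi = pi``.  The term ``sin(phi)/x`` has a removable singularity at the
apex (it tends to ``b``), handled by starting the integration one short
analytic series step away from ``s = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


class NonClosureError(RuntimeError):
    """The profile never reached phi = pi within the guard arc length."""


@dataclass(frozen=True)
class ShapeParams:
    """The two unknowns of the shape problem.

    Attributes
    ----------
    b : float
        Curvature at the apex, units 1/length.  Must be positive.
    c : float
        Capillary constant (body-force density / surface tension),
        units 1/length**2.  ``c = 0`` is the force-free sphere; negative
        values are rejected.
    """

    b: float
    c: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.b) or self.b <= 0:
            raise ValueError(f"apex curvature b must be positive, got {self.b}")
        if not np.isfinite(self.c) or self.c < 0:
            raise ValueError(f"capillary constant c must be >= 0, got {self.c}")


@dataclass(frozen=True)
class ProfileCurve:
    """Integrated meridional profile, sampled along arc length.

    ``s`` increases strictly from 0; ``x >= 0`` is the radial coordinate,
    ``z >= 0`` the depth below the apex, ``phi`` the inclination in
    [0, pi].  The final sample is the contact point ``phi = pi``.
    ``volume`` is the solid-of-revolution volume accumulated by the
    integrator, ``x_max`` the equatorial radius located by the
    ``phi = pi/2`` event.
    """

    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    volume: float
    x_max: float
    params: ShapeParams

    @property
    def closed(self) -> bool:
        return bool(self.phi[-1] >= np.pi - 1e-6)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"s": self.s, "x": self.x, "z": self.z, "phi": self.phi})


@dataclass(frozen=True)
class GeometryObservables:
    """Height, width and volume of an aggregate (measured or predicted)."""

    h: float
    w: float
    V: float

    def __post_init__(self) -> None:
        for name, v in (("h", self.h), ("w", self.w), ("V", self.V)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"observable {name} must be positive, got {v}")

    @property
    def aspect(self) -> float:
        """Height-to-width ratio; 1 for a sphere, < 1 when flattened."""
        return self.h / self.w


# Arc length of the analytic series step that skips the apex singularity,
# in the units of 1/b (i.e. multiplied by 1/b before use).
_APEX_STEP = 1e-6
# Guard: if phi has not reached pi within this many units of 1/b, the
# parameters are pathological.
_GUARD_ARC = 50.0


def _apex_series(params: ShapeParams, s0: float) -> np.ndarray:
    """Series expansion of (x, z, phi, V) near the apex.

    Near s = 0 the profile is locally spherical with curvature b:
    phi = b*s + O(s^3), x = s - b^2 s^3/6 + O(s^5), z = b s^2/2 + O(s^4).
    """
    b = params.b
    x0 = s0 - (b * b) * s0**3 / 6.0
    z0 = b * s0**2 / 2.0
    phi0 = b * s0
    v0 = np.pi * b * s0**4 / 4.0  # pi * int x^2 sin(phi) ds ~ pi b s^4/4
    return np.array([x0, z0, phi0, v0])


def _rhs(s: float, y: np.ndarray, b: float, c: float) -> list[float]:
    x, z, phi, _ = y
    sphi = np.sin(phi)
    return [np.cos(phi), sphi, 2.0 * b + c * z - sphi / x, np.pi * x * x * sphi]


def integrate_profile(
    params: ShapeParams,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_samples: int = 2000,
    dense: bool = True,
) -> ProfileCurve:
    """Integrate the profile from the apex to the phi = pi contact point.

    Parameters
    ----------
    params : ShapeParams
        Apex curvature and capillary constant (any consistent length unit).
    rtol, atol : float
        Tolerances of the adaptive integrator.  ``atol`` is scaled by the
        natural length 1/b so accuracy is unit-independent.
    max_samples : int
        Number of dense samples returned along the curve.
    dense : bool
        When False, skip the dense resampling and return only the solver's
        own steps plus the terminal point (sufficient for (h, w, V); much
        faster inside the fitting loop).

    Returns
    -------
    ProfileCurve
        Profile samples plus the accumulated solid-of-revolution volume and
        the equatorial radius.

    Raises
    ------
    NonClosureError
        If phi never reaches pi within an arc length of 50/b.
    ValueError
        Via ShapeParams validation (b <= 0 or c < 0).
    """
    b, c = params.b, params.c
    if c == 0.0:
        # Force-free limit: the profile is exactly a sphere of radius 1/b.
        # The ODE is singular at closure there (x -> 0 as phi -> pi), so the
        # closed form replaces the integration.
        s = np.linspace(0.0, np.pi / b, max_samples)
        return ProfileCurve(
            s=s,
            x=np.sin(b * s) / b,
            z=(1.0 - np.cos(b * s)) / b,
            phi=b * s,
            volume=4.0 * np.pi / (3.0 * b**3),
            x_max=1.0 / b,
            params=params,
        )
    scale = 1.0 / b
    s0 = _APEX_STEP * scale
    y0 = _apex_series(params, s0)

    def contact(s, y, *args):
        return y[2] - np.pi

    contact.terminal = True
    contact.direction = 1

    def equator(s, y, *args):
        return y[2] - np.pi / 2

    equator.direction = 1

    sol = solve_ivp(
        _rhs,
        (s0, _GUARD_ARC * scale),
        y0,
        args=(b, c),
        method="DOP853",
        rtol=rtol,
        atol=atol * scale,
        events=(contact, equator),
        dense_output=dense,
    )
    if not sol.success or len(sol.t_events[0]) == 0:
        raise NonClosureError(
            f"profile for b={b:g}, c={c:g} did not reach phi=pi within arc length {_GUARD_ARC / b:g}"
        )

    s_end = sol.t_events[0][0]
    y_end = sol.y_events[0][0]

    # Equatorial radius from the phi = pi/2 event (dx/ds = 0 there).
    if len(sol.t_events[1]):
        x_max = float(sol.y_events[1][0][0])
    else:  # pragma: no cover - phi=pi/2 always precedes phi=pi
        x_max = float(np.max(sol.y[0]))

    if dense:
        s_samp = np.linspace(0.0, s_end, max_samples)
        y_samp = sol.sol(np.clip(s_samp, s0, s_end))
        # Patch the apex region with the series values.
        below = s_samp < s0
        if np.any(below):
            for i in np.nonzero(below)[0]:
                y_samp[:, i] = _apex_series(params, s_samp[i]) if s_samp[i] > 0 else (0, 0, 0, 0)
        y_samp[:, -1] = y_end
    else:
        keep = sol.t < s_end
        s_samp = np.concatenate([[0.0], sol.t[keep], [s_end]])
        y_samp = np.concatenate(
            [np.zeros((4, 1)), sol.y[:, keep], y_end[:, None]], axis=1
        )

    return ProfileCurve(
        s=s_samp,
        x=y_samp[0],
        z=y_samp[1],
        phi=np.clip(y_samp[2], 0.0, np.pi),
        volume=float(y_end[3]),
        x_max=x_max,
        params=params,
    )


def compute_observables(profile: ProfileCurve) -> GeometryObservables:
    """Height, width and volume of the drop described by a closed profile.

    h is the depth of the contact point below the apex, w twice the
    equatorial radius, and V the volume of the solid of revolution
    ``pi * int x^2 sin(phi) ds`` (the flat contact disk closes the surface
    and contributes no volume).
    """
    if not profile.closed:
        raise ValueError("profile does not reach phi = pi; cannot measure a closed drop")
    return GeometryObservables(h=float(profile.z[-1]), w=2.0 * profile.x_max, V=profile.volume)


def shape_observables(params: ShapeParams, rtol: float = 1e-9) -> GeometryObservables:
    """Convenience composition: integrate the profile and measure (h, w, V)."""
    return compute_observables(integrate_profile(params, rtol=rtol, dense=False))


def equivalent_radius(volume: float) -> float:
    """Radius of the sphere with the given volume, R = (3V / 4 pi)^(1/3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def nondimensionalize(params: ShapeParams, length_scale: float) -> ShapeParams:
    """Scale (b, c) by a reference length R: b~ = b*R, c~ = c*R**2."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    return ShapeParams(b=params.b * length_scale, c=params.c * length_scale**2)


def redimensionalize(params: ShapeParams, length_scale: float) -> ShapeParams:
    """Inverse of :func:`nondimensionalize`."""
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    return ShapeParams(b=params.b / length_scale, c=params.c / length_scale**2)


def profile_to_csv(profile: ProfileCurve, path, unit: str = "dimensionless") -> None:
    """Write the profile as CSV (columns s, x, z, phi) with a unit comment."""
    df = profile.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# length unit: {unit}\n")
        df.to_csv(fh, index=False)
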