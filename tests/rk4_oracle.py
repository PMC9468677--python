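"""Independent fixed-step RK4 reference integrator for the profile equation.

Brute-force oracle for the adaptive integrator: classical RK4 with a fixed
step (default 1e-5 in apex-curvature units), trapezoid accumulation of the
solid-of-revolution volume, and Newton refinement of the phi = pi terminal
point inside the final step.  Shares no code with the package integrator.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _deriv(x, z, phi, b, c):
    sphi = np.sin(phi)
    return np.cos(phi), sphi, 2.0 * b + c * z - sphi / x


@numba.njit(cache=True)
def _step(x, z, phi, h, b, c):
    k1x, k1z, k1p = _deriv(x, z, phi, b, c)
    k2x, k2z, k2p = _deriv(x + 0.5 * h * k1x, z + 0.5 * h * k1z, phi + 0.5 * h * k1p, b, c)
    k3x, k3z, k3p = _deriv(x + 0.5 * h * k2x, z + 0.5 * h * k2z, phi + 0.5 * h * k2p, b, c)
    k4x, k4z, k4p = _deriv(x + h * k3x, z + h * k3z, phi + h * k3p, b, c)
    return (
        x + h * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0,
        z + h * (k1z + 2 * k2z + 2 * k3z + k4z) / 6.0,
        phi + h * (k1p + 2 * k2p + 2 * k3p + k4p) / 6.0,
    )


@numba.njit(cache=True)
def rk4_profile(b, c, step=1e-5):
    """Integrate the profile to phi = pi.

    Returns (s_end, x_end, z_end, volume, x_max); s and lengths are in the
    caller's units (step is scaled by 1/b internally).
    """
    h = step / b
    s = 1e-6 / b
    x = s
    z = b * s * s / 2.0
    phi = b * s
    vol = np.pi * b * s**4 / 4.0
    x_max = x
    guard = 50.0 / b
    while phi < np.pi and s < guard:
        x0, z0, phi0 = x, z, phi
        f0 = np.pi * x0 * x0 * np.sin(phi0)
        x, z, phi = _step(x0, z0, phi0, h, b, c)
        if phi >= np.pi:
            # Newton-refine the phi = pi crossing inside [s, s + h].
            dt = h
            for _ in range(5):
                xe, ze, pe = _step(x0, z0, phi0, dt, b, c)
                _, _, dp = _deriv(xe, ze, pe, b, c)
                dt += (np.pi - pe) / dp
            x, z, phi = _step(x0, z0, phi0, dt, b, c)
            vol += 0.5 * dt * (f0 + np.pi * x * x * np.sin(phi))
            s += dt
            if x > x_max:
                x_max = x
            return s, x, z, vol, x_max
        vol += 0.5 * h * (f0 + np.pi * x * x * np.sin(phi))
        if x > x_max:
            x_max = x
        s += h
    return s, x, z, vol, x_max
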