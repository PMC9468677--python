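"""Forward shape model: sphere limits, profile invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuetension.laplace_shape import (
    ShapeParams,
    compute_observables,
    equivalent_radius,
    integrate_profile,
    nondimensionalize,
    redimensionalize,
    shape_observables,
)

from rk4_oracle import rk4_profile


@pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 3.7])
def test_force_free_profile_is_a_sphere(b):
    """With no body force the drop is a sphere of radius 1/b."""
    prof = integrate_profile(ShapeParams(b, 0.0))
    obs = compute_observables(prof)
    r = 1.0 / b
    assert obs.h == pytest.approx(2 * r, rel=1e-9)
    assert obs.w == pytest.approx(2 * r, rel=1e-9)
    assert obs.V == pytest.approx(4 * np.pi * r**3 / 3, rel=1e-9)
    assert prof.s[-1] == pytest.approx(np.pi * r, rel=1e-9)


@pytest.mark.parametrize("b,c", [(1.0, 0.5), (1.0, 1.0), (0.7, 3.0), (2.0, 0.1)])
def test_profile_invariants(b, c):
    """Apex start, monotone depth, inclination within [0, pi], closure."""
    prof = integrate_profile(ShapeParams(b, c))
    assert prof.x[0] == 0 and prof.z[0] == 0 and prof.phi[0] == 0
    assert np.all(np.diff(prof.s) > 0)
    assert np.all(np.diff(prof.z) >= -1e-12)
    assert np.all((prof.phi >= 0) & (prof.phi <= np.pi))
    assert prof.phi[-1] == pytest.approx(np.pi, abs=1e-8)
    assert np.all(prof.x >= 0)
    assert prof.closed


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ShapeParams(0.0, 1.0)
    with pytest.raises(ValueError):
        ShapeParams(-1.0, 1.0)
    with pytest.raises(ValueError):
        ShapeParams(1.0, -0.5)


def test_adaptive_matches_fixed_step_reference():
    """Terminal point of the adaptive integration agrees with a fixed-step
    RK4 reference at step 1e-5 to better than 1e-6 relative."""
    prof = integrate_profile(ShapeParams(1.0, 0.5))
    s, x, z, v, xmax = rk4_profile(1.0, 0.5)
    assert prof.z[-1] == pytest.approx(z, rel=1e-6)
    assert prof.x[-1] == pytest.approx(x, rel=1e-6)


def test_volume_matches_trapezoid_quadrature_oracle():
    """Accumulated volume agrees with trapezoid quadrature on the fine-step
    reference profile."""
    prof = integrate_profile(ShapeParams(1.0, 1.0))
    _, _, _, v_ref, _ = rk4_profile(1.0, 1.0)
    assert prof.volume == pytest.approx(v_ref, rel=1e-5)


def test_observables_require_closed_profile():
    prof = integrate_profile(ShapeParams(1.0, 0.5))
    bad = type(prof)(
        s=prof.s[:100], x=prof.x[:100], z=prof.z[:100], phi=prof.phi[:100],
        volume=prof.volume, x_max=prof.x_max, params=prof.params,
    )
    with pytest.raises(ValueError, match="phi"):
        compute_observables(bad)


def test_oblate_only():
    """Flattened drops are wider than tall; equality holds only force-free."""
    sphere = shape_observables(ShapeParams(1.0, 0.0))
    assert sphere.h == pytest.approx(sphere.w, rel=1e-12)
    for c in [0.25, 1.0, 4.0]:
        obs = shape_observables(ShapeParams(1.0, c))
        assert obs.h < obs.w


def test_nondimensionalize_example():
    p = nondimensionalize(ShapeParams(b=0.01, c=4e-6), length_scale=100.0)
    assert p.b == pytest.approx(1.0)
    assert p.c == pytest.approx(0.04)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    b=st.floats(0.01, 100.0),
    c=st.floats(0.0, 100.0),
    scale=st.floats(1e-3, 1e4),
)
def test_nondimensionalize_round_trip(b, c, scale):
    p = ShapeParams(b, c)
    q = redimensionalize(nondimensionalize(p, scale), scale)
    assert q.b == pytest.approx(p.b, rel=1e-12)
    assert q.c == pytest.approx(p.c, rel=1e-12)


def test_scale_invariance_of_dimensionless_map():
    """Observables of scaled parameters equal R-scaled observables."""
    R = 250.0
    tilde = ShapeParams(1.3, 0.7)
    phys = redimensionalize(tilde, R)
    obs_t = shape_observables(tilde)
    obs_p = shape_observables(phys)
    assert obs_p.h == pytest.approx(obs_t.h * R, rel=1e-7)
    assert obs_p.w == pytest.approx(obs_t.w * R, rel=1e-7)
    assert obs_p.V == pytest.approx(obs_t.V * R**3, rel=1e-7)


def test_equivalent_radius():
    assert equivalent_radius(4 * np.pi / 3) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        equivalent_radius(-1.0)


def test_profile_csv_round_trip(tmp_path):
    import pandas as pd

    from tissuetension.laplace_shape import profile_to_csv

    prof = integrate_profile(ShapeParams(1.0, 0.5))
    path = tmp_path / "profile.csv"
    profile_to_csv(prof, path, unit="um")
    df = pd.read_csv(path, comment="#")
    assert list(df.columns) == ["s", "x", "z", "phi"]
    np.testing.assert_allclose(df["z"].to_numpy(), prof.z, rtol=1e-12)
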