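import math

import numpy as np
import pytest

from rhizograd import (
    StabilityError,
    advective_step,
    build_grid,
    depth_properties,
    effective_diffusion,
    get_fixture,
    retardation_factor,
)
from rhizograd.transport import diffusion_step


@pytest.fixture
def grid():
    return build_grid(r0=0.0642, n=50, dr=0.02)


def test_grid_quadrature(grid):
    """Shell volumes and interfaces tile the annular domain exactly."""
    total = math.pi * (grid.outer_radius**2 - grid.r0**2)
    assert np.sum(grid.V) == pytest.approx(total, rel=1e-12)
    assert grid.r_inner[0] == grid.r0
    assert grid.r_outer[-1] == pytest.approx(grid.outer_radius)
    assert np.all(grid.r_center == 0.5 * (grid.r_inner + grid.r_outer))
    assert np.allclose(grid.A_int, 2 * np.pi * grid.r_outer)


def test_build_grid_validation():
    with pytest.raises(ValueError):
        build_grid(r0=-1.0)
    with pytest.raises(ValueError):
        build_grid(r0=0.1, n=1)


def test_retardation_bounds_and_limits():
    s = get_fixture("glucose")
    dp = depth_properties(10.0)
    C = np.array([0.0, 0.01, 0.1, 1.0, 100.0])
    for kind in ("slope", "secant"):
        R = retardation_factor(s, dp, C, kind)
        assert np.all(R >= 1.0)
        assert np.all(np.diff(R) < 0)  # hindrance saturates away with C
    # both variants agree in the trace-concentration limit
    r0s = retardation_factor(s, dp, 0.0, "slope")
    r0c = retardation_factor(s, dp, 0.0, "secant")
    assert r0s == pytest.approx(r0c)
    assert r0s == pytest.approx(1.0 + (dp.rho / dp.eps) * s.Smax * s.Ks)
    with pytest.raises(ValueError):
        retardation_factor(s, dp, -0.1)
    with pytest.raises(ValueError):
        retardation_factor(s, dp, 1.0, "chord")


def test_effective_diffusion_never_exceeds_aqueous():
    s = get_fixture("glucose")
    for d in (1.0, 10.0, 80.0):
        dp = depth_properties(d)
        De = effective_diffusion(s, dp, 0.5)
        assert 0 < De < s.D_inf


def test_diffusion_conserves_mass_and_smooths(grid):
    rng = np.random.default_rng(0)
    C = rng.uniform(0.0, 2.0, grid.n)
    De = np.full(grid.n - 1, 5e-6)
    C1, J = diffusion_step(C, grid, De, dt=1.0)
    assert np.sum(C1 * grid.V) == pytest.approx(np.sum(C * grid.V), rel=1e-13)
    assert J.shape == (grid.n - 1,)
    # variance cannot grow under pure diffusion with closed boundaries
    assert np.var(C1) <= np.var(C)


def test_diffusion_uniform_profile_is_stationary(grid):
    C = np.full(grid.n, 0.7)
    C1, J = diffusion_step(C, grid, np.full(grid.n - 1, 5e-6), dt=1.0)
    assert np.allclose(C1, C)
    assert np.allclose(J, 0.0)


def test_diffusion_two_box_analytic():
    """One step on two annuli matches the hand-written flux update."""
    g = build_grid(r0=0.1, n=2, dr=0.05)
    C = np.array([2.0, 1.0])
    De, dt = 4e-6, 10.0
    J_expected = De * (C[0] - C[1]) / g.dr * g.A_int[0] * dt
    C1, J = diffusion_step(C, g, np.array([De]), dt)
    assert J[0] == pytest.approx(J_expected)
    assert C1[0] == pytest.approx(C[0] - J_expected / g.V[0])
    assert C1[1] == pytest.approx(C[1] + J_expected / g.V[1])


def test_stability_guard(grid):
    C = np.ones(grid.n)
    with pytest.raises(StabilityError, match="reduce dt"):
        diffusion_step(C, grid, np.full(grid.n - 1, 5e-6), dt=1e5)


def test_advective_step_conservation(grid):
    rng = np.random.default_rng(1)
    C = rng.uniform(0.0, 1.0, grid.n)
    v0, dt = 1e-6, 10.0
    C1, into_root = advective_step(C, grid, v0, dt)
    assert into_root == pytest.approx(v0 * C[0] * dt)
    assert np.sum(C1 * grid.V) + into_root == pytest.approx(
        np.sum(C * grid.V), rel=1e-13
    )
    # v0 = 0 is the identity
    C2, m = advective_step(C, grid, 0.0, dt)
    assert m == 0.0 and np.all(C2 == C)
    with pytest.raises(ValueError):
        advective_step(C, grid, -1e-6, dt)
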