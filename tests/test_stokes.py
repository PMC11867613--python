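import numpy as np
import pytest

from polypflow.geometry import DomainGrid, SolidMask, rasterize_solid
from polypflow.kinematics import MotionSpec, displaced_surface
from polypflow.stokes import (
    FluidProps,
    SolverConfig,
    analytic_expanding_sphere,
    aperture_flux,
    solve_quasi_steady,
)


def _sphere_mask(grid, a=0.5, adot=0.01, z0=5.0):
    rc, zc = grid.r_centers[:, None], grid.z_centers[None, :]
    dist = np.hypot(rc, zc - z0)
    chi = (dist <= a).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ur = np.where(dist > 0, adot * rc / dist, 0.0) * chi
        uz = np.where(dist > 0, adot * (zc - z0) / dist, 0.0) * chi
    return SolidMask(grid=grid, chi=chi, u_r=ur, u_z=uz)


@pytest.fixture(scope="module")
def sphere_solution(small_grid):
    mask = _sphere_mask(small_grid)
    cfg = SolverConfig(grid=small_grid)
    return mask, solve_quasi_steady(mask, FluidProps(), cfg), cfg


def test_hydrostatic_rest_is_quiescent(small_grid):
    mask = _sphere_mask(small_grid, adot=0.0)
    cfg = SolverConfig(grid=small_grid)
    flow = solve_quasi_steady(mask, FluidProps(), cfg)
    assert np.max(np.abs(flow.u_r)) <= cfg.tol
    assert np.max(np.abs(flow.u_z)) <= cfg.tol


def test_stokes_linearity_doubling(small_grid):
    cfg = SolverConfig(grid=small_grid)
    m1 = _sphere_mask(small_grid, adot=0.01)
    m2 = _sphere_mask(small_grid, adot=0.02)
    f1 = solve_quasi_steady(m1, FluidProps(), cfg)
    f2 = solve_quasi_steady(m2, FluidProps(), cfg)
    scale = np.max(np.abs(f2.u_z))
    assert np.max(np.abs(f2.u_r - 2 * f1.u_r)) <= 1e-10 * scale
    assert np.max(np.abs(f2.u_z - 2 * f1.u_z)) <= 1e-10 * scale


def test_kinematic_reversibility(small_grid):
    """Negating every boundary velocity negates the whole field: the
    defining time-reversibility of creeping flow."""
    cfg = SolverConfig(grid=small_grid)
    m1 = _sphere_mask(small_grid, adot=0.01)
    m2 = _sphere_mask(small_grid, adot=-0.01)
    f1 = solve_quasi_steady(m1, FluidProps(), cfg)
    f2 = solve_quasi_steady(m2, FluidProps(), cfg)
    scale = np.max(np.abs(f1.u_z))
    assert np.max(np.abs(f1.u_r + f2.u_r)) <= 1e-10 * scale
    assert np.max(np.abs(f1.u_z + f2.u_z)) <= 1e-10 * scale


def test_expanding_sphere_oracle(sphere_solution, small_grid):
    """Penalized solve against the analytic source solution u = adot (a/r)^2."""
    mask, flow, cfg = sphere_solution
    a, adot, z0 = 0.5, 0.01, 5.0
    from polypflow.pipeline import _bilinear

    g = small_grid
    for r, z in [(2 * a, z0), (0.0, z0 + 2 * a)]:
        ur = _bilinear(flow.u_r, g.r_faces, g.z_centers, r, z)
        uz = _bilinear(flow.u_z, g.r_centers, g.z_faces, r, z)
        d = np.hypot(r, z - z0)
        radial = (ur * r + uz * (z - z0)) / d
        expected = analytic_expanding_sphere(a, adot, [d])[0]
        assert radial == pytest.approx(expected, rel=0.10)


def test_divergence_free_in_fluid(sphere_solution):
    mask, flow, cfg = sphere_solution
    div = flow.divergence()
    fluid = mask.chi < 0.5
    u_scale = flow.diagnostics["boundary_speed"]
    assert np.max(np.abs(div[fluid])) <= cfg.tol * u_scale / min(
        flow.grid.dr, flow.grid.dz
    )


def test_penalization_error_below_threshold(sphere_solution):
    _, flow, cfg = sphere_solution
    assert flow.diagnostics["penalization_error"] <= cfg.penalization_threshold


def test_mass_conservation_control_box(sphere_solution, small_grid):
    """Net flux through a closed control surface enclosing only fluid
    vanishes to solver tolerance."""
    _, flow, _ = sphere_solution
    g = small_grid
    i0, i1, j0, j1 = 30, 50, 10, 40  # box away from the sphere
    rf, rc = g.r_faces, g.r_centers
    side_out = 2 * np.pi * rf[i1] * g.dz * np.sum(flow.u_r[i1, j0:j1])
    side_in = 2 * np.pi * rf[i0] * g.dz * np.sum(flow.u_r[i0, j0:j1])
    ring = 2 * np.pi * rc[i0:i1] * g.dr
    top = np.sum(flow.u_z[i0:i1, j1] * ring)
    bottom = np.sum(flow.u_z[i0:i1, j0] * ring)
    net = side_out - side_in + top - bottom
    scale = flow.diagnostics["boundary_speed"] * 2 * np.pi * rf[i1] * g.dz * (j1 - j0)
    assert abs(net) <= 1e-10 * scale


def test_quasi_steady_snapshot_reproducibility(small_grid):
    """Recomputing a snapshot in isolation reproduces it bit for bit."""
    cfg = SolverConfig(grid=small_grid)
    m = _sphere_mask(small_grid)
    f1 = solve_quasi_steady(m, FluidProps(), cfg)
    f2 = solve_quasi_steady(m, FluidProps(), cfg)
    assert np.array_equal(f1.u_r, f2.u_r)
    assert np.array_equal(f1.u_z, f2.u_z)
    assert np.array_equal(f1.p, f2.p)


class TestAnalyticExpandingSphere:
    def test_surface_and_2a_values(self):
        assert analytic_expanding_sphere(0.5, 0.01, [0.5])[0] == pytest.approx(0.01)
        assert analytic_expanding_sphere(0.5, 0.01, [1.0])[0] == pytest.approx(0.0025)

    def test_rejects_interior_radii(self):
        with pytest.raises(ValueError):
            analytic_expanding_sphere(0.5, 0.01, [0.4])

    def test_field_is_divergence_free(self):
        # spherical divergence (1/r^2) d(r^2 u)/dr of u = adot a^2 / r^2
        a, adot = 0.5, 0.01
        r = np.linspace(0.6, 3.0, 200)
        u = analytic_expanding_sphere(a, adot, r)
        div = np.gradient(r**2 * u, r) / r**2
        assert np.max(np.abs(div)) < 1e-12


class TestApertureFlux:
    def test_zero_field(self, geometry, small_grid):
        from polypflow.stokes import FlowField

        flow = FlowField(
            grid=small_grid,
            time=0.0,
            u_r=np.zeros((small_grid.nr + 1, small_grid.nz)),
            u_z=np.zeros((small_grid.nr, small_grid.nz + 1)),
            p=np.zeros((small_grid.nr, small_grid.nz)),
        )
        assert aperture_flux(flow, geometry) == 0.0

    def test_uniform_speed_closed_form(self, geometry, small_grid):
        from polypflow.stokes import FlowField

        g = small_grid
        w = 0.3
        r0 = 10 * g.dr  # disc edge aligned with a face -> exact quadrature
        u_z = np.zeros((g.nr, g.nz + 1))
        u_z[g.r_centers <= r0, :] = w
        flow = FlowField(
            grid=g,
            time=0.0,
            u_r=np.zeros((g.nr + 1, g.nz)),
            u_z=u_z,
            p=np.zeros((g.nr, g.nz)),
        )
        flux = aperture_flux(flow, geometry, disc_radius=r0, plane_z=5.0)
        assert flux == pytest.approx(w * np.pi * r0**2, rel=1e-9)

    def test_mid_expansion_flux_balances_cavity_rate(self, geometry, small_grid):
        """Volume-derivative oracle: aperture influx ~ -dV/dt at mid-stroke."""
        from polypflow.geometry import cavity_volume
        from polypflow.pipeline import _snapshot_field

        motion = MotionSpec.from_ratio("3:1", geometry)
        ramp = motion.temporal()
        A = motion.amplitude()
        t = 1.5
        state = displaced_surface(geometry, motion, t)
        flow = _snapshot_field(
            geometry, state, FluidProps(), SolverConfig(grid=small_grid)
        )
        flux = aperture_flux(flow, geometry)
        eps = 1e-5
        s = float(ramp.s(t))
        vol = lambda ss: cavity_volume(
            geometry, lambda z: motion.amplitude_scale * A(z) * ss
        )
        dVdt = (vol(s + eps) - vol(s - eps)) / (2 * eps) * float(ramp.rate(t))
        assert flux == pytest.approx(-dVdt, rel=0.05)
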