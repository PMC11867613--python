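from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polypflow.geometry import DomainGrid
from polypflow.postprocess import (
    EmptyDetectionError,
    VorticityField,
    grid_sensitivity,
    max_velocity_table,
    reynolds_number,
    track_vortices,
    vorticity,
)
from polypflow.stokes import FlowField


# --------------------------------------------------------------------------
# velocity maxima


def test_constant_trace_maximum(small_result):
    res = small_result
    fake = type(res)(
        label=res.label,
        config=res.config,
        geometry=res.geometry,
        motion=res.motion,
        times=res.times,
        z_points=res.z_points,
        speeds=np.full_like(res.speeds, 0.321),
        opening_diameter=res.opening_diameter,
        cavity_volume=res.cavity_volume,
        ramp_s=res.ramp_s,
        ramp_rate=res.ramp_rate,
    )
    table = max_velocity_table([fake], phase="expansion", refine=False)
    assert np.allclose(table.table.to_numpy(), 0.321)


def test_maxima_decay_with_height(small_result):
    """The intake current weakens with distance above the aperture."""
    table = max_velocity_table([small_result], phase="expansion", refine=False)
    col = table.table.iloc[:, 0].to_numpy()
    assert col[0] > col[-1]
    assert np.all(np.diff(col) <= 1e-15)


# --------------------------------------------------------------------------
# vorticity


def _field_from_components(grid, ur_c, uz_c):
    """Staggered field whose center averages equal the given components."""
    u_r = np.zeros((grid.nr + 1, grid.nz))
    u_r[1:-1, :] = 0.5 * (ur_c[:-1, :] + ur_c[1:, :])
    u_r[0, :] = 0.0
    u_z = np.zeros((grid.nr, grid.nz + 1))
    u_z[:, 1:-1] = 0.5 * (uz_c[:, :-1] + uz_c[:, 1:])
    return FlowField(
        grid=grid, time=0.0, u_r=u_r, u_z=u_z, p=np.zeros((grid.nr, grid.nz))
    )


def test_vorticity_of_uniform_field_is_zero(small_grid):
    g = small_grid
    flow = FlowField(
        grid=g,
        time=0.0,
        u_r=np.full((g.nr + 1, g.nz), 0.7),
        u_z=np.full((g.nr, g.nz + 1), -0.3),
        p=np.zeros((g.nr, g.nz)),
    )
    assert np.max(np.abs(vorticity(flow).omega)) < 1e-12


def test_vorticity_of_linear_shear(small_grid):
    # u_r = c z, u_z = 0  =>  omega = c everywhere
    g = small_grid
    c = 2.5
    u_r = np.tile(c * g.z_centers, (g.nr + 1, 1))
    flow = FlowField(
        grid=g,
        time=0.0,
        u_r=u_r,
        u_z=np.zeros((g.nr, g.nz + 1)),
        p=np.zeros((g.nr, g.nz)),
    )
    np.testing.assert_allclose(vorticity(flow).omega, c, rtol=1e-9)


def test_vorticity_odd_under_field_negation(small_result):
    f = small_result.fields[3]
    neg = FlowField(grid=f.grid, time=f.time, u_r=-f.u_r, u_z=-f.u_z, p=-f.p)
    np.testing.assert_array_equal(vorticity(neg).omega, -vorticity(f).omega)


def test_nondimensionalization_scale(small_result):
    f = small_result.fields[3]
    v = vorticity(f, t_scale=2.0)
    np.testing.assert_allclose(v.omega_star, 2.0 * v.omega)


# --------------------------------------------------------------------------
# vortex tracking on a constructed fixture


def _blob_frames(grid, positions, value=1.0):
    """Synthetic vorticity frames: a 3x3 blob at the given (i, j) cells."""
    frames = []
    for t, (i, j) in enumerate(positions):
        om = np.zeros((grid.nr, grid.nz))
        om[i : i + 3, j : j + 3] = value
        frames.append(
            VorticityField(grid=grid, time=float(t), omega=om, t_scale=1.0)
        )
    return frames


def test_blob_separation_at_constructed_frame():
    g = DomainGrid(nr=41, nz=81)
    wall = np.column_stack([np.zeros(50), np.linspace(0, 10, 50)])  # axis wall
    # blob starts against the wall, then jumps far beyond delta at frame 3
    frames = _blob_frames(g, [(0, 20), (0, 20), (1, 20), (20, 20), (20, 20)])
    track = track_vortices(
        frames, threshold=0.5, surface_points=wall, phase_times=None
    )
    (s,) = [st for st in track.structures if "separation" in st.events]
    assert s.events["separation"] == pytest.approx(3.0)
    assert s.events["formation"] == pytest.approx(0.0)


def test_fading_attached_blob_separates_when_it_vanishes():
    g = DomainGrid(nr=41, nz=81)
    wall = np.column_stack([np.zeros(50), np.linspace(0, 10, 50)])
    frames = _blob_frames(g, [(0, 20), (0, 20), (0, 20), (0, 20), (0, 20)])
    for f in frames[3:]:
        f.omega[:] = 0.0  # the structure fades while frames continue
    track = track_vortices(frames, threshold=0.5, surface_points=wall)
    (s,) = track.structures
    assert s.events["separation"] == pytest.approx(3.0)


def test_empty_detection_signalled(small_grid):
    g = small_grid
    frames = [
        VorticityField(grid=g, time=float(t), omega=np.zeros((g.nr, g.nz)), t_scale=1.0)
        for t in range(3)
    ]
    with pytest.raises(EmptyDetectionError):
        track_vortices(frames, threshold=1.0)


def test_opposite_signed_structures_tracked_independently():
    g = DomainGrid(nr=41, nz=81)
    frames = []
    for t in range(3):
        om = np.zeros((g.nr, g.nz))
        om[5:8, 20:23] = 1.0
        om[20:23, 20:23] = -1.0
        frames.append(VorticityField(grid=g, time=float(t), omega=om, t_scale=1.0))
    track = track_vortices(frames, threshold=0.5, phase_times=[0.0, 3.0])
    signs = sorted(s.sign for s in track.structures)
    assert signs == [-1, 1]
    roles = {s.role for s in track.structures}
    assert "main" in roles and "secondary" in roles


# --------------------------------------------------------------------------
# Reynolds number


def test_reynolds_number_formula():
    assert reynolds_number(1000.0, 0.01, 1e-4, 0.001) == pytest.approx(1.0)
    assert reynolds_number(1000.0, 0.0, 1e-4, 0.001) == 0.0


def test_reynolds_rejects_zero_viscosity():
    with pytest.raises(ValueError):
        reynolds_number(1000.0, 0.01, 1e-4, 0.0)


@given(
    rho=st.floats(1.0, 2000.0),
    U=st.floats(0.0, 1.0),
    L=st.floats(1e-6, 1e-2),
    mu=st.floats(1e-5, 1.0),
    k=st.floats(0.5, 4.0),
)
def test_reynolds_linearity(rho, U, L, mu, k):
    base = reynolds_number(rho, U, L, mu)
    assert reynolds_number(k * rho, U, L, mu) == pytest.approx(k * base)
    assert reynolds_number(rho, k * U, L, mu) == pytest.approx(k * base)
    assert reynolds_number(rho, U, k * L, mu) == pytest.approx(k * base)
    assert reynolds_number(rho, U, L, k * mu) == pytest.approx(base / k)


# --------------------------------------------------------------------------
# grid sensitivity


def test_identical_resolutions_have_zero_difference(small_config):
    cfg = replace(small_config, snapshot_interval=0.5)
    report = grid_sensitivity(cfg, levels=2, factor=1.0)
    assert report.pair_differences_pct[0] == pytest.approx(0.0, abs=1e-12)
    assert report.chosen_index == 0


def test_sensitivity_requires_two_levels(small_config):
    with pytest.raises(ValueError):
        grid_sensitivity(small_config, levels=1)
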