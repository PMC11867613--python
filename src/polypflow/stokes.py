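"""Quasi-steady axisymmetric Stokes solver with Brinkman volume penalization.

At the scale of the polyp the Reynolds number is well below one, so inertia
is dropped entirely and each instant is an independent stationary Stokes
problem: the flow field is fully determined by the instantaneous geometry and
boundary velocity.  The solid (periderm + polyp body with its moving
subumbrella surface) enters through a volume-penalization term
``(mu/eta) * chi * (u - U)`` that drags the velocity in masked cells toward
the prescribed solid velocity ``U``.

Discretization: uniform staggered (MAC) grid in (r, z) with the full
axisymmetric Stokes operator including the 1/r metric terms, assembled as a
single sparse saddle-point system and solved directly (SuperLU).  Boundary
conditions: symmetry on the axis, no-slip floor, zero-normal-traction open
top and lateral boundaries with pressure gauge 0.  Inside solid cells the
continuity row is replaced by ``p = 0``; the fluid region satisfies the
discrete divergence-free constraint to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DomainGrid, PolypGeometry, SolidMask

__all__ = [
    "SolverError",
    "FluidProps",
    "SolverConfig",
    "FlowField",
    "solve_quasi_steady",
    "aperture_flux",
    "analytic_expanding_sphere",
]


class SolverError(RuntimeError):
    """Linear-solve failure or penalization error above threshold."""


@dataclass(frozen=True)
class FluidProps:
    """Sea-water properties: density (kg/m^3) and dynamic viscosity (Pa s).

    For a pure Stokes problem with prescribed boundary velocities the
    velocity field is independent of both (viscosity only sets the pressure
    scale); they are kept for Reynolds-number reporting and pressure output.
    """

    density: float = 1000.0
    viscosity: float = 1e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class SolverConfig:
    grid: DomainGrid = field(default_factory=DomainGrid)
    #: penalization strength (s): solid cells relax to the prescribed
    #: velocity on this time scale; smaller = stiffer
    eta: float = 1e-8
    #: tolerance for the discrete divergence / rest-state checks, relative
    #: to the peak boundary speed
    tol: float = 1e-8
    #: maximum tolerated penalization error as a fraction of the peak
    #: boundary speed
    penalization_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.tol <= 0:
            raise ValueError("eta and tol must be positive")


@dataclass
class FlowField:
    """Staggered velocity (mm/s) and cell-centered pressure at one instant."""

    grid: DomainGrid
    time: float
    u_r: np.ndarray  # (nr+1, nz) radial velocity on r-faces
    u_z: np.ndarray  # (nr, nz+1) axial velocity on z-faces
    p: np.ndarray  # (nr, nz) pressure at cell centers
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def divergence(self) -> np.ndarray:
        """Discrete divergence (1/s) in every cell."""
        g = self.grid
        rf = g.r_faces
        rc = g.r_centers
        radial = (
            rf[1:, None] * self.u_r[1:, :] - rf[:-1, None] * self.u_r[:-1, :]
        ) / (rc[:, None] * g.dr)
        axial = (self.u_z[:, 1:] - self.u_z[:, :-1]) / g.dz
        return radial + axial

    def center_velocity(self):
        """Velocity components averaged to cell centers, shape (nr, nz)."""
        ur = 0.5 * (self.u_r[:-1, :] + self.u_r[1:, :])
        uz = 0.5 * (self.u_z[:, :-1] + self.u_z[:, 1:])
        return ur, uz

    def scaled(self, factor: float, time: Optional[float] = None) -> "FlowField":
        """Field multiplied by a scalar (exact for Stokes linearity)."""
        return FlowField(
            grid=self.grid,
            time=self.time if time is None else time,
            u_r=self.u_r * factor,
            u_z=self.u_z * factor,
            p=self.p * factor,
            diagnostics=dict(self.diagnostics),
        )


def _face_penalization(mask: SolidMask):
    """chi and prescribed velocity on r- and z-faces from cell data.

    A face is penalized when either adjacent cell is solid; the prescribed
    face velocity averages the prescribed values of the solid neighbors.
    """
    chi = mask.chi
    nr, nz = chi.shape

    g = mask.grid
    chi_r = np.zeros((nr + 1, nz))
    chi_r[1:-1, :] = np.maximum(chi[:-1, :], chi[1:, :])
    w = chi[:-1, :] + chi[1:, :]
    ur_face = np.zeros((nr + 1, nz))
    # interpolate the axisymmetric flux density r*u rather than u itself so
    # the volume swept by the rasterized surface matches the kinematic one
    rc = g.r_centers
    rf = g.r_faces
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = (
            mask.u_r[:-1, :] * rc[:-1, None] * chi[:-1, :]
            + mask.u_r[1:, :] * rc[1:, None] * chi[1:, :]
        ) / (w * rf[1:-1, None])
    ur_face[1:-1, :] = np.where(w > 0, avg, 0.0)

    chi_z = np.zeros((nr, nz + 1))
    chi_z[:, 1:-1] = np.maximum(chi[:, :-1], chi[:, 1:])
    wz = chi[:, :-1] + chi[:, 1:]
    uz_face = np.zeros((nr, nz + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        avgz = (mask.u_z[:, :-1] * chi[:, :-1] + mask.u_z[:, 1:] * chi[:, 1:]) / wz
    uz_face[:, 1:-1] = np.where(wz > 0, avgz, 0.0)

    return chi_r, ur_face, chi_z, uz_face


def solve_quasi_steady(
    mask: SolidMask, props: FluidProps, cfg: SolverConfig, time: float = 0.0
) -> FlowField:
    """Solve the stationary penalized Stokes system for one snapshot.

    Returns the :class:`FlowField`; raises :class:`SolverError` on linear
    solver failure or when the penalization error exceeds the configured
    fraction of the peak boundary speed.
    """
    g = cfg.grid
    if mask.grid.nr != g.nr or mask.grid.nz != g.nz:
        raise SolverError("mask and solver grids are inconsistent")
    nr, nz = g.nr, g.nz
    dr, dz = g.dr, g.dz
    mu = props.viscosity
    K = mu / cfg.eta  # penalization coefficient

    chi_r, Ur, chi_z, Uz = _face_penalization(mask)

    n_ur = (nr + 1) * nz
    n_uz = nr * (nz + 1)
    n_p = nr * nz
    off_uz = n_ur
    off_p = n_ur + n_uz

    def iur(i, j):
        return i * nz + j

    def iuz(i, j):
        return off_uz + i * (nz + 1) + j

    def ip(i, j):
        return off_p + i * nz + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_ur + n_uz + n_p)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    rf = g.r_faces
    rc = g.r_centers

    # ---- radial momentum on r-faces -------------------------------------
    for i in range(nr + 1):
        for j in range(nz):
            row = iur(i, j)
            if i == 0:
                add(row, row, 1.0)  # axis: u_r = 0
                continue
            if i == nr:
                # open side: sigma_rr = -p + 2 mu du_r/dr = 0
                add(row, row, 2.0 * mu / dr)
                add(row, iur(nr - 1, j), -2.0 * mu / dr)
                add(row, ip(nr - 1, j), -1.0)
                continue
            r_i = rf[i]
            c_out = mu * rc[i] / (r_i * dr * dr)
            c_in = mu * rc[i - 1] / (r_i * dr * dr)
            add(row, iur(i + 1, j), c_out)
            add(row, iur(i - 1, j), c_in)
            cz = mu / (dz * dz)
            if j == 0:
                # no-slip floor: ghost = -u => (u_{j+1} - 3 u_j) / dz^2
                add(row, iur(i, j + 1), cz)
                z_diag = -3.0 * cz
            elif j == nz - 1:
                # open top, zero tangential stress: ghost = u
                add(row, iur(i, j - 1), cz)
                z_diag = -1.0 * cz
            else:
                add(row, iur(i, j + 1), cz)
                add(row, iur(i, j - 1), cz)
                z_diag = -2.0 * cz
            diag = -(c_out + c_in) - mu / (r_i * r_i) + z_diag
            # pressure gradient
            add(row, ip(i, j), -1.0 / dr)
            add(row, ip(i - 1, j), 1.0 / dr)
            # penalization
            if chi_r[i, j] > 0:
                add(row, row, diag - K * chi_r[i, j])
                rhs[row] = -K * chi_r[i, j] * Ur[i, j]
            else:
                add(row, row, diag)

    # ---- axial momentum on z-faces --------------------------------------
    for i in range(nr):
        for j in range(nz + 1):
            row = iuz(i, j)
            if j == 0:
                add(row, row, 1.0)  # floor: u_z = 0
                continue
            if j == nz:
                # open top: sigma_zz = -p + 2 mu du_z/dz = 0
                add(row, row, 2.0 * mu / dz)
                add(row, iuz(i, nz - 1), -2.0 * mu / dz)
                add(row, ip(i, nz - 1), -1.0)
                continue
            r_c = rc[i]
            c_out = mu * rf[i + 1] / (r_c * dr * dr) if i < nr - 1 else 0.0
            c_in = mu * rf[i] / (r_c * dr * dr) if i > 0 else 0.0
            cz = mu / (dz * dz)
            diag = -(c_out + c_in) - 2.0 * cz
            if i < nr - 1:
                add(row, iuz(i + 1, j), c_out)
            if i > 0:
                add(row, iuz(i - 1, j), c_in)
            add(row, iuz(i, j + 1), cz)
            add(row, iuz(i, j - 1), cz)
            add(row, ip(i, j), -1.0 / dz)
            add(row, ip(i, j - 1), 1.0 / dz)
            if chi_z[i, j] > 0:
                add(row, row, diag - K * chi_z[i, j])
                rhs[row] = -K * chi_z[i, j] * Uz[i, j]
            else:
                add(row, row, diag)

    # ---- continuity / pressure rows -------------------------------------
    solid = mask.chi > 0.5
    for i in range(nr):
        for j in range(nz):
            row = ip(i, j)
            if solid[i, j]:
                add(row, row, 1.0)  # pressure gauge inside solid
                continue
            r_c = rc[i]
            add(row, iur(i + 1, j), rf[i + 1] / (r_c * dr))
            add(row, iur(i, j), -rf[i] / (r_c * dr))
            add(row, iuz(i, j + 1), 1.0 / dz)
            add(row, iuz(i, j), -1.0 / dz)

    A = sp.csc_matrix(
        (vals, (rows, cols)), shape=(n_ur + n_uz + n_p, n_ur + n_uz + n_p)
    )
    try:
        lu = spla.splu(A)
        x = lu.solve(rhs)
    except RuntimeError as exc:
        raise SolverError(f"sparse LU factorization failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("linear solve produced non-finite values")

    u_r = x[:n_ur].reshape(nr + 1, nz)
    u_z = x[off_uz:off_p].reshape(nr, nz + 1)
    p = x[off_p:].reshape(nr, nz)

    field_out = FlowField(grid=g, time=time, u_r=u_r, u_z=u_z, p=p)

    u_scale = max(np.max(np.abs(Ur)), np.max(np.abs(Uz)))
    div = field_out.divergence()
    max_div_fluid = float(np.max(np.abs(div[~solid]))) if (~solid).any() else 0.0
    pen_err = 0.0
    if u_scale > 0:
        err_r = np.abs(u_r - Ur)[chi_r > 0]
        err_z = np.abs(u_z - Uz)[chi_z > 0]
        pen_err = float(
            max(
                err_r.max() if err_r.size else 0.0,
                err_z.max() if err_z.size else 0.0,
            )
            / u_scale
        )
        if pen_err > cfg.penalization_threshold:
            raise SolverError(
                f"penalization error {pen_err:.2e} exceeds threshold "
                f"{cfg.penalization_threshold:.2e}"
            )
        if max_div_fluid > cfg.tol * u_scale / min(dr, dz):
            raise SolverError(
                f"fluid divergence {max_div_fluid:.2e} above tolerance"
            )
    field_out.diagnostics.update(
        max_divergence=max_div_fluid,
        penalization_error=pen_err,
        boundary_speed=float(u_scale),
    )
    return field_out


def aperture_flux(
    flow: FlowField,
    geometry: PolypGeometry,
    disc_radius: Optional[float] = None,
    plane_z: Optional[float] = None,
) -> float:
    """Signed volumetric rate (mm^3/s) through the aperture-plane disc.

    Integrates the axial velocity over a horizontal disc in the mouth
    throat; positive values are outflow (upward).  By default the disc sits
    one cell below the aperture plane and spans the bowl opening there, so
    it captures exactly the cavity exchange (everything else at that height
    is solid): the value balances the cavity volume rate.  An explicit
    ``disc_radius``/``plane_z`` pair integrates over that disc instead.
    """
    g = flow.grid
    if plane_z is None:
        plane_z = geometry.exposed_height - 1.5 * g.dz
    j = int(np.clip(np.searchsorted(g.z_faces, plane_z + 1e-12) - 1, 0, g.nz))
    if disc_radius is None:
        disc_radius = float(geometry.subumbrella_profile(g.z_faces[j]))
    cols = g.r_centers <= disc_radius
    ring = 2.0 * np.pi * g.r_centers[cols] * g.dr
    return float(np.sum(flow.u_z[cols, j] * ring))


def analytic_expanding_sphere(a: float, adot: float, radii) -> np.ndarray:
    """Radial speeds of the potential source flow around an expanding sphere.

    A rigid sphere of radius ``a`` expanding at rate ``adot`` in unbounded
    creeping flow drives the purely radial field ``u(r) = adot (a/r)^2``,
    which is divergence-free for r > a.  Used as the independent oracle for
    the penalized solver.  Rejects radii inside the sphere.
    """
    r = np.asarray(radii, dtype=float)
    if a <= 0:
        raise ValueError("sphere radius must be positive")
    if np.any(r < a):
        raise ValueError("evaluation radii must satisfy r >= a")
    return adot * (a / r) ** 2
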