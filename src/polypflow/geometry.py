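"""Parametric axisymmetric geometry of a periderm-dwelling olivooid polyp.

The tetraradial pagoda-shaped periderm and the bowl-shaped subumbrella it
encloses are reduced to bodies of revolution in cylindrical coordinates
``(r, z)``, with ``z = 0`` at the sea floor and the peridermal aperture facing
up.  This module is the pipeline's synthetic-data generator: it builds the
rest profiles, evaluates cavity volumes of displaced states, and rasterizes
the solid onto the computational grid used by the flow solver.

Units: lengths in mm, times in s throughout the package (velocities mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "UnderResolvedError",
    "GeometryParams",
    "Profile",
    "PolypGeometry",
    "DomainGrid",
    "SolidMask",
    "canonical_params",
    "build_polyp_profile",
    "cavity_volume",
    "rasterize_solid",
]


class GeometryError(ValueError):
    """Raised for parameter sets or displaced states that are not realizable."""


class UnderResolvedError(GeometryError):
    """Raised when the grid cannot resolve the geometry it is asked to carry."""


# Fraction of the subumbrella height (above the apex) at which the bowl is
# widest.  Not quantified by the fossil material; fixed once.
_BOWL_BULGE_FRACTION = 0.5

# Minimum clearance (mm) kept between the displaced bowl and the inner
# periderm wall before a state is rejected as self-intersecting.
_CLEARANCE = 0.005


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the periderm and the enclosed subumbrella (mm).

    The defaults encode the published fossil dimensions: a 2.0 mm tall
    periderm, 0.6 mm across at the base (0.3 mm radius), inserted 0.18 mm
    into the sediment, enclosing a 0.7 mm tall bowl-shaped subumbrella.
    ``opening_radius`` (the bowl mouth) and ``subumbrella_max_radius`` are
    configurable because the source material quotes conflicting figures for
    the bowl's width; neither is treated as ground truth.
    """

    periderm_height: float = 2.0
    periderm_base_radius: float = 0.3
    aperture_radius: float = 0.1
    insertion_depth: float = 0.18
    subumbrella_height: float = 0.7
    subumbrella_max_radius: float = 0.12
    opening_radius: float = 0.05
    ridge_amplitude: float = 0.0
    ridge_count: int = 8
    #: exponent of the periderm taper r(h) = R_b - (R_b - R_a) (h/H)^p;
    #: p = 5 keeps the profile near the base radius over most of the height
    #: and concentrates the narrowing near the aperture (pagoda-like).
    taper_exponent: float = 5.0

    def __post_init__(self) -> None:
        lengths = {
            "periderm_height": self.periderm_height,
            "periderm_base_radius": self.periderm_base_radius,
            "aperture_radius": self.aperture_radius,
            "insertion_depth": self.insertion_depth,
            "subumbrella_height": self.subumbrella_height,
            "subumbrella_max_radius": self.subumbrella_max_radius,
            "opening_radius": self.opening_radius,
            "ridge_amplitude": self.ridge_amplitude,
        }
        for name, value in lengths.items():
            if value < 0:
                raise GeometryError(f"{name} must be >= 0, got {value}")
        if self.aperture_radius >= self.periderm_base_radius:
            raise GeometryError("aperture_radius must be < periderm_base_radius")
        if self.insertion_depth >= self.periderm_height:
            raise GeometryError("insertion_depth must be < periderm_height")
        if self.subumbrella_height >= self.periderm_height - self.insertion_depth:
            raise GeometryError("subumbrella must fit inside the exposed periderm")
        if self.ridge_count < 0:
            raise GeometryError("ridge_count must be >= 0")

    @property
    def exposed_height(self) -> float:
        return self.periderm_height - self.insertion_depth


def canonical_params() -> GeometryParams:
    """Default parameter set: every published dimension plus documented defaults."""
    return GeometryParams()


class Profile:
    """Single-valued radius-vs-height curve r(z), non-negative, on a z span.

    Thin wrapper over a monotone-in-z sample set with PCHIP interpolation;
    evaluation outside the span returns the endpoint values.
    """

    def __init__(self, z: np.ndarray, r: np.ndarray):
        z = np.asarray(z, dtype=float)
        r = np.asarray(r, dtype=float)
        if z.ndim != 1 or z.shape != r.shape:
            raise GeometryError("profile needs matching 1-d z and r arrays")
        if np.any(np.diff(z) <= 0):
            raise GeometryError("profile z samples must be strictly increasing")
        if np.any(r < -1e-12):
            raise GeometryError("profile radii must be non-negative")
        self.z = z
        self.r = np.clip(r, 0.0, None)
        self._interp = PchipInterpolator(self.z, self.r, extrapolate=False)

    @property
    def z_min(self) -> float:
        return float(self.z[0])

    @property
    def z_max(self) -> float:
        return float(self.z[-1])

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = self._interp(np.clip(z, self.z_min, self.z_max))
        return np.asarray(out, dtype=float)

    def surface_points(self, n: int = 400) -> np.ndarray:
        """(n, 2) array of (r, z) points along the curve."""
        zz = np.linspace(self.z_min, self.z_max, n)
        return np.column_stack([self(zz), zz])

    def to_csv(self, path, n: int = 400) -> None:
        import pandas as pd

        zz = np.linspace(self.z_min, self.z_max, n)
        pd.DataFrame({"z_mm": zz, "r_mm": self(zz)}).to_csv(path, index=False)


@dataclass(frozen=True)
class PolypGeometry:
    """Rest-state profiles of the exposed periderm and the subumbrella bowl."""

    params: GeometryParams
    periderm_profile: Profile
    subumbrella_profile: Profile
    exposed_height: float
    rest_cavity_volume: float
    #: periderm shell outer surface points used for wall-distance queries
    wall_thickness: float = 0.04

    @property
    def apex_z(self) -> float:
        return self.subumbrella_profile.z_min

    def periderm_inner(self, z) -> np.ndarray:
        """Inner wall radius of the periderm shell (outer profile minus shell)."""
        return np.clip(self.periderm_profile(z) - self.wall_thickness, 0.0, None)


def build_polyp_profile(params: GeometryParams) -> PolypGeometry:
    """Construct the rest geometry from parameters.

    The periderm tapers smoothly (power law, optionally perturbed by annular
    ridges) from the base radius at the floor to the aperture radius at the
    exposed tip; the bowl hangs from the aperture plane, anchored at its apex
    ``exposed_height - subumbrella_height`` above the floor.  Raises
    :class:`GeometryError` if the bowl would intersect the periderm wall.
    """
    h_exp = params.exposed_height
    zz = np.linspace(0.0, h_exp, 800)

    # intrinsic periderm height coordinate: the buried part is below z = 0
    h = (zz + params.insertion_depth) / params.periderm_height
    r_peri = params.periderm_base_radius - (
        params.periderm_base_radius - params.aperture_radius
    ) * h ** params.taper_exponent
    if params.ridge_amplitude > 0 and params.ridge_count > 0:
        # annular ridges fade toward the tip so the aperture radius is exact
        envelope = 1.0 - h**4
        r_peri = r_peri + params.ridge_amplitude * envelope * np.sin(
            2.0 * np.pi * params.ridge_count * h
        )
    periderm = Profile(zz, r_peri)

    z_apex = h_exp - params.subumbrella_height
    z_bulge = z_apex + _BOWL_BULGE_FRACTION * params.subumbrella_height
    bowl_z = np.array([z_apex, z_bulge, h_exp])
    bowl_r = np.array([0.0, params.subumbrella_max_radius, params.opening_radius])
    zz_b = np.linspace(z_apex, h_exp, 400)
    bowl = Profile(zz_b, PchipInterpolator(bowl_z, bowl_r)(zz_b))

    inner = np.clip(periderm(zz_b) - 0.04, 0.0, None)
    if np.any(bowl(zz_b) > inner - _CLEARANCE):
        raise GeometryError("subumbrella bowl intersects the periderm wall")

    geometry = PolypGeometry(
        params=params,
        periderm_profile=periderm,
        subumbrella_profile=bowl,
        exposed_height=h_exp,
        rest_cavity_volume=0.0,
    )
    volume = cavity_volume(geometry, lambda z: np.zeros_like(np.asarray(z, float)))
    return replace(geometry, rest_cavity_volume=volume)


def cavity_volume(geometry: PolypGeometry, displacement) -> float:
    """Volume (mm^3) of revolution of the displaced subumbrella cavity.

    ``displacement`` maps z (mm) to the radial offset (mm) of the bowl wall.
    The cavity is the solid of revolution bounded by the displaced bowl
    profile between the apex and the aperture plane.  Displacements that push
    the wall below the axis or through the periderm are rejected.
    """
    bowl = geometry.subumbrella_profile
    zz = np.linspace(bowl.z_min, bowl.z_max, 1000)
    r = bowl(zz) + np.asarray(displacement(zz), dtype=float)
    if np.any(r < -1e-12):
        raise GeometryError("displaced bowl profile crosses the axis")
    inner = geometry.periderm_inner(zz)
    if np.any(r > inner - _CLEARANCE + 1e-12):
        raise GeometryError("displaced bowl profile crosses the periderm wall")
    return float(np.pi * np.trapezoid(r**2, zz))


@dataclass(frozen=True)
class DomainGrid:
    """Uniform staggered (MAC) grid on the axisymmetric domain [0,R] x [0,H].

    The 20 x 10 x 10 mm cuboid of the source setup reduces to a cylinder of
    radius 5 mm and height 10 mm.  Radial velocities live on r-faces
    (``(nr+1, nz)``), axial velocities on z-faces (``(nr, nz+1)``), pressure
    at cell centers (``(nr, nz)``).
    """

    radius_extent: float = 5.0
    height_extent: float = 10.0
    nr: int = 121
    nz: int = 241
    staggering: str = "MAC"

    def __post_init__(self) -> None:
        if self.nr < 4 or self.nz < 4:
            raise GeometryError("grid must have at least 4 cells per direction")
        if self.radius_extent <= 0 or self.height_extent <= 0:
            raise GeometryError("domain extents must be positive")

    @property
    def dr(self) -> float:
        return self.radius_extent / self.nr

    @property
    def dz(self) -> float:
        return self.height_extent / self.nz

    @property
    def r_faces(self) -> np.ndarray:
        return np.linspace(0.0, self.radius_extent, self.nr + 1)

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def z_faces(self) -> np.ndarray:
        return np.linspace(0.0, self.height_extent, self.nz + 1)

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    def refined(self, factor: float) -> "DomainGrid":
        """Same domain at ``factor`` times the resolution (cells rounded)."""
        return replace(
            self, nr=int(round(self.nr * factor)), nz=int(round(self.nz * factor))
        )


@dataclass
class SolidMask:
    """Rasterized solid indicator with embedded boundary velocities.

    ``chi`` is 1 in solid cells and 0 in fluid; ``u_r``/``u_z`` hold the
    prescribed velocity (mm/s) of solid cells (zero on the rigid periderm and
    deep body, the nearest-surface-point velocity on the subumbrella wall).
    """

    grid: DomainGrid
    chi: np.ndarray
    u_r: np.ndarray
    u_z: np.ndarray
    #: cells within the moving-surface band (bool), for diagnostics
    moving: np.ndarray = field(default=None)

    def solid_volume(self) -> float:
        """Volume of revolution (mm^3) covered by solid cells."""
        g = self.grid
        ring = 2.0 * np.pi * g.r_centers[:, None] * g.dr * g.dz
        return float(np.sum(self.chi * ring))

    def fingerprint(self) -> bytes:
        """Stable content hash inputs for memoizing solves on identical masks."""
        return b"".join(
            [
                np.ascontiguousarray(self.chi).tobytes(),
                np.ascontiguousarray(self.u_r).tobytes(),
                np.ascontiguousarray(self.u_z).tobytes(),
            ]
        )


def rasterize_solid(geometry: PolypGeometry, boundary, grid: DomainGrid) -> SolidMask:
    """Rasterize periderm + polyp body with the displaced subumbrella surface.

    The solid is everything inside the periderm outer profile below the
    aperture plane except the (displaced) subumbrella cavity: the space
    between bowl and periderm is occupied by the polyp body, so the only
    water inside the periderm is the cavity, and it communicates with the
    exterior solely through the bowl mouth at the aperture.  Solid cells
    whose nearest surface feature is the subumbrella carry the radial surface
    velocity of the nearest surface point (flux-corrected by r_surface/r_cell
    so the discrete swept volume matches the kinematic one); periderm and
    deep-body cells are rigid.

    ``boundary`` is a :class:`polypflow.kinematics.BoundaryState` (anything
    with ``profile_z``, ``profile_r`` and ``u_r`` arrays).
    """
    g = grid
    rc = g.r_centers[:, None]
    zc = g.z_centers[None, :]
    h_exp = geometry.exposed_height

    below_tip = zc <= h_exp
    inside_periderm = (rc <= geometry.periderm_profile(zc[0])[None, :]) & below_tip

    # displaced cavity region: strictly inside the displaced bowl profile
    prof_z = np.asarray(boundary.profile_z, dtype=float)
    prof_r = np.asarray(boundary.profile_r, dtype=float)
    bowl_interp = PchipInterpolator(prof_z, prof_r, extrapolate=False)
    in_span = (zc >= prof_z[0]) & (zc <= prof_z[-1])
    bowl_r_at = np.where(in_span, np.nan_to_num(bowl_interp(zc), nan=0.0), 0.0)
    cavity = inside_periderm & in_span & (rc < bowl_r_at)

    chi = (inside_periderm & ~cavity).astype(float)

    # resolution checks: cavity and its mouth must be carried by the grid
    if chi.any():
        mouth_row = int(np.clip(np.searchsorted(g.z_centers, h_exp) - 1, 0, g.nz - 1))
        mouth_cells = int(np.sum(cavity[:, mouth_row]))
        if cavity.sum() < 4 or mouth_cells < 1:
            raise UnderResolvedError(
                "grid does not resolve the subumbrella cavity or its mouth; "
                f"cavity cells={int(cavity.sum())}, mouth cells={mouth_cells}"
            )

    u_r = np.zeros_like(chi)
    u_z = np.zeros_like(chi)
    moving = np.zeros(chi.shape, dtype=bool)

    vel = np.asarray(boundary.u_r, dtype=float)
    if chi.any() and np.any(vel != 0.0):
        # velocities are sampled against the reference (rest) surface
        # parametrization: the motion is radial-only, so the z-parametrization
        # of the surface is unchanged and the reference lookup is exact in z;
        # it also keeps the unit problem identical whenever the rasterized
        # geometry is, which the pipeline memoization relies on
        ref_r = geometry.subumbrella_profile(prof_z)
        surf = np.column_stack([ref_r, prof_z])
        sub_tree = cKDTree(surf)
        rigid = geometry.periderm_profile.surface_points(400)
        floor = np.column_stack(
            [np.linspace(0.0, g.radius_extent, 200), np.zeros(200)]
        )
        rigid_tree = cKDTree(np.vstack([rigid, floor]))

        band = 2.5 * max(g.dr, g.dz)
        idx = np.argwhere(chi > 0.5)
        pts = np.column_stack([g.r_centers[idx[:, 0]], g.z_centers[idx[:, 1]]])
        d_sub, j_sub = sub_tree.query(pts)
        d_rig, _ = rigid_tree.query(pts)
        take = (d_sub <= band) & (d_sub <= d_rig)
        for (i, j), jj in zip(idx[take], j_sub[take]):
            r_cell = max(g.r_centers[i], 0.5 * g.dr)
            u_r[i, j] = vel[jj] * ref_r[jj] / r_cell
            moving[i, j] = True

    return SolidMask(grid=g, chi=chi, u_r=u_r, u_z=u_z, moving=moving)
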