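"""Prescribed subumbrella kinematics: amplitude profile times temporal ramp.

The subumbrella wall moves radially only, as the product of a z-dependent
amplitude ``A(z)`` (cubic spline through control points, anchored to zero at
the bowl apex) and a smooth temporal ramp ``s(t)`` that rises 0 -> 1 over the
expansion phase and returns 1 -> 0 over the contraction phase.  The ramp rate
is a beta-shaped bump vanishing at the phase endpoints, with its maximum at a
configurable fraction of each phase (defaults anchored so the 3 s : 1 s
scenario peaks at 1.8 s during expansion and 3.5 s during contraction).

The four canonical scenarios share one ramp shape time-stretched over the
expansion phase (1, 2, 3 or 4 s) with the contraction fixed at 1 s, so peak
wall speeds — and, by Stokes linearity, peak flow speeds — scale as 1/T_exp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import betainc, betaln

from .geometry import PolypGeometry, _CLEARANCE

__all__ = [
    "KinematicsError",
    "MotionSpec",
    "BoundaryState",
    "TemporalProfile",
    "temporal_profile",
    "amplitude_profile",
    "displaced_surface",
    "opening_diameter",
    "default_control_points",
    "parse_ratio",
    "AMPLITUDE_SCALE",
]

#: Dimensionless scale applied to the amplitude control points.  Frozen once
#: during development against the canonical fast-cycle (1 s : 1 s) scenario so
#: that its expansion-phase peak speed at the z = 2.05 mm cut point lands on
#: 0.0155 (velocity units of the solver, see the methods note); the creeping-
#: flow response is proportional to this scale, which makes the calibration a
#: single linear rescaling.
AMPLITUDE_SCALE = 0.076488

# total beta-bump sharpness a+b of the ramp rate; 6 gives a quartic-like bump
# with C2 ramps and zero rate at the phase endpoints
_BUMP_ORDER = 6.0


class KinematicsError(ValueError):
    """Raised for motion states that violate geometric validity."""


def parse_ratio(label: str) -> Tuple[float, float]:
    """Map scenario shorthand like ``"3:1"`` to ``(T_exp, T_con)`` seconds."""
    try:
        a, b = label.split(":")
        t_exp, t_con = float(a), float(b)
    except Exception as exc:  # noqa: BLE001 - uniform error type
        raise KinematicsError(f"cannot parse ratio label {label!r}") from exc
    if t_exp <= 0 or t_con <= 0:
        raise KinematicsError("phase durations must be positive")
    return t_exp, t_con


def default_control_points(geometry: PolypGeometry) -> Tuple[Tuple[float, float], ...]:
    """Default amplitude control points (z mm, A mm) for a geometry.

    Outward at mid-bowl (+0.05 mm) and inward at the rim (-0.02 mm): the bowl
    inflates while its mouth narrows, which simultaneously draws water in
    through the aperture and shrinks the opening over the expansion phase.
    """
    z0 = geometry.apex_z
    z1 = geometry.exposed_height
    return ((z0, 0.0), (0.5 * (z0 + z1), 0.05), (z1, -0.02))


@dataclass(frozen=True)
class TemporalProfile:
    """One-cycle ramp ``s(t)`` and its rate, piecewise beta-bump integrals."""

    T_exp: float
    T_con: float
    peak_fraction_exp: float
    peak_fraction_con: float

    @property
    def cycle(self) -> float:
        return self.T_exp + self.T_con

    @property
    def t_peak_exp(self) -> float:
        return self.peak_fraction_exp * self.T_exp

    @property
    def t_peak_con(self) -> float:
        return self.T_exp + self.peak_fraction_con * self.T_con

    def _ab(self, fraction: float) -> Tuple[float, float]:
        # the ramp rate is a Beta(a, b) bump whose mode (a-1)/(a+b-2) sits at
        # the requested fraction of the phase
        a = 1.0 + (_BUMP_ORDER - 2.0) * fraction
        b = _BUMP_ORDER - a
        return a, b

    def s(self, t):
        t = np.asarray(t, dtype=float)
        tau_e = np.clip(t / self.T_exp, 0.0, 1.0)
        tau_c = np.clip((t - self.T_exp) / self.T_con, 0.0, 1.0)
        ae, be = self._ab(self.peak_fraction_exp)
        ac, bc = self._ab(self.peak_fraction_con)
        up = betainc(ae, be, tau_e)
        down = 1.0 - betainc(ac, bc, tau_c)
        return np.where(t <= self.T_exp, up, down)

    def rate(self, t):
        """ds/dt; positive on expansion, negative on contraction."""
        t = np.asarray(t, dtype=float)
        ae, be = self._ab(self.peak_fraction_exp)
        ac, bc = self._ab(self.peak_fraction_con)
        tau_e = np.clip(t / self.T_exp, 0.0, 1.0)
        tau_c = np.clip((t - self.T_exp) / self.T_con, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pdf_e = np.exp(
                (ae - 1.0) * np.log(np.where(tau_e > 0, tau_e, 1.0))
                + (be - 1.0) * np.log(np.where(tau_e < 1, 1.0 - tau_e, 1.0))
                - betaln(ae, be)
            )
            pdf_c = np.exp(
                (ac - 1.0) * np.log(np.where(tau_c > 0, tau_c, 1.0))
                + (bc - 1.0) * np.log(np.where(tau_c < 1, 1.0 - tau_c, 1.0))
                - betaln(ac, bc)
            )
        pdf_e = np.where((tau_e > 0) & (tau_e < 1), pdf_e, 0.0)
        pdf_c = np.where((tau_c > 0) & (tau_c < 1), pdf_c, 0.0)
        return np.where(t <= self.T_exp, pdf_e / self.T_exp, -pdf_c / self.T_con)


def temporal_profile(
    T_exp: float,
    T_con: float,
    peak_fraction_exp: float = 0.6,
    peak_fraction_con: float = 0.5,
) -> TemporalProfile:
    """Build the C1 cycle ramp; rejects non-positive durations."""
    if T_exp <= 0 or T_con <= 0:
        raise KinematicsError("phase durations must be positive")
    if not (0.0 < peak_fraction_exp < 1.0 and 0.0 < peak_fraction_con < 1.0):
        raise KinematicsError("peak fractions must lie strictly in (0, 1)")
    return TemporalProfile(T_exp, T_con, peak_fraction_exp, peak_fraction_con)


def amplitude_profile(
    control_points: Sequence[Tuple[float, float]],
) -> Callable[[np.ndarray], np.ndarray]:
    """Cubic spline A(z) through control points, clamped to 0 at the apex.

    The first control point is the apex anchor and must carry A = 0; the
    spline leaves it with zero slope.  Evaluation outside the control span
    returns 0.  Duplicate z values are rejected.
    """
    pts = sorted(control_points)
    z = np.array([p[0] for p in pts], dtype=float)
    a = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(z) <= 0):
        raise KinematicsError("duplicate z values in amplitude control points")
    if abs(a[0]) > 1e-12:
        raise KinematicsError("apex anchor control point must have A = 0")
    if len(z) == 1:
        return lambda zz: np.zeros_like(np.asarray(zz, dtype=float))
    spline = CubicSpline(z, a, bc_type=((1, 0.0), (2, 0.0)))
    z_lo, z_hi = z[0], z[-1]

    def A(zz):
        zz = np.asarray(zz, dtype=float)
        inside = (zz >= z_lo) & (zz <= z_hi)
        out = np.where(inside, spline(np.clip(zz, z_lo, z_hi)), 0.0)
        return np.asarray(out, dtype=float)

    return A


@dataclass(frozen=True)
class MotionSpec:
    """Full motion prescription for one expansion/contraction cycle."""

    T_exp: float
    T_con: float = 1.0
    amplitude_control_points: Tuple[Tuple[float, float], ...] = ()
    peak_fraction_exp: float = 0.6
    peak_fraction_con: float = 0.5
    amplitude_scale: float = AMPLITUDE_SCALE

    def __post_init__(self) -> None:
        if self.T_exp <= 0 or self.T_con <= 0:
            raise KinematicsError("phase durations must be positive")

    @classmethod
    def from_ratio(
        cls, label: str, geometry: PolypGeometry, **overrides
    ) -> "MotionSpec":
        t_exp, t_con = parse_ratio(label)
        pts = overrides.pop(
            "amplitude_control_points", default_control_points(geometry)
        )
        return cls(
            T_exp=t_exp, T_con=t_con, amplitude_control_points=tuple(pts), **overrides
        )

    @property
    def cycle(self) -> float:
        return self.T_exp + self.T_con

    def temporal(self) -> TemporalProfile:
        return temporal_profile(
            self.T_exp, self.T_con, self.peak_fraction_exp, self.peak_fraction_con
        )

    def amplitude(self) -> Callable[[np.ndarray], np.ndarray]:
        return amplitude_profile(self.amplitude_control_points)


@dataclass(frozen=True)
class BoundaryState:
    """Displaced subumbrella surface and its velocity at one instant.

    ``u_r = velocity_shape * rate``: the shape (mm) is the rate-independent
    part ``amplitude_scale * A(z)``, so quasi-steady solvers can normalize by
    the instantaneous ramp rate.  Axial and azimuthal surface velocities are
    identically zero (radial-only motion).
    """

    time: float
    profile_z: np.ndarray
    profile_r: np.ndarray
    velocity_shape: np.ndarray
    rate: float
    opening_diameter: float

    @property
    def u_r(self) -> np.ndarray:
        return self.velocity_shape * self.rate

    @property
    def u_z(self) -> np.ndarray:
        return np.zeros_like(self.profile_r)


def displaced_surface(
    geometry: PolypGeometry, motion: MotionSpec, t: float, n: int = 200
) -> BoundaryState:
    """Displaced bowl profile and surface velocity at time ``t`` of the cycle.

    Raises :class:`KinematicsError` outside the cycle or when the displaced
    wall crosses the axis or the periderm.
    """
    if t < -1e-12 or t > motion.cycle + 1e-12:
        raise KinematicsError(f"t={t} outside cycle [0, {motion.cycle}]")
    ramp = motion.temporal()
    A = motion.amplitude()
    bowl = geometry.subumbrella_profile
    zz = np.linspace(bowl.z_min, bowl.z_max, n)
    shape = motion.amplitude_scale * A(zz)
    s = float(ramp.s(t))
    rate = float(ramp.rate(t))
    r = bowl(zz) + shape * s
    if np.any(r < -1e-12):
        raise KinematicsError("displaced profile crosses the symmetry axis")
    if np.any(r > geometry.periderm_inner(zz) - _CLEARANCE + 1e-12):
        raise KinematicsError("displaced profile crosses the periderm wall")
    return BoundaryState(
        time=float(t),
        profile_z=zz,
        profile_r=r,
        velocity_shape=shape,
        rate=rate,
        opening_diameter=2.0 * float(r[-1]),
    )


def opening_diameter(state: BoundaryState) -> float:
    """Diameter (mm) of the bowl rim opening in the given state."""
    return state.opening_diameter
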