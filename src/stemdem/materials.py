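"""Physical property reductions for branch material and contact parameters.

Covers the elastic/shear modulus relations, the tilt-board friction
reductions and the inclined-plate drop test for the coefficient of
restitution.

Restitution reduction
---------------------
The drop rig releases a specimen from a height ``h1`` above a plate
inclined at ``alpha``; after the oblique bounce the specimen flies
ballistically, falls a further height ``h2`` and lands a horizontal
distance ``L_reb`` from the impact point.  With impact speed
``v0 = sqrt(2 g h1)`` vertically downward and a smooth (frictionless)
bounce that reverses the normal velocity component scaled by ``e``:

    v_x =  (1 + e) * v0 * sin(alpha) * cos(alpha)
    v_y =  v0 * ((1 + e) * cos(alpha)^2 - 1)        (upward positive)

and the landing condition  ``-h2 = v_y t - g t^2 / 2``, ``L_reb = v_x t``
defines ``e`` implicitly.  ``restitution_from_drop`` inverts this relation
numerically (it is strictly monotone in ``e``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "TensileMeasurement",
    "TiltMeasurement",
    "DropGeometry",
    "elastic_modulus",
    "shear_modulus",
    "elastic_from_shear",
    "static_friction",
    "rolling_friction",
    "rebound_distance",
    "restitution_from_drop",
]

G_ACCEL = 9.81  # m/s^2


@dataclass(frozen=True)
class TensileMeasurement:
    """Tensile test reading: force F (N), contact area A (mm^2),
    effective length L (mm) and elongation dL (mm)."""

    F: float
    A: float
    L: float
    dL: float

    def __post_init__(self):
        if min(self.F, self.A, self.L, self.dL) <= 0:
            raise ValueError("all tensile measurement fields must be positive")
        if self.dL >= self.L:
            raise ValueError("elongation must be smaller than the effective length")


@dataclass(frozen=True)
class TiltMeasurement:
    """Critical tilt-board angles (deg) for sliding and rolling onset."""

    theta_static: float
    theta_rolling: float

    def __post_init__(self):
        for th in (self.theta_static, self.theta_rolling):
            if not 0 < th < 90:
                raise ValueError("critical angles must lie in (0, 90) degrees")


@dataclass(frozen=True)
class DropGeometry:
    """Inclined-plate drop rig: drop height h1 (mm), fall height h2 (mm),
    plate angle alpha (deg), measured horizontal rebound distance (mm)."""

    h1: float = 30.0
    h2: float = 40.0
    ramp_angle: float = 45.0
    rebound_distance: float = 0.0

    def __post_init__(self):
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("drop heights must be positive")
        if not 0 < self.ramp_angle < 90:
            raise ValueError("ramp angle must lie in (0, 90) degrees")
        if self.rebound_distance < 0:
            raise ValueError("rebound distance cannot be negative")


def elastic_modulus(meas: TensileMeasurement) -> float:
    """Elastic modulus E = (F/A) / (dL/L), returned in Pa.

    F in N, A in mm^2, lengths in mm.
    """
    stress_pa = meas.F / (meas.A * 1e-6)
    strain = meas.dL / meas.L
    return stress_pa / strain


def shear_modulus(E: float, mu: float) -> float:
    """Isotropic shear modulus G = E / (2 (1 + mu)), Pa."""
    if mu <= -1:
        raise ValueError("Poisson ratio must exceed -1")
    return E / (2.0 * (1.0 + mu))


def elastic_from_shear(G: float, mu: float) -> float:
    """Inverse of :func:`shear_modulus`: E = 2 G (1 + mu)."""
    return 2.0 * G * (1.0 + mu)


def static_friction(theta_static_deg: float) -> float:
    """Static friction coefficient tan(theta_s) from the sliding-onset angle."""
    if not 0 <= theta_static_deg < 90:
        raise ValueError("static angle must lie in [0, 90) degrees")
    return math.tan(math.radians(theta_static_deg))


def rolling_friction(theta_rolling_deg: float) -> float:
    """Rolling friction coefficient e/r at rolling onset.

    The couple balance on the tilted plate gives
    e/r = tan(theta_r) * cos(theta_r) = sin(theta_r).
    """
    if not 0 <= theta_rolling_deg < 90:
        raise ValueError("rolling angle must lie in [0, 90) degrees")
    return math.sin(math.radians(theta_rolling_deg))


def rebound_distance(e: float, geom: DropGeometry) -> float:
    """Forward kinematics: horizontal landing distance (mm) for a given
    coefficient of restitution under the rig geometry."""
    if not 0 <= e <= 1:
        raise ValueError("restitution must lie in [0, 1]")
    v0 = math.sqrt(2.0 * G_ACCEL * geom.h1 * 1e-3)
    a = math.radians(geom.ramp_angle)
    vx = (1.0 + e) * v0 * math.sin(a) * math.cos(a)
    vy = v0 * ((1.0 + e) * math.cos(a) ** 2 - 1.0)  # upward positive
    h2 = geom.h2 * 1e-3
    # -h2 = vy t - g t^2/2  ->  t = (vy + sqrt(vy^2 + 2 g h2)) / g
    t = (vy + math.sqrt(vy * vy + 2.0 * G_ACCEL * h2)) / G_ACCEL
    return vx * t * 1e3


def restitution_from_drop(geom: DropGeometry) -> float:
    """Invert the rig kinematics: restitution coefficient from the measured
    rebound distance.  Raises if the distance implies e > 1."""
    L = geom.rebound_distance
    if L == 0:
        return 0.0
    L_max = rebound_distance(1.0, geom)
    if L > L_max:
        raise ValueError(
            f"rebound distance {L:.3g} mm exceeds the elastic limit "
            f"{L_max:.3g} mm of this geometry (implies e > 1)"
        )
    # even a fully inelastic smooth bounce carries the tangential momentum
    # forward, so the geometry has a finite minimum landing distance
    L_min = rebound_distance(0.0, geom)
    if L < L_min:
        raise ValueError(
            f"rebound distance {L:.3g} mm is below the inelastic floor "
            f"{L_min:.3g} mm of this geometry (implies e < 0)"
        )
    return brentq(lambda e: rebound_distance(e, geom) - L, 0.0, 1.0, xtol=1e-12)
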