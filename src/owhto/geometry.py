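"""Exact 3-D geometry of the square-column osteotomy model.

The tibia surrogate is a square column whose top surface is inclined
posteriorly by the initial posterior slope ``alpha0``.  A medial
open-wedge osteotomy is modelled as a planar cut hinging on the lateral
edge ("true lateral hinge": the hinge line is parallel to the osteotomy
line in the axial view), and the correction is a rigid rotation of the
proximal fragment about that hinge line.

Fixed right-handed frame used throughout the package::

    x = medial (+), y = anterior (+), z = superior (+)

Angle sign convention: a positive slope / osteotomy inclination descends
posteriorly (equivalently, rises anteriorly), so the sagittal plane
osteotomy inclination (SPOI) carries the same sign as the posterior
slope.  All public angles are in degrees; lengths are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColumnModel",
    "OsteotomyPlan",
    "SlopeLine",
    "InvalidPlanError",
    "DegenerateDirectionError",
    "hinge_axis",
    "rotate_about_axis",
    "opened_slope_direction",
    "sagittal_slope_angle",
    "closed_form_pts",
    "transform_point",
]

_UNIT_TOL = 1e-12


class InvalidPlanError(ValueError):
    """Raised when an osteotomy plan violates its geometric domain."""


class DegenerateDirectionError(ValueError):
    """Raised when a direction has no anteroposterior component to project."""


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ColumnModel:
    """Square-column tibia surrogate.

    The column occupies ``x in [0, width_ml]`` (lateral face at x=0,
    medial at x=width_ml), ``y in [0, depth_ap]`` (posterior face at
    y=0, anterior at y=depth_ap) and rises from z=0 to a sloped top
    surface.  The top plane reaches ``height`` at the anterior edge and
    drops posteriorly at ``alpha0``::

        z_top(y) = height - (depth_ap - y) * tan(alpha0)

    The measured slope is provably independent of all three dimensions;
    the defaults are a convenient desk-scale block.
    """

    width_ml: float = 50.0
    depth_ap: float = 50.0
    height: float = 100.0
    alpha0: float = 10.0

    def __post_init__(self) -> None:
        if min(self.width_ml, self.depth_ap, self.height) <= 0:
            raise ValueError("column dimensions must be positive")
        if not -90.0 < self.alpha0 < 90.0:
            raise ValueError("alpha0 must lie in (-90, 90) degrees")

    def top_z(self, y: float) -> float:
        """Height of the top surface at anteroposterior position ``y``."""
        return self.height - (self.depth_ap - y) * np.tan(np.radians(self.alpha0))

    def slope_endpoints(self) -> "SlopeLine":
        """Anterior (A) and posterior (B) slope end-points on the top-surface midline."""
        x = self.width_ml / 2.0
        a = np.array([x, self.depth_ap, self.top_z(self.depth_ap)])
        b = np.array([x, 0.0, self.top_z(0.0)])
        return SlopeLine(point_a=a, point_b=b)

    def top_corners(self) -> np.ndarray:
        """The four top-surface corner vertices, shape (4, 3)."""
        w, d = self.width_ml, self.depth_ap
        return np.array(
            [[x, y, self.top_z(y)] for x in (0.0, w) for y in (0.0, d)]
        )


@dataclass(frozen=True)
class OsteotomyPlan:
    """One simulated medial open-wedge osteotomy.

    Parameters
    ----------
    spoi : float
        Sagittal plane osteotomy inclination φ in degrees; positive
        descends posteriorly (same convention as the posterior slope).
    correction : float
        Opening-wedge correction angle θ in degrees, >= 0.
    cut_height : float
        Height (z, mm) of the hinge line where it meets the
        posterolateral corner of the column.
    hinge_axis_override : optional unit 3-vector
        Replaces the true-lateral hinge direction derived from ``spoi``.
    """

    spoi: float
    correction: float
    cut_height: float = 50.0
    hinge_axis_override: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not -90.0 < self.spoi < 90.0:
            raise InvalidPlanError("spoi must lie in (-90, 90) degrees")
        if self.correction < 0:
            raise InvalidPlanError("correction angle must be >= 0")
        if self.hinge_axis_override is not None:
            v = _as_vec3(self.hinge_axis_override)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise InvalidPlanError("hinge_axis_override must be unit length")
            object.__setattr__(self, "hinge_axis_override", v)

    @property
    def hinge_direction(self) -> np.ndarray:
        if self.hinge_axis_override is not None:
            return self.hinge_axis_override
        return hinge_axis(self.spoi)

    def hinge_point(self) -> np.ndarray:
        """A point on the hinge line: the posterolateral cut corner."""
        return np.array([0.0, 0.0, self.cut_height])

    def plane_z(self, y: float) -> float:
        """Height of the osteotomy plane at ``y`` (independent of x)."""
        return self.cut_height + y * np.tan(np.radians(self.spoi))


@dataclass(frozen=True)
class SlopeLine:
    """The digitized slope line: anterior end-point A, posterior end-point B."""

    point_a: np.ndarray
    point_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_a", _as_vec3(self.point_a))
        object.__setattr__(self, "point_b", _as_vec3(self.point_b))
        if np.allclose(self.point_a, self.point_b):
            raise ValueError("slope end-points must be distinct")

    def direction(self) -> np.ndarray:
        """Posterior-to-anterior direction B -> A (not normalised)."""
        return self.point_a - self.point_b


def hinge_axis(spoi: float) -> np.ndarray:
    """Unit direction of the true lateral hinge for a given SPOI.

    The hinge lies in the osteotomy plane, has no medial-lateral
    component, and makes angle ``spoi`` with the axial plane, descending
    posteriorly for positive ``spoi``:  ``(0, cos φ, sin φ)``.
    """
    if not -90.0 < spoi < 90.0:
        raise InvalidPlanError("spoi must lie in (-90, 90) degrees")
    r = np.radians(spoi)
    return np.array([0.0, np.cos(r), np.sin(r)])


def rotate_about_axis(v, axis, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about a unit ``axis`` by ``angle`` degrees.

    v' = v cosθ + (axis × v) sinθ + axis (axis·v)(1 − cosθ)

    The rotation is right-handed about ``axis``; lengths are preserved
    to machine precision.
    """
    v = _as_vec3(v)
    axis = _as_vec3(axis)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be unit length")
    th = np.radians(angle)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


def opened_slope_direction(alpha0: float, plan: OsteotomyPlan) -> np.ndarray:
    """Top-surface slope-line direction after opening the wedge.

    Takes the pre-correction slope direction ``(0, cos α0, sin α0)`` and
    rotates it about the plan's hinge axis by the correction angle.  The
    sagittal slope measured from the result is invariant to the sign of
    the rotation (only the medial-lateral component flips).
    """
    r = np.radians(alpha0)
    s = np.array([0.0, np.cos(r), np.sin(r)])
    out = rotate_about_axis(s, plan.hinge_direction, plan.correction)
    return out / np.linalg.norm(out)


def sagittal_slope_angle(d) -> float:
    """Inclination, in degrees, of the sagittal (y–z) projection of ``d``.

    Positive when the line rises anteriorly, i.e. for a positive
    posterior slope.  Raises :class:`DegenerateDirectionError` when the
    direction has no anteroposterior component to project.
    """
    d = _as_vec3(d)
    if d[1] == 0.0:
        raise DegenerateDirectionError("direction has zero anteroposterior component")
    return float(np.degrees(np.arctan2(d[2], d[1]) if d[1] > 0 else np.arctan2(-d[2], -d[1])))


def closed_form_pts(alpha0: float, spoi: float, theta: float) -> float:
    """Posterior slope after correction, by the analytic closed form.

    Collapsing the Rodrigues rotation of the slope direction about the
    true-lateral hinge and the sagittal projection gives::

        α'(θ) = atan( [sin α0 cos θ + sin φ cos(α0 − φ)(1 − cos θ)] /
                      [cos α0 cos θ + cos φ cos(α0 − φ)(1 − cos θ)] )

    For φ = α0 the ratio reduces to tan α0 exactly, so a cut parallel to
    the plateau slope never changes the measured slope.
    """
    if not -90.0 < spoi < 90.0:
        raise InvalidPlanError("spoi must lie in (-90, 90) degrees")
    a0, phi, th = (np.radians(x) for x in (alpha0, spoi, theta))
    c = np.cos(a0 - phi) * (1.0 - np.cos(th))
    num = np.sin(a0) * np.cos(th) + np.sin(phi) * c
    den = np.cos(a0) * np.cos(th) + np.cos(phi) * c
    if den <= 0.0:
        raise ValueError("slope line left the anterior half-space; angles out of domain")
    return float(np.degrees(np.arctan2(num, den)))


def transform_point(p, plan: OsteotomyPlan, hinge_point=None) -> np.ndarray:
    """Rigid motion of a proximal-fragment point under the wedge opening.

    Rotates ``p`` about the hinge line (through ``hinge_point``, along
    the plan's hinge direction) by the correction angle, with the sign
    that elevates the medial side of the fragment (the gap opens
    medially).  Callers leave distal-fragment points untouched.
    """
    p = _as_vec3(p)
    h = plan.hinge_point() if hinge_point is None else _as_vec3(hinge_point)
    # negative right-handed angle about (0, cosφ, sinφ) raises +x points
    return h + rotate_about_axis(p - h, plan.hinge_direction, -plan.correction)
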