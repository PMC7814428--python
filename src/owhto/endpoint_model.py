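"""Trigonometric end-point model of the wedge opening.

An explicit 2-D construction per slope end-point: the anterior
end-point P1 swings about the anterior hinge end-point H1, and the
posterior end-point P2 about the posterior hinge end-point H2, each in
the plane perpendicular to the hinge axis through its own hinge point.
Within that plane, the end-point sits at radius ``r`` and signed angle
``theta_i`` above the osteotomy-plane (OP) trace, so its offset from
the OP line is::

    ϰ  = r · sin(θi)           before correction
    ϰ' = r · sin(θi + θ)       after opening the wedge by θ

When θ1 = θ2 both end-points gain identical offsets for every θ and the
posterior slope is preserved; this happens exactly when the osteotomy
plane is parallel to the plateau slope.  The module exists to verify
that planar argument against the full 3-D geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ColumnModel, OsteotomyPlan

__all__ = ["EndpointSpec", "endpoint_offset", "endpoints_from_column", "slope_preserved"]

#: angle-equality tolerance (degrees) for the slope-preservation criterion
ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class EndpointSpec:
    """Per-endpoint polar coordinates about the hinge end-points.

    r1, r2 : radii (mm) from H1 to P1 and H2 to P2, measured in the
        planes perpendicular to the hinge axis.
    theta1, theta2 : signed angles (degrees) of P1 and P2 above the
        osteotomy-plane line within those planes.
    """

    r1: float
    r2: float
    theta1: float
    theta2: float

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("endpoint radii must be positive")
        for t in (self.theta1, self.theta2):
            if not -90.0 < t < 90.0:
                raise ValueError("endpoint angles must lie in (-90, 90) degrees")


def endpoint_offset(r: float, theta_i: float, theta: float) -> float:
    """Offset ``r·sin(theta_i + theta)`` of an end-point from the OP line.

    With ``theta = 0`` this is the pre-correction offset ``r·sin(theta_i)``.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    return float(r * np.sin(np.radians(theta_i + theta)))


def _polar_about_hinge(p: np.ndarray, h: np.ndarray, axis: np.ndarray) -> tuple[float, float]:
    """(r, theta_deg) of point ``p`` about hinge point ``h`` in the plane ⟂ axis.

    The in-plane reference direction is the osteotomy-plane trace (the
    pure medial direction, which is perpendicular to every true-lateral
    hinge); positive theta means above the plane.
    """
    u = np.array([1.0, 0.0, 0.0])     # OP-line trace in the ⟂ plane
    w = np.cross(u, axis)             # in-plane normal, points above the OP
    v = p - h
    v_perp = v - np.dot(v, axis) * axis
    r = float(np.linalg.norm(v_perp))
    theta = float(np.degrees(np.arctan2(np.dot(v_perp, w), np.dot(v_perp, u))))
    return r, theta


def endpoints_from_column(column: ColumnModel, plan: OsteotomyPlan) -> EndpointSpec:
    """Derive (r1, θ1, r2, θ2) from the column's coordinates.

    P1/P2 are the anterior/posterior slope end-points on the top-surface
    midline; H1/H2 are the anterior/posterior end-points of the lateral
    hinge line, i.e. where the hinge crosses the column's anterior and
    posterior faces.
    """
    axis = plan.hinge_direction
    line = column.slope_endpoints()
    h1 = np.array([0.0, column.depth_ap, plan.plane_z(column.depth_ap)])
    h2 = np.array([0.0, 0.0, plan.plane_z(0.0)])
    r1, t1 = _polar_about_hinge(line.point_a, h1, axis)
    r2, t2 = _polar_about_hinge(line.point_b, h2, axis)
    return EndpointSpec(r1=r1, r2=r2, theta1=t1, theta2=t2)


def slope_preserved(spec: EndpointSpec, tol: float = ANGLE_TOL) -> bool:
    """True iff the wedge opening leaves the posterior slope unchanged.

    The criterion is θ1 = θ2 (within ``tol`` degrees): equal end-point
    angles gain equal offsets ``r·sin(θi+θ) − r·sin(θi)`` relative to
    their radii for every correction, so the slope line keeps its
    inclination.
    """
    return abs(spec.theta1 - spec.theta2) < tol
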