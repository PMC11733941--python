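"""Closed-form 3-D primitives for the DMDGP search tree.

Everything here works on plain float 3-tuples (``Point3``): these routines sit
in the innermost loop of the solver, where tuple arithmetic is markedly
faster than small numpy arrays.

The canonical frame fixes the first three vertices of an order: x1 at the
origin, x2 on the negative x-axis, x3 in the upper (y > 0) half of the
xy-plane.  Every later vertex lies in the intersection of three spheres
centred at its three immediate predecessors; the intersection holds at most
two points, mirror images through the predecessors' plane, and the choice
between them is one bit of the binary representation.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

Point3 = Tuple[float, float, float]
PlaneRef = Tuple[Point3, Point3, Point3]

#: default tolerance (signed-volume units) below which a point counts as
#: lying on its reference plane; loosen to ~1e-3 for experimental coordinates
ON_PLANE_TOL = 1e-7

#: default collinearity tolerance for reference triples (triangle area)
COLLINEAR_TOL = 1e-10


class InfeasibleGeometryError(ValueError):
    """Requested distances admit no embedding (e.g. triangle inequality)."""


class DegenerateReferenceError(ValueError):
    """Reference points are collinear/coincident and define no plane."""


def _sub(a: Point3, b: Point3) -> Point3:
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _add(a: Point3, b: Point3) -> Point3:
    return (a[0] + b[0], a[1] + b[1], a[2] + b[2])


def _scale(a: Point3, s: float) -> Point3:
    return (a[0] * s, a[1] * s, a[2] * s)


def _dot(a: Point3, b: Point3) -> float:
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a: Point3, b: Point3) -> Point3:
    return (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )


def _norm(a: Point3) -> float:
    return math.sqrt(_dot(a, a))


def _unit(a: Point3) -> Point3:
    n = _norm(a)
    if n == 0.0:
        raise DegenerateReferenceError("zero-length direction vector")
    return (a[0] / n, a[1] / n, a[2] / n)


def dist(a: Point3, b: Point3) -> float:
    """Euclidean distance between two points."""
    return _norm(_sub(a, b))


def signed_volume(ref: PlaneRef, p: Point3) -> float:
    """det[p2-p1, p3-p1, p-p1]: six times the signed tetrahedron volume."""
    p1, p2, p3 = ref
    return _dot(_cross(_sub(p2, p1), _sub(p3, p1)), _sub(p, p1))


def _check_ref(ref: PlaneRef, tol: float = COLLINEAR_TOL) -> None:
    p1, p2, p3 = ref
    area2 = _norm(_cross(_sub(p2, p1), _sub(p3, p1)))
    if area2 <= tol:
        raise DegenerateReferenceError(
            "reference points are collinear or coincident"
        )


def place_first_three(d12: float, d13: float, d23: float
                      ) -> Tuple[Point3, Point3, Point3]:
    """Canonical placement of the first three vertices of a DMDGP order.

    x1 is the origin, x2 sits on the negative x-axis at distance ``d12`` and
    x3 in the upper half (y > 0) of the xy-plane, with the angle at x1 given
    by the Law of Cosines.  Raises :class:`InfeasibleGeometryError` if the
    three distances violate the (strict) triangle inequality.
    """
    if min(d12, d13, d23) <= 0.0:
        raise InfeasibleGeometryError("distances must be positive")
    if (d12 + d13 <= d23) or (d12 + d23 <= d13) or (d13 + d23 <= d12):
        raise InfeasibleGeometryError(
            f"triangle inequality violated for ({d12}, {d13}, {d23})"
        )
    cos_t = (d12 * d12 + d13 * d13 - d23 * d23) / (2.0 * d12 * d13)
    cos_t = max(-1.0, min(1.0, cos_t))
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    x1 = (0.0, 0.0, 0.0)
    x2 = (-d12, 0.0, 0.0)
    x3 = (-d13 * cos_t, d13 * sin_t, 0.0)
    return x1, x2, x3


def trilaterate(a: Point3, b: Point3, c: Point3,
                ra: float, rb: float, rc: float,
                tol: float = 1e-9) -> List[Point3]:
    """Intersect three spheres centred at non-collinear ``a``, ``b``, ``c``.

    Returns 0, 1 or 2 points.  Two points are mirror images through the
    plane of the anchors and are returned positive-orientation first (the
    point with orientation bit 1 with respect to ``(a, b, c)``).  When the
    discriminant falls within ``tol**2`` of zero the unique in-plane point
    is returned; an empty list means the spheres do not meet within ``tol``.
    """
    _check_ref((a, b, c))
    ex = _unit(_sub(b, a))
    d = dist(b, a)
    ac = _sub(c, a)
    i = _dot(ex, ac)
    ey = _unit(_sub(ac, _scale(ex, i)))
    j = _dot(ey, ac)
    ez = _cross(ex, ey)

    x = (ra * ra - rb * rb + d * d) / (2.0 * d)
    y = (ra * ra - rc * rc + i * i + j * j - 2.0 * i * x) / (2.0 * j)
    z2 = ra * ra - x * x - y * y

    base = _add(a, _add(_scale(ex, x), _scale(ey, y)))
    if z2 > tol * tol:
        z = math.sqrt(z2)
        p_pos = _add(base, _scale(ez, z))
        p_neg = _add(base, _scale(ez, -z))
        out = [p_pos, p_neg]
    elif z2 > -2.0 * tol * max(ra, rb, rc, tol):
        out = [base]
    else:
        return []
    # residual guard: reject marginal pseudo-intersections
    for p in out:
        if (abs(dist(p, a) - ra) > max(tol, 1e-9)
                or abs(dist(p, b) - rb) > max(tol, 1e-9)
                or abs(dist(p, c) - rc) > max(tol, 1e-9)):
            return []
    return out


def orientation_bit(ref: PlaneRef, p: Point3, tol: float = ON_PLANE_TOL) -> int:
    """Side of the predecessors' plane on which ``p`` lies: 1 above, 0 below.

    Points within ``tol`` (signed-volume units) of the plane take bit 0 by
    convention, which makes the bit of a degenerate (single-intersection)
    vertex well defined.
    """
    _check_ref(ref)
    v = signed_volume(ref, p)
    return 1 if v > tol else 0


def reflect(ref: PlaneRef, p: Point3) -> Point3:
    """Mirror image of ``p`` through the plane spanned by ``ref``."""
    _check_ref(ref)
    p1, p2, p3 = ref
    n = _unit(_cross(_sub(p2, p1), _sub(p3, p1)))
    d = _dot(n, _sub(p, p1))
    return _sub(p, _scale(n, 2.0 * d))


# ---------------------------------------------------------------------------
# internal-coordinate helpers (used to turn rigid-geometry parameters into
# discretization distances)

def dist13(l1: float, l2: float, theta_deg: float) -> float:
    """1-3 distance across two bonds meeting at angle ``theta_deg``."""
    t = math.radians(theta_deg)
    return math.sqrt(l1 * l1 + l2 * l2 - 2.0 * l1 * l2 * math.cos(t))


def extend_chain(a: Point3, b: Point3, c: Point3,
                 bond: float, theta_deg: float, tau_deg: float) -> Point3:
    """Place the next atom of a chain a-b-c-d from internal coordinates.

    ``bond`` is |c-d|, ``theta_deg`` the angle b-c-d and ``tau_deg`` the
    torsion a-b-c-d (standard NeRF construction).
    """
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = _unit(_sub(c, b))
    n = _unit(_cross(_sub(b, a), bc))
    m = _cross(n, bc)
    d2 = (
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(tau),
        bond * math.sin(theta) * math.sin(tau),
    )
    return (
        c[0] + bc[0] * d2[0] + m[0] * d2[1] + n[0] * d2[2],
        c[1] + bc[1] * d2[0] + m[1] * d2[1] + n[1] * d2[2],
        c[2] + bc[2] * d2[0] + m[2] * d2[1] + n[2] * d2[2],
    )


def chain_end_distance(bonds: Sequence[float],
                       angles_deg: Sequence[float],
                       torsions_deg: Sequence[float]) -> float:
    """End-to-end distance of a chain given bonds, angles and torsions.

    ``len(bonds) = k`` places ``k + 1`` atoms; ``angles_deg`` has ``k - 1``
    entries and ``torsions_deg`` ``k - 2``.
    """
    k = len(bonds)
    if len(angles_deg) != k - 1 or len(torsions_deg) != k - 2:
        raise ValueError("inconsistent internal-coordinate counts")
    pts: List[Point3] = [(0.0, 0.0, 0.0), (bonds[0], 0.0, 0.0)]
    if k >= 2:
        t = math.radians(angles_deg[0])
        pts.append((
            bonds[0] - bonds[1] * math.cos(t),
            bonds[1] * math.sin(t),
            0.0,
        ))
    for idx in range(2, k):
        pts.append(extend_chain(pts[idx - 2], pts[idx - 1], pts[idx],
                                bonds[idx], angles_deg[idx - 1],
                                torsions_deg[idx - 2]))
    return dist(pts[0], pts[-1])
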