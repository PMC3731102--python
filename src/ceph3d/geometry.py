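"""Exact 3D Euclidean primitives: distances, midpoints, vertex angles,
triangle metrics.

All angles are reported in degrees because the clinical symmetry
threshold (4 degrees of semiangle discrepancy) is stated in degrees.
Cosines are clamped to [-1, 1] before arccos so near-collinear landmark
triples yield 0/180 degrees instead of NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .landmarks import DEGENERACY_TOL_MM, LandmarkSet, Point3

__all__ = [
    "DegeneracyError",
    "IncompleteSetError",
    "TriangleMetrics",
    "distance",
    "midpoint",
    "vertex_angle",
    "triangle",
]


class DegeneracyError(ValueError):
    """Raised when coincident or collinear landmarks make a quantity ill-defined."""


class IncompleteSetError(KeyError):
    """Raised when an analysis operation requires landmarks that are absent."""

    def __init__(self, subject_id: str, missing: tuple[str, ...]):
        self.subject_id = subject_id
        self.missing = missing
        super().__init__(
            f"subject {subject_id!r}: missing landmarks {', '.join(missing)}"
        )


def distance(p: Point3, q: Point3) -> float:
    """Euclidean distance between two points, in mm."""
    return math.dist(p.as_tuple(), q.as_tuple())


def midpoint(p: Point3, q: Point3) -> Point3:
    """Componentwise midpoint of two points."""
    return Point3((p.x + q.x) / 2.0, (p.y + q.y) / 2.0, (p.z + q.z) / 2.0)


def vertex_angle(a: Point3, vertex: Point3, b: Point3) -> float:
    """Interior angle at ``vertex`` between rays to ``a`` and ``b``, in degrees.

    Raises :class:`DegeneracyError` if either ray is shorter than the
    coincidence tolerance.
    """
    ua = (a.x - vertex.x, a.y - vertex.y, a.z - vertex.z)
    ub = (b.x - vertex.x, b.y - vertex.y, b.z - vertex.z)
    na = math.hypot(*ua)
    nb = math.hypot(*ub)
    if na < DEGENERACY_TOL_MM or nb < DEGENERACY_TOL_MM:
        raise DegeneracyError(
            "zero-length ray at vertex: endpoints coincide with the vertex"
        )
    cos = (ua[0] * ub[0] + ua[1] * ub[1] + ua[2] * ub[2]) / (na * nb)
    cos = max(-1.0, min(1.0, cos))
    return math.degrees(math.acos(cos))


@dataclass(frozen=True)
class TriangleMetrics:
    """Side lengths, interior angles and perimeter of a landmark triangle.

    ``side_lengths`` and ``vertex_angles`` are keyed by landmark code; the
    side key is the vertex *opposite* that side. Angles are degrees, sides
    and perimeter mm.
    """

    name: str
    vertices: tuple[str, str, str]
    side_lengths: dict[str, float]
    vertex_angles: dict[str, float]
    perimeter: float


def triangle(
    a_name: str, v_name: str, b_name: str, s: LandmarkSet
) -> TriangleMetrics:
    """Compute full metrics for the triangle on three named landmarks.

    Raises :class:`IncompleteSetError` for absent landmarks and
    :class:`DegeneracyError` for coincident vertices. Collinear (but
    non-coincident) triples are valid and yield angles {0, 0, 180}.
    """
    names = (a_name, v_name, b_name)
    missing = tuple(n for n in names if n not in s)
    if missing:
        raise IncompleteSetError(s.subject_id, missing)
    pts = {n: s[n] for n in names}
    for i, m in enumerate(names):
        for n in names[i + 1:]:
            if distance(pts[m], pts[n]) < DEGENERACY_TOL_MM:
                raise DegeneracyError(
                    f"coincident landmarks {m} and {n} in triangle "
                    f"{'-'.join(names)} (subject {s.subject_id!r})"
                )
    # side opposite each vertex
    sides = {
        a_name: distance(pts[v_name], pts[b_name]),
        v_name: distance(pts[a_name], pts[b_name]),
        b_name: distance(pts[a_name], pts[v_name]),
    }
    angles = {
        a_name: vertex_angle(pts[v_name], pts[a_name], pts[b_name]),
        v_name: vertex_angle(pts[a_name], pts[v_name], pts[b_name]),
        b_name: vertex_angle(pts[a_name], pts[b_name], pts[v_name]),
    }
    return TriangleMetrics(
        name="-".join(names),
        vertices=names,
        side_lengths=sides,
        vertex_angles=angles,
        perimeter=sum(sides.values()),
    )
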