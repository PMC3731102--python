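"""Landmark and measurement registries for 3D cephalometric analysis.

The analysis operates on 12 named cephalometric landmarks digitized on
CBCT reconstructions. Four are paired right-side points (CdR, GoR, FzR,
KrR), four are their left mirrors, and four lie on the midsagittal plane
(Me, N, Gl, DB). From these, 21 inter-landmark Euclidean distances are
defined; those distances are the sides of the 7 triangles used for
symmetry assessment plus the midline glabella-menton distance.

All coordinates are millimetres in an arbitrary right-handed scanner
frame. No axis-orientation convention (LPS/RAS) is imposed: every
quantity the analysis reports is invariant under rigid motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Laterality",
    "LANDMARKS",
    "RIGHT_LANDMARKS",
    "LEFT_LANDMARKS",
    "MIDLINE_LANDMARKS",
    "MIRROR",
    "MEASUREMENTS",
    "MEASUREMENT_ENDPOINTS",
    "TRIANGLES",
    "MANDIBULAR_TRIANGLES",
    "Point3",
    "LandmarkSet",
    "ValidationReport",
    "laterality",
    "mirror_code",
    "validate_landmark_set",
    "DEGENERACY_TOL_MM",
]

# Coincidence tolerance for landmark pairs, far below the 0.4 mm CBCT voxel.
DEGENERACY_TOL_MM = 1e-9


class Laterality(str, Enum):
    RIGHT = "right"
    LEFT = "left"
    MIDLINE = "midline"


RIGHT_LANDMARKS: tuple[str, ...] = ("CdR", "GoR", "FzR", "KrR")
LEFT_LANDMARKS: tuple[str, ...] = ("CdL", "GoL", "FzL", "KrL")
MIDLINE_LANDMARKS: tuple[str, ...] = ("Me", "N", "Gl", "DB")

#: Registry order: right/left pairs first, then midline points.
LANDMARKS: tuple[str, ...] = (
    "CdR", "CdL", "GoR", "GoL", "FzR", "FzL", "KrR", "KrL",
    "Me", "N", "Gl", "DB",
)

#: Involutive right<->left partner map; midline landmarks map to themselves.
MIRROR: dict[str, str] = {
    "CdR": "CdL", "CdL": "CdR",
    "GoR": "GoL", "GoL": "GoR",
    "FzR": "FzL", "FzL": "FzR",
    "KrR": "KrL", "KrL": "KrR",
    "Me": "Me", "N": "N", "Gl": "Gl", "DB": "DB",
}

#: The 21 linear measurements, in registry order. The first ten are the
#: sides of the three craniofacial triangles plus Gl-Me; the remaining
#: eleven are the sides of the four mandibular (ramus and body) triangles.
MEASUREMENTS: tuple[str, ...] = (
    "CdR-Me", "CdL-Me", "CdR-CdL",
    "FzR-Me", "FzL-Me", "FzR-FzL",
    "GoR-N", "GoL-N", "GoR-GoL",
    "Gl-Me",
    "KrR-CdR", "KrR-GoR", "CdR-GoR",
    "KrL-CdL", "KrL-GoL", "CdL-GoL",
    "DB-Me", "DB-GoR", "Me-GoR", "DB-GoL", "Me-GoL",
)

MEASUREMENT_ENDPOINTS: dict[str, tuple[str, str]] = {
    code: tuple(code.split("-")) for code in MEASUREMENTS  # type: ignore[misc]
}

#: The 7 triangles as ordered vertex triples, keyed by display name.
#: The last four are the mandibular ramus (Kr-Cd-Go) and body (DB-Me-Go)
#: triangles, one per side.
TRIANGLES: dict[str, tuple[str, str, str]] = {
    "CdR-Me-CdL": ("CdR", "Me", "CdL"),
    "FzR-Me-FzL": ("FzR", "Me", "FzL"),
    "GoR-N-GoL": ("GoR", "N", "GoL"),
    "KrR-CdR-GoR": ("KrR", "CdR", "GoR"),
    "KrL-CdL-GoL": ("KrL", "CdL", "GoL"),
    "DB-Me-GoR": ("DB", "Me", "GoR"),
    "DB-Me-GoL": ("DB", "Me", "GoL"),
}

MANDIBULAR_TRIANGLES: tuple[str, ...] = (
    "KrR-CdR-GoR", "KrL-CdL-GoL", "DB-Me-GoR", "DB-Me-GoL",
)


def laterality(code: str) -> Laterality:
    """Return the laterality of a landmark code."""
    if code in RIGHT_LANDMARKS:
        return Laterality.RIGHT
    if code in LEFT_LANDMARKS:
        return Laterality.LEFT
    if code in MIDLINE_LANDMARKS:
        return Laterality.MIDLINE
    raise KeyError(f"unknown landmark code: {code!r}")


def mirror_code(code: str) -> str:
    """Return the contralateral partner of a landmark code.

    Midline landmarks are their own partner.
    """
    try:
        return MIRROR[code]
    except KeyError:
        raise KeyError(f"unknown landmark code: {code!r}") from None


@dataclass(frozen=True)
class Point3:
    """A 3D point in millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        # coerce to builtin float so serialization is repr-stable
        for name in ("x", "y", "z"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate {name}={v!r}")
            object.__setattr__(self, name, v)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class LandmarkSet:
    """One subject's named 3D landmark coordinates.

    A set is *complete* when all 12 registry landmarks are present;
    the analysis operations require completeness.
    """

    subject_id: str
    points: dict[str, Point3] = field(default_factory=dict)
    age: float | None = None

    def __post_init__(self) -> None:
        for code in self.points:
            if code not in MIRROR:
                raise KeyError(f"unknown landmark code: {code!r}")

    @property
    def complete(self) -> bool:
        return all(code in self.points for code in LANDMARKS)

    def missing(self) -> tuple[str, ...]:
        return tuple(c for c in LANDMARKS if c not in self.points)

    def __getitem__(self, code: str) -> Point3:
        return self.points[code]

    def __contains__(self, code: str) -> bool:
        return code in self.points

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ValidationReport:
    """Outcome of structural validation of a landmark set.

    ``degenerate_pairs`` lists landmark pairs closer than the coincidence
    tolerance; such pairs make distances, ratios and angles meaningless.
    """

    subject_id: str
    missing: tuple[str, ...] = ()
    non_finite: tuple[str, ...] = ()
    degenerate_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not (self.missing or self.non_finite or self.degenerate_pairs)


def validate_landmark_set(s: LandmarkSet) -> ValidationReport:
    """Check a landmark set for completeness and geometric degeneracy.

    Never raises: returns a report listing every violation. Coincident
    landmark pairs (separation below ``DEGENERACY_TOL_MM``) are flagged
    because they collapse triangles and zero out ratio denominators.
    """
    missing = s.missing()
    # Point3 rejects non-finite values at construction, but points may be
    # built by other routes (e.g. object.__setattr__); re-check here.
    non_finite = tuple(
        code for code, p in s.points.items()
        if not all(math.isfinite(c) for c in p.as_tuple())
    )
    present = [c for c in LANDMARKS if c in s.points]
    degenerate: list[tuple[str, str]] = []
    for i, a in enumerate(present):
        pa = s.points[a]
        for b in present[i + 1:]:
            pb = s.points[b]
            d = math.dist(pa.as_tuple(), pb.as_tuple())
            if d < DEGENERACY_TOL_MM:
                degenerate.append((a, b))
    return ValidationReport(
        subject_id=s.subject_id,
        missing=missing,
        non_finite=non_finite,
        degenerate_pairs=tuple(degenerate),
    )


def _check_registry() -> None:
    assert len(LANDMARKS) == 12
    assert len(set(LANDMARKS)) == 12
    assert len(MEASUREMENTS) == 21
    assert len(TRIANGLES) == 7
    # every triangle side plus Gl-Me is a registered measurement
    sides: set[frozenset[str]] = set()
    for a, v, b in TRIANGLES.values():
        sides |= {frozenset((a, v)), frozenset((v, b)), frozenset((a, b))}
    sides.add(frozenset(("Gl", "Me")))
    registered = {frozenset(ep) for ep in MEASUREMENT_ENDPOINTS.values()}
    assert sides == registered


_check_registry()
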