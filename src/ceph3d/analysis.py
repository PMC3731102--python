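"""Per-subject craniofacial symmetry analysis.

From one complete 12-landmark set this module derives:

* the 21 inter-landmark distances;
* the 7 triangles (3 craniofacial, 4 mandibular) with sides and angles;
* the **semiangle test**: the apex angle CdR-Me-CdL is split by the ray
  from Me to CdM (midpoint of the inter-condylar segment CdR-CdL) into
  two semiangles; the mandible is called symmetric when the two halves
  differ by at most a threshold (default 4 degrees, inclusive). Equal
  semiangles are equivalent to the condyle-menton triangle being
  isosceles, i.e. to left-right symmetry of that triangle.
* all 45 pairwise ratios among the 10 craniofacial distances (the sides
  of the three upper triangles plus Gl-Me) — perfect facial symmetry
  demands homologous distances in a 1:1 ratio;
* the 9 named mandibular ramus/body ratios;
* the millimetric left-right discrepancy of the three homologous distance
  pairs (Fz-Me, Go-N, Cd-Me), classified against a threshold (default
  5 mm, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import (
    DegeneracyError,
    IncompleteSetError,
    TriangleMetrics,
    distance,
    midpoint,
    triangle,
    vertex_angle,
)
from .landmarks import (
    DEGENERACY_TOL_MM,
    MEASUREMENT_ENDPOINTS,
    MEASUREMENTS,
    TRIANGLES,
    LandmarkSet,
)

__all__ = [
    "AnalysisConfig",
    "MeasurementVector",
    "SemiangleResult",
    "RatioEntry",
    "RatioTable",
    "MandibleRatios",
    "DiscrepancyResult",
    "PatientReport",
    "FACIAL_RATIO_DISTANCES",
    "MANDIBLE_RATIO_DEFS",
    "compute_measurements",
    "semiangle_symmetry",
    "facial_ratios",
    "mandible_ratios",
    "lr_discrepancy",
    "analyze_patient",
]

#: The 10 distances entering the facial (craniofacial) ratio table, in
#: registry order: sides of CdR-Me-CdL, FzR-Me-FzL, GoR-N-GoL, plus Gl-Me.
FACIAL_RATIO_DISTANCES: tuple[str, ...] = (
    "CdR-Me", "CdL-Me", "CdR-CdL",
    "FzR-Me", "FzL-Me", "FzR-FzL",
    "GoR-N", "GoL-N", "GoR-GoL",
    "Gl-Me",
)

#: The 9 mandibular ratios: numerator / denominator measurement codes.
#: The five left/right comparisons put the left side in the numerator;
#: the within-body ratios compare the DB side against the Me side; the
#: last two compare each ramus base against the DB-Me body base.
MANDIBLE_RATIO_DEFS: dict[str, tuple[str, str]] = {
    "R_Kr_Cd": ("KrL-CdL", "KrR-CdR"),
    "R_Kr_Go": ("KrL-GoL", "KrR-GoR"),
    "R_Cd_Go": ("CdL-GoL", "CdR-GoR"),
    "R_DB_Go": ("DB-GoL", "DB-GoR"),
    "R_Go_Me": ("Me-GoL", "Me-GoR"),
    "R_DB_GoL_Me": ("DB-GoL", "Me-GoL"),
    "R_DB_GoR_Me": ("DB-GoR", "Me-GoR"),
    "R_KrL_CdL_DB_Me": ("KrL-CdL", "DB-Me"),
    "R_KrR_CdR_DB_Me": ("KrR-CdR", "DB-Me"),
}

#: The three homologous left/right distance pairs of the millimetric
#: discrepancy test, keyed by short name.
DISCREPANCY_PAIRS: dict[str, tuple[str, str]] = {
    "Fz": ("FzR-Me", "FzL-Me"),
    "Go": ("GoR-N", "GoL-N"),
    "Cd": ("CdR-Me", "CdL-Me"),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-subject analysis.

    semiangle_threshold_deg
        Maximum admissible semiangle discrepancy (inclusive) for a
        subject to be called symmetric. Degrees.
    discrepancy_threshold_mm
        Maximum admissible left-right millimetric discrepancy
        (inclusive). Millimetres.
    ratio_tolerance
        Deviation from 1.0 beyond which a facial ratio is flagged as
        departing from the 1:1 ideal. Dimensionless.
    """

    semiangle_threshold_deg: float = 4.0
    discrepancy_threshold_mm: float = 5.0
    ratio_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if self.semiangle_threshold_deg <= 0:
            raise ValueError("semiangle_threshold_deg must be positive")
        if self.discrepancy_threshold_mm <= 0:
            raise ValueError("discrepancy_threshold_mm must be positive")
        if self.ratio_tolerance <= 0:
            raise ValueError("ratio_tolerance must be positive")


@dataclass
class MeasurementVector:
    """The 21 named inter-landmark distances for one subject, in mm."""

    subject_id: str
    values: dict[str, float]

    def __getitem__(self, code: str) -> float:
        return self.values[code]


@dataclass(frozen=True)
class SemiangleResult:
    """Outcome of the semiangle symmetry test at the menton.

    ``semi_right`` is the angle CdR-Me-CdM, ``semi_left`` CdL-Me-CdM;
    their sum equals ``full_angle`` (CdM lies on the segment CdR-CdL, so
    the three rays from Me are coplanar). ``degenerate`` flags a menton
    collinear with the inter-condylar line, where the split is
    ill-conditioned.
    """

    subject_id: str
    full_angle: float
    semi_right: float
    semi_left: float
    difference: float
    symmetric: bool
    threshold: float
    degenerate: bool = False


@dataclass(frozen=True)
class RatioEntry:
    numerator: str
    denominator: str
    value: float
    flagged: bool


@dataclass
class RatioTable:
    """All pairwise ratios among the facial distances.

    Keys are (numerator, denominator) measurement-code pairs with the
    numerator first in registry order. ``flagged`` marks entries whose
    value deviates from the 1:1 ideal by more than the tolerance.
    """

    subject_id: str
    entries: dict[tuple[str, str], RatioEntry]
    tolerance: float

    def __getitem__(self, key: tuple[str, str]) -> RatioEntry:
        return self.entries[key]


@dataclass
class MandibleRatios:
    """The 9 named mandibular ramus/body ratios (dimensionless)."""

    subject_id: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass(frozen=True)
class DiscrepancyResult:
    """Left-right millimetric discrepancies of the three homologous pairs."""

    subject_id: str
    d_Fz: float
    d_Go: float
    d_Cd: float
    max_discrepancy: float
    within_threshold: bool
    threshold: float

    @property
    def within_5mm(self) -> bool:
        return self.within_threshold


@dataclass
class PatientReport:
    """All per-subject results, computed from one landmark set."""

    subject_id: str
    measurements: MeasurementVector
    triangles: dict[str, TriangleMetrics]
    semiangle: SemiangleResult
    facial_ratios: RatioTable
    mandible_ratios: MandibleRatios
    discrepancy: DiscrepancyResult

    def to_dict(self) -> dict:
        """JSON-serializable nested representation."""
        return {
            "subject_id": self.subject_id,
            "measurements": dict(self.measurements.values),
            "triangles": {
                name: {
                    "vertices": list(t.vertices),
                    "side_lengths": dict(t.side_lengths),
                    "vertex_angles": dict(t.vertex_angles),
                    "perimeter": t.perimeter,
                }
                for name, t in self.triangles.items()
            },
            "semiangle": {
                "full_angle_deg": self.semiangle.full_angle,
                "semi_right_deg": self.semiangle.semi_right,
                "semi_left_deg": self.semiangle.semi_left,
                "difference_deg": self.semiangle.difference,
                "symmetric": self.semiangle.symmetric,
                "threshold_deg": self.semiangle.threshold,
                "degenerate": self.semiangle.degenerate,
            },
            "facial_ratios": {
                f"{n}/{d}": {"value": e.value, "flagged": e.flagged}
                for (n, d), e in self.facial_ratios.entries.items()
            },
            "mandible_ratios": dict(self.mandible_ratios.values),
            "discrepancy": {
                "d_Fz_mm": self.discrepancy.d_Fz,
                "d_Go_mm": self.discrepancy.d_Go,
                "d_Cd_mm": self.discrepancy.d_Cd,
                "max_discrepancy_mm": self.discrepancy.max_discrepancy,
                "within_threshold": self.discrepancy.within_threshold,
                "threshold_mm": self.discrepancy.threshold,
            },
        }

    def to_row(self) -> dict[str, object]:
        """Flat one-row representation for tabular (CSV) export.

        Columns use registry codes verbatim; ratio columns are named
        ``numerator/denominator``.
        """
        row: dict[str, object] = {"subject_id": self.subject_id}
        for code in MEASUREMENTS:
            row[code] = self.measurements.values[code]
        sa = self.semiangle
        row["full_angle_deg"] = sa.full_angle
        row["semi_right_deg"] = sa.semi_right
        row["semi_left_deg"] = sa.semi_left
        row["semiangle_diff_deg"] = sa.difference
        row["semiangle_symmetric"] = sa.symmetric
        row["semiangle_degenerate"] = sa.degenerate
        for (n, d), e in self.facial_ratios.entries.items():
            row[f"{n}/{d}"] = e.value
        for name, v in self.mandible_ratios.values.items():
            row[name] = v
        dc = self.discrepancy
        row["d_Fz_mm"] = dc.d_Fz
        row["d_Go_mm"] = dc.d_Go
        row["d_Cd_mm"] = dc.d_Cd
        row["max_discrepancy_mm"] = dc.max_discrepancy
        row["within_discrepancy_threshold"] = dc.within_threshold
        return row


def _require(s: LandmarkSet, codes: tuple[str, ...]) -> None:
    missing = tuple(c for c in codes if c not in s)
    if missing:
        raise IncompleteSetError(s.subject_id, missing)


def compute_measurements(s: LandmarkSet) -> MeasurementVector:
    """Compute all 21 registry distances from a complete landmark set."""
    if not s.complete:
        raise IncompleteSetError(s.subject_id, s.missing())
    values = {
        code: distance(s[a], s[b])
        for code, (a, b) in MEASUREMENT_ENDPOINTS.items()
    }
    return MeasurementVector(subject_id=s.subject_id, values=values)


def semiangle_symmetry(
    s: LandmarkSet, threshold_deg: float = 4.0
) -> SemiangleResult:
    """Split the CdR-Me-CdL apex angle at the inter-condylar midpoint.

    CdM is the midpoint of the segment CdR-CdL; the semiangles are the
    angles at Me between each condyle and CdM. The subject is symmetric
    when ``|semi_right - semi_left| <= threshold_deg`` (inclusive).

    A menton lying on the inter-condylar line (within the coincidence
    tolerance) makes the split ill-conditioned; the result is returned
    with ``degenerate=True`` rather than raising, so cohort runs survive
    pathological subjects.
    """
    _require(s, ("CdR", "CdL", "Me"))
    cdr, cdl, me = s["CdR"], s["CdL"], s["Me"]
    if distance(cdr, cdl) < DEGENERACY_TOL_MM:
        raise DegeneracyError(
            f"condyles coincide for subject {s.subject_id!r}: CdM undefined"
        )
    cdm = midpoint(cdr, cdl)
    full = vertex_angle(cdr, me, cdl)
    semi_r = vertex_angle(cdr, me, cdm)
    semi_l = vertex_angle(cdl, me, cdm)
    # perpendicular distance from Me to line(CdR, CdL)
    u = (cdl.x - cdr.x, cdl.y - cdr.y, cdl.z - cdr.z)
    w = (me.x - cdr.x, me.y - cdr.y, me.z - cdr.z)
    cross = (
        u[1] * w[2] - u[2] * w[1],
        u[2] * w[0] - u[0] * w[2],
        u[0] * w[1] - u[1] * w[0],
    )
    dist_to_line = math.hypot(*cross) / math.hypot(*u)
    degenerate = dist_to_line < DEGENERACY_TOL_MM
    diff = abs(semi_r - semi_l)
    return SemiangleResult(
        subject_id=s.subject_id,
        full_angle=full,
        semi_right=semi_r,
        semi_left=semi_l,
        difference=diff,
        symmetric=diff <= threshold_deg,
        threshold=threshold_deg,
        degenerate=degenerate,
    )


def facial_ratios(m: MeasurementVector, tolerance: float = 0.10) -> RatioTable:
    """All 45 unordered-pair ratios among the 10 facial distances.

    The numerator is whichever distance comes first in registry order, so
    ratio orientation is deterministic. Each entry is flagged when its
    value deviates from 1 by more than ``tolerance``.
    """
    entries: dict[tuple[str, str], RatioEntry] = {}
    for i, num in enumerate(FACIAL_RATIO_DISTANCES):
        for den in FACIAL_RATIO_DISTANCES[i + 1:]:
            dv = m.values[den]
            if dv < DEGENERACY_TOL_MM:
                raise DegeneracyError(
                    f"zero denominator {den} for subject {m.subject_id!r}"
                )
            value = m.values[num] / dv
            entries[(num, den)] = RatioEntry(
                numerator=num,
                denominator=den,
                value=value,
                flagged=abs(value - 1.0) > tolerance,
            )
    return RatioTable(subject_id=m.subject_id, entries=entries, tolerance=tolerance)


def mandible_ratios(m: MeasurementVector) -> MandibleRatios:
    """The 9 named ramus/body ratios of the four mandibular triangles."""
    values: dict[str, float] = {}
    for name, (num, den) in MANDIBLE_RATIO_DEFS.items():
        dv = m.values[den]
        if dv < DEGENERACY_TOL_MM:
            raise DegeneracyError(
                f"zero denominator {den} for subject {m.subject_id!r}"
            )
        values[name] = m.values[num] / dv
    return MandibleRatios(subject_id=m.subject_id, values=values)


def lr_discrepancy(
    m: MeasurementVector, threshold_mm: float = 5.0
) -> DiscrepancyResult:
    """Absolute left-right differences of the three homologous pairs.

    The subject is within tolerance when the largest of the three
    discrepancies is at most ``threshold_mm`` (inclusive).
    """
    diffs = {
        key: abs(m.values[r] - m.values[l])
        for key, (r, l) in DISCREPANCY_PAIRS.items()
    }
    mx = max(diffs.values())
    return DiscrepancyResult(
        subject_id=m.subject_id,
        d_Fz=diffs["Fz"],
        d_Go=diffs["Go"],
        d_Cd=diffs["Cd"],
        max_discrepancy=mx,
        within_threshold=mx <= threshold_mm,
        threshold=threshold_mm,
    )


def analyze_patient(
    s: LandmarkSet, config: AnalysisConfig | None = None
) -> PatientReport:
    """Run the full per-subject analysis on one complete landmark set."""
    config = config or AnalysisConfig()
    if not s.complete:
        raise IncompleteSetError(s.subject_id, s.missing())
    m = compute_measurements(s)
    tris = {name: triangle(*verts, s) for name, verts in TRIANGLES.items()}
    return PatientReport(
        subject_id=s.subject_id,
        measurements=m,
        triangles=tris,
        semiangle=semiangle_symmetry(s, config.semiangle_threshold_deg),
        facial_ratios=facial_ratios(m, config.ratio_tolerance),
        mandible_ratios=mandible_ratios(m),
        discrepancy=lr_discrepancy(m, config.discrepancy_threshold_mm),
    )
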