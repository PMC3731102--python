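"""Reading and writing subject landmark data.

Three formats are supported:

* **csv** — the package's cohort dialect: header
  ``subject_id,landmark,x_mm,y_mm,z_mm``, one row per (subject, landmark),
  UTF-8, ``.`` decimal separator. Any number of subjects per file.
* **fcsv** — the 3D Slicer markups fiducial dialect (one subject per
  file). The fiducial ``label`` column is matched to landmark codes
  case-insensitively; unknown labels are skipped with a warning.
* **json** — ``{"subject_id": ..., "points": {code: [x, y, z]}}``, either
  a single object or a list of them.

Loading is strict about the landmark vocabulary (an unknown code in csv
or json is an error, not a skip) and about duplicates, because a silently
dropped or doubled landmark corrupts every downstream symmetry statistic.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from typing import Iterable, TextIO

from .landmarks import LANDMARKS, MIRROR, LandmarkSet, Point3

__all__ = [
    "FORMATS",
    "LandmarkParseError",
    "DuplicateLandmarkError",
    "VocabularyError",
    "load_landmarks",
    "write_landmarks",
    "loads_landmarks",
    "dumps_landmarks",
]

logger = logging.getLogger(__name__)

FORMATS = ("csv", "fcsv", "json")

CSV_HEADER = ("subject_id", "landmark", "x_mm", "y_mm", "z_mm")

#: case-insensitive label -> canonical code
_CODE_BY_LOWER = {c.lower(): c for c in MIRROR}


class LandmarkParseError(ValueError):
    """A row or document that cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateLandmarkError(LandmarkParseError):
    """The same (subject, landmark) appears more than once."""


class VocabularyError(LandmarkParseError):
    """A landmark code outside the 12-code registry."""


def _parse_float(text: str, what: str, line: int | None) -> float:
    try:
        return float(text)
    except ValueError:
        raise LandmarkParseError(f"non-numeric {what}: {text!r}", line) from None


def _canonical_code(label: str, line: int | None, strict: bool) -> str | None:
    code = _CODE_BY_LOWER.get(label.strip().lower())
    if code is None:
        if strict:
            raise VocabularyError(f"unknown landmark code {label!r}", line)
        logger.warning("skipping unknown landmark label %r", label)
    return code


def _add_point(
    sets: dict[str, LandmarkSet],
    order: list[str],
    subject: str,
    code: str,
    p: Point3,
    line: int | None,
) -> None:
    if subject not in sets:
        sets[subject] = LandmarkSet(subject_id=subject)
        order.append(subject)
    if code in sets[subject].points:
        raise DuplicateLandmarkError(
            f"duplicate landmark {code} for subject {subject!r}", line
        )
    sets[subject].points[code] = p


def _load_csv(stream: TextIO) -> list[LandmarkSet]:
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise LandmarkParseError("empty file: expected header", 1) from None
    if tuple(h.strip() for h in header) != CSV_HEADER:
        raise LandmarkParseError(
            f"bad header {header!r}; expected {','.join(CSV_HEADER)}", 1
        )
    sets: dict[str, LandmarkSet] = {}
    order: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 5:
            raise LandmarkParseError(
                f"expected 5 fields, got {len(row)}", lineno
            )
        subject, label, xs, ys, zs = (c.strip() for c in row)
        code = _canonical_code(label, lineno, strict=True)
        assert code is not None
        p = Point3(
            _parse_float(xs, "x_mm", lineno),
            _parse_float(ys, "y_mm", lineno),
            _parse_float(zs, "z_mm", lineno),
        )
        _add_point(sets, order, subject, code, p, lineno)
    return [sets[s] for s in order]


def _load_json(stream: TextIO) -> list[LandmarkSet]:
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"invalid JSON: {exc.msg}", exc.lineno) from None
    records = doc if isinstance(doc, list) else [doc]
    out: list[LandmarkSet] = []
    seen: set[str] = set()
    for rec in records:
        if not isinstance(rec, dict) or "subject_id" not in rec or "points" not in rec:
            raise LandmarkParseError(
                "each record must be an object with 'subject_id' and 'points'"
            )
        subject = str(rec["subject_id"])
        if subject in seen:
            raise DuplicateLandmarkError(f"duplicate subject {subject!r}")
        seen.add(subject)
        s = LandmarkSet(subject_id=subject, age=rec.get("age"))
        for label, xyz in rec["points"].items():
            code = _canonical_code(label, None, strict=True)
            assert code is not None
            if code in s.points:
                raise DuplicateLandmarkError(
                    f"duplicate landmark {code} for subject {subject!r}"
                )
            if not (isinstance(xyz, (list, tuple)) and len(xyz) == 3):
                raise LandmarkParseError(
                    f"point {label!r} of subject {subject!r} is not an [x,y,z] triple"
                )
            s.points[code] = Point3(float(xyz[0]), float(xyz[1]), float(xyz[2]))
        out.append(s)
    return out


def _load_fcsv(stream: TextIO, subject_id: str | None) -> list[LandmarkSet]:
    """Parse a 3D Slicer markups fiducial file (one subject).

    Only the x, y, z (columns 2-4) and label (column 12) fields are used.
    """
    s = LandmarkSet(subject_id=subject_id or "fcsv-subject")
    n_data = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = next(csv.reader([line]))
        if len(fields) < 12:
            raise LandmarkParseError(
                f"fiducial row has {len(fields)} fields, expected >= 12", lineno
            )
        n_data += 1
        code = _canonical_code(fields[11], lineno, strict=False)
        if code is None:
            continue
        if code in s.points:
            raise DuplicateLandmarkError(
                f"duplicate landmark {code} for subject {s.subject_id!r}", lineno
            )
        s.points[code] = Point3(
            _parse_float(fields[1], "x", lineno),
            _parse_float(fields[2], "y", lineno),
            _parse_float(fields[3], "z", lineno),
        )
    if n_data == 0:
        raise LandmarkParseError("fiducial file contains no data rows")
    return [s]


def load_landmarks(
    source: TextIO | str, format: str = "csv", subject_id: str | None = None
) -> list[LandmarkSet]:
    """Load landmark sets from a text stream or string.

    Parameters
    ----------
    source
        An open text stream, or the file content as a string.
    format
        One of ``csv``, ``fcsv``, ``json``.
    subject_id
        Subject identifier for ``fcsv`` input (the Slicer format stores
        no subject id); ignored for the other formats.
    """
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {FORMATS}")
    stream = _io.StringIO(source) if isinstance(source, str) else source
    if format == "csv":
        return _load_csv(stream)
    if format == "json":
        return _load_json(stream)
    return _load_fcsv(stream, subject_id)


def _write_csv(cohort: list[LandmarkSet]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_HEADER)
    for s in cohort:
        for code in LANDMARKS:
            if code in s.points:
                p = s.points[code]
                w.writerow([s.subject_id, code, repr(p.x), repr(p.y), repr(p.z)])
    return buf.getvalue()


def _write_json(cohort: list[LandmarkSet]) -> str:
    records = []
    for s in cohort:
        rec: dict = {
            "subject_id": s.subject_id,
            "points": {
                code: list(s.points[code].as_tuple())
                for code in LANDMARKS
                if code in s.points
            },
        }
        if s.age is not None:
            rec["age"] = s.age
        records.append(rec)
    return json.dumps(records, indent=2) + "\n"


def _write_fcsv(cohort: list[LandmarkSet]) -> str:
    if len(cohort) != 1:
        raise ValueError(
            "fcsv holds one markups list: write exactly one subject per file"
        )
    s = cohort[0]
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = LPS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, code in enumerate(c for c in LANDMARKS if c in s.points):
        p = s.points[code]
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p.x!r},{p.y!r},{p.z!r},"
            f"0,0,0,1,1,1,0,{code},,"
        )
    return "\n".join(lines) + "\n"


def dumps_landmarks(cohort: Iterable[LandmarkSet], format: str = "csv") -> str:
    """Serialize a cohort to text in the given format.

    Row order is deterministic: subjects in input order, landmarks in
    registry order.
    """
    cohort = list(cohort)
    if any(len(s.points) == 0 for s in cohort):
        raise ValueError("refusing to write an empty landmark set")
    if format == "csv":
        return _write_csv(cohort)
    if format == "json":
        return _write_json(cohort)
    if format == "fcsv":
        return _write_fcsv(cohort)
    raise ValueError(f"unsupported format {format!r}; expected one of {FORMATS}")


def write_landmarks(
    cohort: Iterable[LandmarkSet], stream: TextIO, format: str = "csv"
) -> None:
    """Write a cohort to an open text stream."""
    stream.write(dumps_landmarks(cohort, format))


def loads_landmarks(
    text: str, format: str = "csv", subject_id: str | None = None
) -> list[LandmarkSet]:
    """Load landmark sets from a string (convenience wrapper)."""
    return load_landmarks(text, format, subject_id)
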