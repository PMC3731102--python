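"""Synthetic skull-landmark cohorts with known ground truth.

No patient cohort accompanies the method, so validation relies on
generated landmark sets: a mirror-symmetric adult template is deformed
by parametric asymmetries (lateral chin deviation, condylar
displacement, unilateral ramus scaling) and then corrupted by isotropic
Gaussian digitization noise on the order of the CBCT voxel (0.4 mm).
Ground-truth symmetry quantities are computed on the noise-free deformed
geometry, before noise injection.

The template is mirror-symmetric across the x = 0 plane: right
landmarks at +x, left at -x, midline landmarks at x = 0. Its
coordinates are fixed artifact constants chosen so that all 21
inter-landmark distances fall in anatomically plausible adult ranges
(40-130 mm); they carry no provenance from any measured cohort.

The semiangle statistic is geometrically insensitive: for adult
mandibular proportions it grows by only about 0.2 degrees per
millimetre of left-right condyle-menton length difference, so a
4-degree discrepancy corresponds to roughly 18 mm of length asymmetry.
The default asymmetric class therefore uses deformations on the scale
of frank hemimandibular elongation (12-20 mm) so that it lies clearly
on the asymmetric side of both clinical criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import compute_measurements, lr_discrepancy, semiangle_symmetry
from .landmarks import LANDMARKS, LandmarkSet, Point3, validate_landmark_set
from .geometry import DegeneracyError

__all__ = [
    "TEMPLATE_COORDINATES",
    "AsymmetrySpec",
    "SubjectTruth",
    "LabeledCohort",
    "symmetric_template",
    "apply_asymmetry",
    "generate_cohort",
]

#: Mirror-symmetric template, mm. Right landmarks at +x, left at -x.
TEMPLATE_COORDINATES: dict[str, tuple[float, float, float]] = {
    "CdR": (50.0, -65.0, 40.0),
    "CdL": (-50.0, -65.0, 40.0),
    "GoR": (45.0, -55.0, -35.0),
    "GoL": (-45.0, -55.0, -35.0),
    "FzR": (47.0, -5.0, 32.0),
    "FzL": (-47.0, -5.0, 32.0),
    "KrR": (45.0, -25.0, 38.0),
    "KrL": (-45.0, -25.0, 38.0),
    "Me": (0.0, 0.0, -45.0),
    "N": (0.0, 10.0, 30.0),
    "Gl": (0.0, 12.0, 42.0),
    "DB": (0.0, 25.0, -5.0),
}

_ZERO3 = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class AsymmetrySpec:
    """Parametric deformation of the symmetric template.

    me_lateral_shift
        Chin deviation: translation of Me along +x, mm (signed; positive
        deviates toward the right side).
    cd_shift
        Per-side condylar displacement vectors, mm.
    ramus_scale
        Per-side scaling of the Kr and Go offsets from the condyle;
        values below 1 shorten the ramus on that side.
    noise_sd
        Isotropic Gaussian digitization noise, mm (applied per landmark
        per axis by the cohort generator, never by
        :func:`apply_asymmetry`).
    seed
        Seed recorded for reproducibility of the noise draw.
    """

    me_lateral_shift: float = 0.0
    cd_shift_right: tuple[float, float, float] = _ZERO3
    cd_shift_left: tuple[float, float, float] = _ZERO3
    ramus_scale_right: float = 1.0
    ramus_scale_left: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ramus_scale_right <= 0 or self.ramus_scale_left <= 0:
            raise ValueError("ramus_scale must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.me_lateral_shift == 0.0
            and self.cd_shift_right == _ZERO3
            and self.cd_shift_left == _ZERO3
            and self.ramus_scale_right == 1.0
            and self.ramus_scale_left == 1.0
        )


@dataclass(frozen=True)
class SubjectTruth:
    """Noise-free ground truth for one generated subject."""

    subject_id: str
    spec: AsymmetrySpec
    true_semiangle_diff: float
    true_max_discrepancy: float
    label: str  # "symmetric" | "asymmetric" (design group)


@dataclass
class LabeledCohort:
    """Generated subjects (noisy) with their noise-free ground truth."""

    subjects: list[LandmarkSet]
    truth: list[SubjectTruth]
    seed: int
    noise_sd: float

    def truth_csv(self) -> str:
        lines = ["subject_id,true_semiangle_diff_deg,true_max_discrepancy_mm,label"]
        for t in self.truth:
            lines.append(
                f"{t.subject_id},{t.true_semiangle_diff!r},"
                f"{t.true_max_discrepancy!r},{t.label}"
            )
        return "\n".join(lines) + "\n"


def symmetric_template(subject_id: str = "template") -> LandmarkSet:
    """The mirror-symmetric 12-landmark template."""
    return LandmarkSet(
        subject_id=subject_id,
        points={c: Point3(*TEMPLATE_COORDINATES[c]) for c in LANDMARKS},
    )


def apply_asymmetry(s: LandmarkSet, spec: AsymmetrySpec) -> LandmarkSet:
    """Deterministically deform a complete landmark set (no noise).

    Order of operations: the condyles are translated first; the Kr and
    Go offsets from the *original* condyle position are then rescaled
    and re-attached to the displaced condyle; finally Me is translated
    along +x. Raises :class:`DegeneracyError` if the deformation
    collapses any landmark pair.
    """
    if not s.complete:
        from .geometry import IncompleteSetError

        raise IncompleteSetError(s.subject_id, s.missing())
    pts = {c: np.array(s[c].as_tuple(), dtype=float) for c in LANDMARKS}
    for side, shift, scale in (
        ("R", spec.cd_shift_right, spec.ramus_scale_right),
        ("L", spec.cd_shift_left, spec.ramus_scale_left),
    ):
        cd0 = pts[f"Cd{side}"].copy()
        cd1 = cd0 + np.asarray(shift, dtype=float)
        pts[f"Cd{side}"] = cd1
        for ramus_lm in (f"Kr{side}", f"Go{side}"):
            pts[ramus_lm] = cd1 + scale * (pts[ramus_lm] - cd0)
    pts["Me"] = pts["Me"] + np.array([spec.me_lateral_shift, 0.0, 0.0])
    out = LandmarkSet(
        subject_id=s.subject_id,
        points={c: Point3(*map(float, pts[c])) for c in LANDMARKS},
        age=s.age,
    )
    report = validate_landmark_set(out)
    if report.degenerate_pairs:
        raise DegeneracyError(
            f"asymmetry spec collapses landmark pairs {report.degenerate_pairs} "
            f"for subject {s.subject_id!r}"
        )
    return out


def _noise_free_truth(s: LandmarkSet) -> tuple[float, float]:
    semi = semiangle_symmetry(s)
    disc = lr_discrepancy(compute_measurements(s))
    return semi.difference, disc.max_discrepancy


def _draw_asymmetry(rng: np.random.Generator,
                    magnitude_range: tuple[float, float]) -> AsymmetrySpec:
    """Draw one frank-asymmetry deformation.

    A side is chosen at random; the chin deviates toward it while the
    contralateral condyle is displaced radially away from the menton
    (hemimandibular-elongation pattern) and the ipsilateral ramus is
    mildly shortened.
    """
    lo, hi = magnitude_range
    u_me = float(rng.uniform(lo, hi))
    u_cd = float(rng.uniform(lo, hi))
    toward_right = bool(rng.integers(0, 2))
    elongated = "CdL" if toward_right else "CdR"
    cd = np.array(TEMPLATE_COORDINATES[elongated])
    me = np.array(TEMPLATE_COORDINATES["Me"])
    radial = (cd - me) / np.linalg.norm(cd - me)
    shift = tuple(float(c) for c in u_cd * radial)
    scale_short = float(rng.uniform(0.88, 0.97))
    if toward_right:
        return AsymmetrySpec(
            me_lateral_shift=u_me,
            cd_shift_left=shift,
            ramus_scale_right=scale_short,
        )
    return AsymmetrySpec(
        me_lateral_shift=-u_me,
        cd_shift_right=shift,
        ramus_scale_left=scale_short,
    )


def generate_cohort(
    n: int,
    symmetric_fraction: float = 0.7,
    asym_magnitude_range: tuple[float, float] = (12.0, 20.0),
    noise_sd: float = 0.4,
    seed: int = 0,
) -> LabeledCohort:
    """Generate ``n`` subjects with a known symmetric/asymmetric split.

    Exactly ``round(n * symmetric_fraction)`` subjects are undeformed
    copies of the template ("symmetric"); the rest receive a frank
    asymmetric deformation with magnitudes drawn uniformly from
    ``asym_magnitude_range`` (mm). Isotropic Gaussian noise of
    ``noise_sd`` mm is then added independently per landmark per axis.
    Ground truth is recorded from the noise-free deformed geometry. One
    seeded pseudo-random stream drives all draws, so a fixed seed yields
    a bit-identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= symmetric_fraction <= 1.0:
        raise ValueError("symmetric_fraction must be in [0, 1]")
    lo, hi = asym_magnitude_range
    if not (0.0 < lo <= hi):
        raise ValueError("asym_magnitude_range must satisfy 0 < lo <= hi")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    n_sym = round(n * symmetric_fraction)
    labels = np.array(["symmetric"] * n_sym + ["asymmetric"] * (n - n_sym))
    rng.shuffle(labels)

    template = symmetric_template()
    width = max(4, len(str(n)))
    subjects: list[LandmarkSet] = []
    truth: list[SubjectTruth] = []
    for i, label in enumerate(labels, start=1):
        sid = f"S{i:0{width}d}"
        if label == "symmetric":
            spec = AsymmetrySpec(noise_sd=noise_sd, seed=seed)
        else:
            base = _draw_asymmetry(rng, (lo, hi))
            spec = AsymmetrySpec(
                me_lateral_shift=base.me_lateral_shift,
                cd_shift_right=base.cd_shift_right,
                cd_shift_left=base.cd_shift_left,
                ramus_scale_right=base.ramus_scale_right,
                ramus_scale_left=base.ramus_scale_left,
                noise_sd=noise_sd,
                seed=seed,
            )
        clean = apply_asymmetry(
            LandmarkSet(subject_id=sid, points=dict(template.points)), spec
        )
        diff, disc = _noise_free_truth(clean)
        noise = rng.normal(0.0, noise_sd, size=(len(LANDMARKS), 3))
        noisy_points = {
            code: Point3(
                clean[code].x + noise[j, 0],
                clean[code].y + noise[j, 1],
                clean[code].z + noise[j, 2],
            )
            for j, code in enumerate(LANDMARKS)
        }
        subjects.append(LandmarkSet(subject_id=sid, points=noisy_points))
        truth.append(
            SubjectTruth(
                subject_id=sid,
                spec=spec,
                true_semiangle_diff=diff,
                true_max_discrepancy=disc,
                label=str(label),
            )
        )
    return LabeledCohort(subjects=subjects, truth=truth, seed=seed, noise_sd=noise_sd)
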