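# Methods

## The analysis

`ceph3d` operates on per-subject sets of 12 named cephalometric
landmarks digitized in 3D (typically on CBCT reconstructions), with
coordinates in millimetres in an arbitrary right-handed scanner frame.
Four landmarks are right-sided (CdR, GoR, FzR, KrR), four are their
left mirrors, four are midsagittal (Me, N, Gl, DB). No axis convention
(LPS/RAS) is imposed: every reported quantity — distances, angles,
ratios — is invariant under rigid motion, and the test suite asserts
this directly.

From a complete set the analysis derives 21 Euclidean inter-landmark
distances. These are exactly the sides of 7 triangles — condyle–menton
CdR–Me–CdL, frontozygomatic FzR–Me–FzL, gonion–nasion GoR–N–GoL, the
two ramus triangles Kr–Cd–Go and the two body triangles DB–Me–Go — plus
the midline Gl–Me distance.

### Semiangle test

Let CdM be the midpoint of segment CdR–CdL. The rays from Me to CdR,
CdM and CdL are coplanar, so the apex angle ∠CdR–Me–CdL splits exactly
into ∠CdR–Me–CdM + ∠CdL–Me–CdM (the suite checks additivity to 1e-6°).
Because the median from Me bisects the apex angle iff the triangle is
isosceles, the semiangle difference is a pure index of left–right
condylar symmetry: it is zero iff |CdR–Me| = |CdL–Me|. A subject is
classified symmetric when the difference is ≤ the angular threshold.

Equal-area reasoning gives the small-asymmetry sensitivity: the two
sub-triangles flanking the median have equal areas, so
a·sin α_R = b·sin α_L with a = |Me–CdR|, b = |Me–CdL|, and for adult
proportions (a ≈ b ≈ 118 mm, semiangles ≈ 25°) the difference grows by
tan(25°)/118 rad ≈ 0.22° per mm of |b − a|. A 4° discrepancy therefore
corresponds to roughly 18 mm of condyle–menton length asymmetry — the
angular criterion is deliberately tolerant, and much more tolerant than
the 5 mm millimetric criterion.

### Ratio systems and millimetric discrepancy

All 45 unordered-pair ratios among the 10 craniofacial distances are
computed (numerator = first in registry order, so orientation is
deterministic and the table is invertible). The printed source tables
for the published ratio subset are not machine-readable, so the full
45-pair closure is computed as a documented superset of any subset; a
configurable flag (default deviation > 0.10 from 1.0) marks entries
departing from the 1:1 symmetry ideal. The flag tolerance is an
artifact parameter, not a clinically validated band.

The 9 mandibular ratios follow their published naming exactly: five
left/right comparisons with the left side in the numerator (`R_Kr_Cd` =
KrL–CdL / KrR–CdR, …), two within-body ratios (DB side over Me side),
and two ramus-base over body-base ratios. Relabeling left as right
inverts the five L/R ratios and exchanges the side-specific ones — a
duality the tests exercise.

The millimetric test takes the absolute left–right differences of
Fz–Me, Go–N and Cd–Me and classifies the maximum against the threshold.

### Thresholds and conventions

- Semiangle threshold: 4°, **inclusive** (≤). Millimetric threshold:
  5 mm, inclusive. The source text for both criteria is ambiguous about
  strictness (a mangled comparison glyph); the inclusive reading was
  adopted and both thresholds are configuration-exposed, so the other
  convention is one flag away.
- Cohort standard deviation: sample convention (n−1 denominator) by
  default; the estimator used originally is unstated, so a
  population-sd option (`sd_ddof=0`) exists.
- Prevalence percentages are kept unrounded internally and rounded to
  two decimals only for display.

## Numerical choices

- Angles are computed from clamped cosines (`clip to [−1, 1]` before
  `arccos`), so collinear triples yield exactly 0°/180° instead of NaN.
- Degeneracy tolerance: landmark pairs closer than 1e-9 mm are treated
  as coincident — far below the 0.4 mm voxel, so only genuinely
  pathological input triggers it. Coincident pairs raise errors in
  analysis operations; a menton collinear with the inter-condylar line
  yields a *flagged* (not raised) semiangle result so cohort runs
  survive single pathological subjects. Flagged subjects are excluded
  from the semiangle prevalence and counted in `excluded_semiangle`.
- Incomplete landmark sets load fine but are refused by analysis with
  an explicit error naming the missing codes; silent NaN propagation
  would corrupt cohort percentages.
- Cohort aggregation sorts each column before reducing, making the
  summary exactly (bitwise) permutation invariant rather than merely
  approximately so.

## Synthetic cohorts

No landmark cohort is publicly deposited, so validation uses generated
data with known ground truth.

**Template.** A mirror-symmetric 12-landmark configuration across
x = 0 (right at +x), with fixed coordinates chosen so that all 21
distances lie in anatomically plausible adult ranges (40–130 mm;
inter-condylar width 100 mm, condyle–menton 118 mm, apex angle ≈ 50°).
The coordinates are artifact constants with no provenance from any
measured cohort.

**Deformations** (applied noise-free, in this order): per-side condylar
translation; rescaling of the Kr and Go offsets about the original
condyle position, re-attached to the displaced condyle (values < 1
shorten the ramus); lateral chin translation of Me along +x. Ground
truth (semiangle difference, max discrepancy) is computed on the
deformed geometry *before* noise.

**Noise.** Isotropic Gaussian noise, default sd 0.4 mm per landmark per
axis — the scanner voxel edge, since landmark placement cannot be
sub-voxel perfect. At this level the semiangle difference of a
symmetric subject scatters with sd ≈ 0.15° and the max discrepancy
averages ≈ 0.9 mm, both far inside the clinical thresholds.

**Cohort composition.** `generate_cohort(n, symmetric_fraction, ...)`
makes exactly `round(n × fraction)` undeformed subjects; the rest
receive a frank hemimandibular-elongation pattern: the chin deviates
toward one side while the contralateral condyle is displaced radially
away from the menton, both with magnitudes drawn uniformly from the
configured range, plus mild ipsilateral ramus shortening (scale
0.88–0.97). The default magnitude range is 12–20 mm — the scale of
marked clinical asymmetry — chosen from the sensitivity analysis above
so that the asymmetric class clears both thresholds by many multiples
of the noise-induced scatter and the design labels coincide with the
criterion decisions. One seeded generator stream drives all draws;
a fixed seed reproduces cohorts bit-for-bit.

**What the generator does not emulate.** Real anatomical covariance
(landmark positions vary jointly with skull size and shape), growth and
age structure, graded mild asymmetries near the thresholds, observer-
and landmark-specific digitization error, and any image-domain effects.
Passing tests show the *pipeline* is correct and well-conditioned at
realistic noise; they say nothing about clinical prevalence in real
populations, and the published cohort percentages are not reproducible
without the original patient data.

## Problem sizes

The validation suite uses 1000 random landmark sets for oracle
equivalence, 100–300 subjects per simulated cohort, and 60 replicates
for noise-scaling checks; the acceptance script uses a 300-subject
cohort. These sizes put binomial interval half-widths near 5 percentage
points and run in seconds.

## Known limitations

- The semiangle statistic's low angular sensitivity (≈ 0.2°/mm) means
  the 4° criterion tolerates large millimetric asymmetry; interpret it
  jointly with the 5 mm criterion.
- The 45-pair facial ratio table is a superset of the originally
  published ratio selection (recoverable only as an image); consumers
  wanting a subset should filter by the named pairs.
- FCSV input carries no subject identifier; one file = one subject,
  with the id supplied by the caller (the CLI uses the file stem).
- Landmark *definitions* (anatomical prose) are out of scope; the
  package treats codes as opaque identifiers and trusts upstream
  digitization.
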