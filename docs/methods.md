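# Methods

## The measurement model

The package quantifies how well one acetabulum, mirrored, reproduces its
contralateral counterpart. The comparison is purely geometric and assumes:

- both sides are given as triangle surface meshes in a common metric unit
  (millimetres; CT native scale, no unit conversion anywhere);
- ≥ 3 corresponding landmarks are available per side (non-collinear), with
  ordered correspondence;
- the articular surface of the mirrored side is delineated as a set of
  vertex indices (the ROI). Delineation is an input: the package does not
  segment or delineate.

The pipeline for one direction (LM2RO shown; RM2LO is symmetric):

1. *Mirroring.* The left surface is reflected across a plane. The plane
   defaults to x = 0; since the subsequent registration removes any rigid
   difference, the choice of plane is immaterial, and named coordinate
   planes are implemented as exact sign flips so that double mirroring is a
   bit-exact involution. Face winding is reversed so outward normals stay
   outward.
2. *Landmark pre-registration.* The least-squares rigid transform
   minimising Σ‖T(sᵢ) − tᵢ‖² is solved in closed form (SVD / Kabsch). The
   rotation is sign-corrected to det = +1: reflection can enter the
   pipeline only through the explicit mirroring step, never through a
   registration solve.
3. *ICP refinement.* Point-to-surface ICP: each iteration projects every
   ROI vertex of the (currently transformed) mirrored model onto its exact
   closest point of the full contralateral surface, optionally discards
   correspondences beyond `max_correspondence_distance` (default:
   unlimited; no trimming or robust weighting), solves the proper rigid
   least-squares update for the surviving pairs, and composes it into the
   running transform. Iteration stops when the RMS correspondence distance
   changes by less than `rms_change_tolerance` (default 1e-6 mm) or after
   `max_iterations` (default 100). With a fixed correspondence rule and no
   gating, the recorded RMS sequence is non-increasing (alternating
   minimisation), and this is asserted in tests.
4. *Distance map.* For every ROI vertex, the absolute Euclidean distance
   to the exact closest point over all target triangles, together with the
   attaining point and face. Distances are unsigned; no inside/outside
   sign is computed. Equidistant faces tie-break to the lowest face index,
   making output deterministic.

### Symmetry statistics

- Summary: mean, sample SD (n−1; a single-point map reports SD 0 with a
  warning), 95th percentile by linear interpolation between order
  statistics (`numpy.percentile` default — so 100 points 1..100 give
  95.05), and maximum.
- Threshold percentages: `100 · #{d < t}/n`, strictly smaller-than, at
  0.5 / 1.0 / 1.5 / 2.0 mm by default. A distance of exactly 0.5 mm is
  therefore *not* counted under t = 0.5.
- Matta grading of a mean displacement: ≤ 1 mm anatomical, (1, 3] mm
  imperfect, > 3 mm poor. The published grade names leave (1, 2) mm
  unnamed; mapping all of (1, 3] to imperfect makes the grading total.
  This is an interpretation and is flagged as such in the docstring.
- Agreement categories: half-open, lower-inclusive bins
  [0, 0.5), [0.5, 1), [1, 1.5), [1.5, 2), [2, ∞). The [1.5, 2) bin is
  included so the bins partition [0, ∞). 0.5 mm falls in "0.5–1".
- Direction comparison: pooled per-case means are first checked for
  normality with a Kolmogorov–Smirnov test against a normal distribution
  with the pooled sample's fitted moments (no Lilliefors correction; the
  convention is documented here precisely because several statistics
  packages differ). If normal at the chosen alpha, an unpaired equal-
  variance t test; otherwise a two-sided Mann–Whitney U test whose null
  distribution is enumerated exactly (all C(n₁+n₂, n₁) rank assignments,
  midranks for ties, two-sided p = twice the smaller tail capped at 1) for
  combined n ≤ 20, and normally approximated above. A constant pooled
  sample is routed to the rank test. Identical samples give p = 1 by the
  symmetry of the null.
- Assessor agreement: raw percentage of case-direction means falling in
  the same category for both assessors (no chance correction).

## Exact accelerated closest-point queries

Closest-point queries must equal an exhaustive scan over all faces — the
acceleration is required to be lossless. The implementation uses two
conservative bounds: the distance to the nearest target vertex is an upper
bound `u` on the closest-surface distance, and a face can contain the
closest point only if its centroid lies within `u + r_f` of the query,
where `r_f` is the face's circumradius. Candidate faces are gathered from
k-nearest-centroid queries (k = 24, escalating to 192, then an explicit
ball search for queries whose coverage the k-NN cannot certify), with
faces split into a bulk tier and a small large-circumradius tier so that a
few oversized triangles do not inflate every search ball. The per-pair
point-triangle distance (Voronoi-region case analysis) runs in a compiled
kernel shared by the accelerated and exhaustive paths, so both produce
identical floating-point results; tests assert exact agreement on random
mesh pairs, and an independent implementation (trimesh) is used as an
external cross-check.

## The phantom

Real paired CT surfaces cannot be shipped, so the generator produces the
study situation synthetically: a truncated hemispherical cup (sphere radius
25 mm — adult acetabulum scale; depth fraction 0.8, i.e. truncated at a
polar angle of ≈ 78.5°) surrounded by a 5 mm flat flange ring standing in
for surrounding pelvic bone. The articular ROI is the cup (pole to rim);
the flange belongs only to the registration target, mirroring the
articular-surface-vs-whole-model setup of a real case. Mesh layout is a UV
sphere: rings share the rim's azimuthal vertex count (target edge length
`mesh_resolution`, default 1 mm, at the rim), so vertex density increases
toward the pole.

Two deterministic shape features break rotational symmetry:

- *ellipticity* (default 6 % elongation along x): the oval cup mouth;
- *waviness* (default 4 % of radius, ≈ 1 mm): a smooth six-lobed azimuthal
  radius modulation with a polar twist, standing in for mm-scale bony
  surface irregularity.

These are not cosmetic. A surface of revolution leaves the rotation about
the cup axis unidentifiable, and point-to-surface ICP couples to that
degree of freedom only through surface asymmetry: with ellipticity alone
the azimuthal error of the recovered registration stalls around 0.5–1.4°,
while with the waviness included ICP recovers an injected misalignment to
~0.001° and ~2e-5 mm. Registration accuracy claims on near-rotationally-
symmetric phantoms would be meaningless.

The right cup is the exact mirror (across x = 0) of the generated left
before any perturbation, so perfect symmetry is available as ground truth.
Perturbations:

- *dilation_delta*: every ROI vertex of the left cup moved radially from
  the sphere centre by δ mm; non-ROI vertices blend over a 3 mm cosine
  falloff band.
- *patch defect*: vertices within an angular cap displaced toward the
  centre by depth × cosine taper (1 at the cap centre, 0 at the edge) —
  a localized erosion.
- *noise_sd*: isotropic Gaussian vertex jitter applied to each side with
  independent seeded streams. Noise models per-reconstruction segmentation
  error and therefore affects both sides; applying it to one side only
  would make the two registration directions systematically different (a
  clean vertex is closer to a jagged surface than vice versa — measured
  0.24 vs 0.15 mm mean on a 0.3 mm-noise phantom).
- *misalignment*: a rigid transform applied to the left mesh and its
  landmarks; the ground-truth registration for each direction is recorded
  (mirroring conjugates the transform for LM2RO).
- *landmark_jitter_sd*: per-assessor Gaussian jitter of the landmark
  coordinates, emulating manual picking; assessor k uses stream
  (seed, 1000+k), so two assessors share anatomy but not jitter.

All randomness flows from the required `seed`; generation is bit-exactly
reproducible.

### The synthetic cohort

`make_cohort` fixes the study conditions: 20 cases, per-case rigid
misalignment up to 5° / 3 mm, per-side noise 0.35 mm, landmark jitter
0.5 mm per assessor, true anatomical asymmetry |N(0, 0.2)| mm dilation, and
one case with a 1.5 mm / 20° lateral erosion patch (a visibly asymmetric
cup among otherwise healthy pairs). Cohort runs cap ICP at 40 iterations
with a 1e-5 mm RMS-change tolerance: under noise the summary statistics
are stable to < 2 % after ~25 iterations (measured 0.2512 / 0.2493 /
0.2452 mm mean at 25 / 40 / 100 iterations), and the cap keeps a full
20-case, two-assessor, both-directions run (80 registrations) to a few
minutes on one CPU.

What the phantom does *not* emulate: real acetabular anatomy (lunate
articular surface, fossa, notch), segmentation bias (noise here is
zero-mean and spatially white, real segmentation errors are correlated and
can be systematic), metal artefacts, and anatomically realistic landmark
placement error. Passing phantom tests therefore demonstrates correctness
of the geometry, registration and statistics machinery under known ground
truth — not clinical accuracy on patient data.

## Registration absorption of global dilations — a known property

A uniform radial dilation of the cup is *not* fully visible to the
pipeline: the displacement field δ·r̂ over a cup-shaped ROI has a large
rigid component, and the ICP stage — which legitimately re-minimises the
RMS distance — translates the dilated cup axially by ≈ 1.25 δ toward its
best seat. For a spherical cap of depth fraction 0.8 the optimum is
τ* = E[cos θ]/E[cos²θ] · δ ≈ 1.25 δ with residual mean E|1 − τ*cos θ| ≈
0.26 δ; the measured end-to-end means reproduce this (ratios 0.27, 0.27,
0.25 at δ = 0.25, 0.5, 1.0 mm), with the measured mean strictly increasing
in δ. No rigid-registration pipeline of this design can avoid the effect
on a cup-like ROI — blocking the axial drift would require target surface
overhanging the cup mouth. Consequences: (i) the measured mean understates
*global* size asymmetry by roughly a factor of 4, while *localized*
defects, which have a small rigid component, appear at nearly full depth
(a 2 mm-deep 15° patch raises the 95th percentile by ≈ 1.4 mm but the
median by ≈ 0.27 mm); (ii) the deformation-magnitude check against the
injected dilation is performed without registration (deform, then distance
map against the undeformed copy), where the construction is recovered
exactly (−0.73 mm erosion → 0.73 mm mean within sampling error).

## Numerical choices

- Vertex merging on STL read: exact coordinate match by default
  (merge_tolerance 0); a positive tolerance quantises coordinates onto a
  grid of that pitch (scanner exports sometimes jitter coordinates).
- Degenerate faces: repeated indices or area ≤ 1e-12 mm²; dropped by
  cleaning, rejected by the scalar point-triangle operation, skipped when
  building the surface index.
- Component cleaning threshold: face-connected components below
  `min_component_fraction` (default 0.01) of the largest component's face
  count are removed; artefact fragments are orders of magnitude smaller
  than the bone structure, and the parameter is exposed because the
  appropriate value is data-dependent.
- Landmark solver degeneracy: the centred source configuration must have
  second singular value > 1e-9 × the first (collinearity check).
- Rigid-transform invariants: orthogonality and determinant are validated
  to 1e-6 on input; solver outputs are re-orthonormalised to machine
  precision.
- ICP convergence: the stopping rule is RMS-change based, so a run may hit
  `max_iterations` without the `converged` flag while already
  being well inside any useful tolerance; the trace is returned for
  inspection. Recovery of a misalignment to < 0.5° needs a few hundred
  iterations on the default phantom because the azimuthal mode contracts
  slowly (~1.3 %/iteration at default waviness).
- Tie-breaks: equidistant target faces resolve to the lowest face index in
  both the accelerated and exhaustive paths.
- 0-based vertex indexing everywhere, including ROI files.

## Known limitations

- Rigid registration only; no similarity or deformable variant, so true
  size differences alias partially into the registration (see above).
- Point-to-surface distance is asymmetric (query → target); no Hausdorff
  or two-sided variant.
- The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and is capped at
  combined n = 20 (184 756 arrangements) before switching to the normal
  approximation.
- The phantom's pooled 95th percentile is reported over pooled points;
  per-case p95 values are also reported (mean over cases) since either
  convention is defensible for cohort tables.
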