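# mirrorsym

Contralateral mirror-symmetry assessment of 3D bone surface models.

In acetabular fracture surgery, the quality of the post-operative reduction
is graded by residual displacement (Matta's criteria: anatomical ≤ 1 mm,
imperfect 2–3 mm, poor > 3 mm). A CT-derived 3D model of the *healthy*
contralateral acetabulum, mirrored, can serve as a patient-specific template
for the fractured side — provided left and right acetabula really are
mirror images at the millimetre scale. `mirrorsym` implements the surface
comparison that quantifies this: given STL surface models of the left and
right acetabulum, corresponding landmarks and a delineation of the
articular surface, it

1. **mirrors** one side across a plane,
2. **pre-registers** the mirrored model to the contralateral original with
   a least-squares rigid fit of ≥ 3 corresponding landmarks (Kabsch/SVD,
   reflection excluded),
3. **refines** the alignment with an iterative-closest-point (ICP) scheme
   driven by the articular-surface vertices of the mirrored model, using
   exact point-to-surface correspondences against the full contralateral
   surface, and
4. computes a **distance map**: for every articular-surface vertex, the
   absolute Euclidean distance `d_i = min_{x ∈ target} ‖v_i − x‖` to the
   closest point of the contralateral surface.

Symmetry is summarised as the mean ± SD, 95th percentile and maximum of
`d_i`, and as tolerance-threshold surface percentages
`P(t) = 100 · #{d_i < t}/n` at t = 0.5, 1.0, 1.5, 2.0 mm, chosen to line up
with Matta's reduction thresholds. Both registration directions are
supported (LM2RO: left mirrored onto right original; RM2LO: the converse),
with a normality-gated two-sample test (Kolmogorov–Smirnov, then unpaired
t or exact Mann–Whitney U) comparing per-case means between directions, and
percentage agreement between assessors on categorised means.

Because patient CT surfaces cannot be redistributed, the package ships a
**synthetic phantom generator**: paired acetabular-cup meshes (truncated,
slightly elliptical, mm-scale wavy hemispherical cups with a flange) whose
asymmetry (global radial dilation, localized erosion patch, segmentation
noise) and rigid misalignment are known exactly, so every pipeline stage is
testable against ground truth.

Intended users: surgeons and researchers evaluating 3D reduction assessment,
and developers of surface-comparison pipelines who need a tested,
ground-truth-verifiable reference implementation.

## Worked example

```python
import numpy as np
from mirrorsym import (PhantomSpec, make_cup_pair, run_symmetry_case,
                       random_misalignment)

rng = np.random.default_rng(1)
spec = PhantomSpec(
    seed=21,
    mesh_resolution=1.0,          # mm target edge length
    dilation_delta=0.15,          # true left-right asymmetry, mm
    noise_sd=0.3,                 # per-side segmentation noise, mm
    landmark_jitter_sd=0.5,       # manual landmark variability, mm
    misalignment=random_misalignment(rng, 5.0, 3.0),
)
pair = make_cup_pair(spec)
res = run_symmetry_case(
    pair.left, pair.right,
    pair.landmarks_left, pair.landmarks_right,
    pair.roi_left, direction="LM2RO",
)
s, p = res.summary, res.profile
print(f"mean {s.mean_error:.3f} mm, SD {s.sd:.3f}, p95 {s.p95:.3f}")
for t, pct in zip(p.thresholds, p.surface_percent):
    print(f"  < {t:.1f} mm: {pct:.1f}%")
print("grade of mean:", res.grade.value)
```

Output:

```
mean 0.211 mm, SD 0.180, p95 0.562
  < 0.5 mm: 92.6%
  < 1.0 mm: 99.9%
  < 1.5 mm: 100.0%
  < 2.0 mm: 100.0%
grade of mean: anatomical
```

Reading: after mirroring, landmark pre-registration and ICP refinement, the
articular surfaces of this phantom pair differ by 0.211 mm on average;
92.6 % of articular-surface points deviate by less than 0.5 mm and
essentially all by less than 1.5 mm. A mean of 0.245 mm falls well inside
Matta's anatomical band (≤ 1 mm), i.e. this pair is symmetric enough to
serve as a mirrored template.

The same pipeline is available from the shell:

```bash
mirrorsym phantom --seed 21 --out phantom/        # write STL/CSV bundle
mirrorsym case --left phantom/left.stl --right phantom/right.stl \
    --landmarks-left phantom/landmarks_left.csv \
    --landmarks-right phantom/landmarks_right.csv \
    --roi phantom/roi_left.txt --direction LM2RO --out result/
mirrorsym cohort --manifest cohort.json --out report/
```

`mirrorsym case` writes the rigid transform (JSON), the per-vertex distance
map (CSV and colour-mappable PLY with a `distance_mm` vertex property) and
a summary JSON; `mirrorsym cohort` writes per-case, pooled,
cumulative-curve and direction-test CSVs.

## Notes

See `docs/methods.md` for the model, the phantom's construction, numerical
choices and known limitations — including why a *global* dilation is
partially absorbed by the rigid re-registration (the measured mean
understates a uniform radius change by roughly a factor of 4, while
*localized* defects appear at nearly full depth).
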