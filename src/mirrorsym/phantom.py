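"""Synthetic acetabular-cup phantoms with known ground truth.

Patient CT surfaces cannot be redistributed, so every pipeline stage is
exercised on generated cup pairs instead: a truncated, slightly elliptical
hemispherical cup (the articular surface) surrounded by a flat flange ring
standing in for the surrounding pelvic bone.  The right cup is the exact
mirror (across x = 0) of the left before any deformation; asymmetry
(global radial dilation, a localized erosion patch, vertex noise) and a
rigid misalignment are applied to the left side only and recorded, so the
registration and distance pipeline can be checked against ground truth.

A real acetabulum is far from a surface of revolution: its mouth is oval
and the subchondral bone surface undulates at the millimetre scale.  The
phantom reproduces both — a slight elliptical elongation of the cup along
x (default 6 %) and a smooth azimuthal radius waviness (default 1 mm
amplitude).  Besides realism, these features make the registration problem
well-posed: on an exactly rotationally symmetric cup the rotation about
the cup axis would be unidentifiable, and a surface-based refinement could
not be expected to recover it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import (
    LandmarkSet,
    MeshError,
    RegionOfInterest,
    TriangleMesh,
    write_landmarks,
    write_roi,
    write_stl,
)
from .registration import RigidTransform, mirror_mesh, mirror_points

__all__ = [
    "PatchDefect",
    "PhantomSpec",
    "CupPair",
    "make_cup_pair",
    "assessor_landmarks",
    "deform_radial",
    "deform_patch",
    "random_misalignment",
    "save_pair",
]


@dataclass
class PatchDefect:
    """A localized erosion: a spherical cap of vertices displaced inward.

    ``direction`` points from the cup centre toward the patch centre;
    ``depth_mm`` is the displacement at the centre, tapering with a cosine
    falloff to 0 at the cap edge.
    """

    direction: tuple = (0.0, 0.0, -1.0)
    angular_radius_deg: float = 15.0
    depth_mm: float = 2.0


@dataclass
class PhantomSpec:
    """Parameters of a synthetic cup pair.

    cup_radius
        Sphere radius of the cup in mm (default 25, adult acetabulum scale).
    cup_depth_fraction
        Fraction of the hemisphere depth kept; 0.8 truncates the cup at a
        polar angle of arccos(0.2) ≈ 78.5 degrees.
    rim_width
        Width (mm) of the flat flange ring around the cup mouth.
    mesh_resolution
        Target edge length (mm) at the cup rim.  Rings share the azimuthal
        vertex count of the rim (a UV-sphere layout), so vertices are
        denser toward the pole.
    ellipticity
        Relative elongation of the cup along x (see module docstring).
    waviness
        Relative amplitude of the smooth azimuthal radius modulation
        (six lobes with a polar twist); 0.04 of the cup radius ≈ 1 mm of
        bony surface irregularity at the default scale.
    dilation_delta
        Global radial dilation (mm) of the left articular surface;
        0 = perfectly symmetric pair.
    patch_defect
        Optional localized erosion on the left cup.
    misalignment
        Rigid transform applied to the left mesh and its landmarks.
    noise_sd
        SD (mm) of isotropic Gaussian jitter added to every left vertex.
    landmark_jitter_sd
        SD (mm) of jitter on the landmark coordinates, emulating manual
        assessor input; 0 gives exact landmarks.
    seed
        Required; all randomness flows from it.
    """

    seed: int
    cup_radius: float = 25.0
    cup_depth_fraction: float = 0.8
    rim_width: float = 5.0
    mesh_resolution: float = 1.0
    ellipticity: float = 0.06
    waviness: float = 0.04
    dilation_delta: float = 0.0
    patch_defect: PatchDefect | None = None
    misalignment: RigidTransform | None = None
    noise_sd: float = 0.0
    landmark_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.cup_radius <= 0:
            raise ValueError("cup_radius must be > 0")
        if not 0 < self.cup_depth_fraction <= 1:
            raise ValueError("cup_depth_fraction must be in (0, 1]")
        if self.mesh_resolution <= 0:
            raise ValueError("mesh_resolution must be > 0")
        if self.noise_sd < 0 or self.landmark_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GroundTruth:
    """What a perfect registration should recover, per direction."""

    transform_lm2ro: RigidTransform
    transform_rm2lo: RigidTransform
    dilation_delta: float
    patch_defect: PatchDefect | None
    noise_sd: float
    seed: int


@dataclass
class CupPair:
    left: TriangleMesh
    right: TriangleMesh
    landmarks_left: LandmarkSet
    landmarks_right: LandmarkSet
    roi_left: RegionOfInterest
    roi_right: RegionOfInterest
    ground_truth: GroundTruth
    # exact (unjittered) landmark coordinates, kept so further simulated
    # assessors can re-jitter the same anatomical points
    landmarks_left_exact: np.ndarray | None = None
    landmarks_right_exact: np.ndarray | None = None


def _build_cup(spec: PhantomSpec) -> tuple[TriangleMesh, np.ndarray, int]:
    """Canonical cup + flange mesh centred on the sphere centre (origin),
    pole toward -z, mouth opening toward +z.

    Returns (mesh, analytic landmark points, number of cup vertices).
    """
    r = spec.cup_radius
    theta_max = float(np.arccos(1.0 - spec.cup_depth_fraction))
    res = spec.mesh_resolution
    n_phi = int(round(2.0 * np.pi * r * np.sin(theta_max) / res))
    n_theta = int(round(r * theta_max / res))
    if n_phi * max(1, 2 * n_theta - 1) < 50:
        raise MeshError(
            "mesh_resolution too coarse to form a closed cup (< 50 faces)"
        )
    n_rim = max(1, int(round(spec.rim_width / res)))

    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi

    def modulation(theta, ph):
        # smooth azimuthal waviness (six lobes, twisted in theta), vanishing
        # at the pole so the apex stays regular
        return 1.0 + spec.waviness * np.sin(theta) ** 2 * np.cos(6.0 * ph + 2.0 * theta)

    verts = [np.array([[0.0, 0.0, -r]])]
    for i in range(1, n_theta + 1):
        th = theta_max * i / n_theta
        ri = r * modulation(th, phi)
        ring = np.column_stack(
            [
                ri * np.sin(th) * np.cos(phi),
                ri * np.sin(th) * np.sin(phi),
                -ri * np.cos(th),
            ]
        )
        verts.append(ring)
    n_cup_vertices = 1 + n_theta * n_phi

    rim_mod = modulation(theta_max, phi)
    rho_inner = r * np.sin(theta_max) * rim_mod
    z_rim = -r * np.cos(theta_max)
    for k in range(1, n_rim + 1):
        rho = rho_inner + spec.rim_width * k / n_rim
        ring = np.column_stack(
            [rho * np.cos(phi), rho * np.sin(phi), np.full(n_phi, z_rim)]
        )
        verts.append(ring)
    vertices = np.concatenate(verts)

    faces = []
    # pole fan; winding chosen so normals point away from the sphere centre
    first = 1
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([0, first + jn, first + j])
    # quad strips between consecutive rings (cup rings then flange rings)
    n_rings = n_theta + n_rim
    for i in range(n_rings - 1):
        a = 1 + i * n_phi
        b = 1 + (i + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([a + j, a + jn, b + j])
            faces.append([a + jn, b + jn, b + j])
    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64), provenance="phantom-cup")
    if mesh.n_faces < 50:
        raise MeshError("mesh_resolution too coarse to form a closed cup (< 50 faces)")

    # landmarks: 3 equidistant rim points + the pole (non-coplanar),
    # placed on the modulated surface
    lm_rows = []
    for a in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0):
        ra = r * float(modulation(theta_max, np.array([a]))[0])
        lm_rows.append(
            [
                ra * np.sin(theta_max) * np.cos(a),
                ra * np.sin(theta_max) * np.sin(a),
                -ra * np.cos(theta_max),
            ]
        )
    lm_rows.append([0.0, 0.0, -r])
    lm = np.array(lm_rows)

    # elliptical elongation along x (applied to mesh and landmarks alike)
    mesh.vertices[:, 0] *= 1.0 + spec.ellipticity
    lm[:, 0] *= 1.0 + spec.ellipticity
    return mesh, lm, n_cup_vertices


def deform_radial(
    mesh: TriangleMesh,
    roi: RegionOfInterest,
    delta: float,
    center=(0.0, 0.0, 0.0),
    falloff_band: float = 3.0,
) -> TriangleMesh:
    """Move every ROI vertex radially away from ``center`` by ``delta`` mm
    (negative = erosion).  Non-ROI vertices within ``falloff_band`` mm of
    the ROI are blended with a cosine falloff to avoid a cliff."""
    roi.validate(mesh)
    center = np.asarray(center, dtype=np.float64)
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    rel = mesh.vertices - center
    norms = np.linalg.norm(rel, axis=1)
    if (norms < 1e-9).any():
        raise MeshError("vertex coincident with the dilation center")
    radial = rel / norms[:, None]

    weight = np.zeros(mesh.n_vertices)
    weight[roi.vertex_indices] = 1.0
    outside = np.flatnonzero(weight == 0.0)
    if len(outside) and falloff_band > 0:
        tree = cKDTree(mesh.vertices[roi.vertex_indices])
        d, _ = tree.query(mesh.vertices[outside])
        w = np.where(d < falloff_band, 0.5 * (1.0 + np.cos(np.pi * d / falloff_band)), 0.0)
        weight[outside] = w

    out = mesh.copy()
    out.vertices = mesh.vertices + delta * weight[:, None] * radial
    out.provenance = f"{mesh.provenance}|dilated:{delta}"
    return out


def deform_patch(
    mesh: TriangleMesh,
    center_direction,
    angular_radius_deg: float,
    depth: float,
    center=(0.0, 0.0, 0.0),
) -> TriangleMesh:
    """Displace vertices within an angular cap inward (toward ``center``) by
    ``depth`` times a cosine taper: 1 at the cap centre, 0 at its edge."""
    if not 0 < angular_radius_deg < 90:
        raise ValueError("angular_radius_deg must be in (0, 90)")
    if not np.isfinite(depth):
        raise ValueError("depth must be finite")
    direction = np.asarray(center_direction, dtype=np.float64)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("center_direction must be non-zero")
    direction = direction / n
    center = np.asarray(center, dtype=np.float64)

    rel = mesh.vertices - center
    norms = np.linalg.norm(rel, axis=1)
    safe = np.maximum(norms, 1e-12)
    cosg = np.clip(rel @ direction / safe, -1.0, 1.0)
    gamma = np.arccos(cosg)
    gmax = np.deg2rad(angular_radius_deg)
    inside = gamma < gmax
    taper = np.zeros(mesh.n_vertices)
    taper[inside] = np.cos(0.5 * np.pi * gamma[inside] / gmax)

    radial = rel / safe[:, None]
    out = mesh.copy()
    out.vertices = mesh.vertices - depth * taper[:, None] * radial
    out.provenance = f"{mesh.provenance}|patch:{depth}mm@{angular_radius_deg}deg"
    return out


def random_misalignment(rng: np.random.Generator, max_angle_deg: float, max_translation_mm: float) -> RigidTransform:
    """A random proper rigid transform with rotation angle up to
    ``max_angle_deg`` and translation length up to ``max_translation_mm``."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.2, 1.0) * max_angle_deg
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    t = rng.uniform(0.2, 1.0) * max_translation_mm * t_dir
    return RigidTransform.from_rotvec_deg(axis, angle, t)


_MIRROR_X = np.diag([-1.0, 1.0, 1.0])


def make_cup_pair(spec: PhantomSpec) -> CupPair:
    """Generate a left/right cup pair with landmarks, ROIs and ground truth.

    The right cup is the exact mirror (across x = 0) of the canonical cup;
    dilation, the patch defect, vertex noise and the rigid misalignment are
    applied to the left only.  Generation is deterministic given the seed.
    """
    base, lm_base, n_cup = _build_cup(spec)
    roi_idx = np.arange(n_cup, dtype=np.int64)
    roi_left = RegionOfInterest(roi_idx, label="articular surface (left)")
    roi_right = RegionOfInterest(roi_idx.copy(), label="articular surface (right)")

    right = mirror_mesh(base, "x=0")
    right.provenance = "phantom-right"
    lm_right = mirror_points(lm_base, "x=0")

    left = base.copy()
    left.provenance = "phantom-left"
    if spec.dilation_delta != 0.0:
        left = deform_radial(left, roi_left, spec.dilation_delta)
    if spec.patch_defect is not None:
        left = deform_patch(
            left,
            spec.patch_defect.direction,
            spec.patch_defect.angular_radius_deg,
            spec.patch_defect.depth_mm,
        )
    if spec.noise_sd > 0:
        # segmentation noise affects EACH side's reconstruction independently;
        # the recorded shape asymmetry (dilation, patch) stays left-only
        rng_l = np.random.default_rng([spec.seed, 1])
        rng_r = np.random.default_rng([spec.seed, 2])
        left.vertices = left.vertices + rng_l.normal(0.0, spec.noise_sd, left.vertices.shape)
        right.vertices = right.vertices + rng_r.normal(0.0, spec.noise_sd, right.vertices.shape)
    lm_left = lm_base.copy()
    t_mis = spec.misalignment if spec.misalignment is not None else RigidTransform.identity()
    left.vertices = t_mis.apply(left.vertices)
    lm_left = t_mis.apply(lm_left)
    left.provenance = "phantom-left"

    lms_left, lms_right = assessor_landmarks(spec, lm_left, lm_right, assessor=1)

    # Ground truth: mirroring the misaligned left across x=0 conjugates the
    # misalignment, so LM2RO should recover M ∘ T⁻¹ ∘ M; RM2LO (clean right
    # mirrored back onto the misaligned left) should recover T itself.
    t_inv = t_mis.inverse()
    lm2ro = RigidTransform(
        _MIRROR_X @ t_inv.linear @ _MIRROR_X,
        _MIRROR_X @ t_inv.translation,
        proper=True,
    )
    truth = GroundTruth(
        transform_lm2ro=lm2ro,
        transform_rm2lo=t_mis,
        dilation_delta=spec.dilation_delta,
        patch_defect=spec.patch_defect,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    return CupPair(
        left, right, lms_left, lms_right, roi_left, roi_right, truth,
        landmarks_left_exact=lm_left, landmarks_right_exact=lm_right,
    )


def make_cohort(
    n_cases: int = 20,
    seed: int = 0,
    mesh_resolution: float = 1.0,
    noise_sd: float = 0.35,
    landmark_jitter_sd: float = 0.5,
    assessors: int = 2,
):
    """A synthetic study cohort emulating paired healthy acetabula.

    Each case is a cup pair with a random rigid misalignment (up to 5 deg /
    3 mm, the residual pose difference between two CT acquisitions), vertex
    noise on one side (segmentation noise), a small true anatomical
    asymmetry (|N(0, 0.2)| mm radial dilation), and jittered landmarks per
    assessor (manual input variability).  One case carries an additional
    localized erosion patch, emulating a subject with a visibly asymmetric
    lateral wall.

    Returns ``(cases, repeat_assessors)`` ready for
    :func:`mirrorsym.pipeline.run_cohort`; ``repeat_assessors`` is None when
    ``assessors < 2``.
    """
    from .pipeline import CaseInput

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng([seed, 777])
    cases = []
    repeat: dict = {}
    erosion_case = 10 if n_cases > 10 else n_cases - 1
    for i in range(n_cases):
        mis = random_misalignment(rng, 5.0, 3.0)
        dilation = float(abs(rng.normal(0.0, 0.2)))
        patch = None
        if i == erosion_case:
            patch = PatchDefect(direction=(0.6, 0.0, -0.8), angular_radius_deg=20.0, depth_mm=1.5)
        spec = PhantomSpec(
            seed=int(rng.integers(2**31)),
            mesh_resolution=mesh_resolution,
            dilation_delta=dilation,
            patch_defect=patch,
            misalignment=mis,
            noise_sd=noise_sd,
            landmark_jitter_sd=landmark_jitter_sd,
        )
        pair = make_cup_pair(spec)
        case_id = f"case{i:02d}"
        cases.append(
            CaseInput(
                case_id,
                pair.left,
                pair.right,
                pair.landmarks_left,
                pair.landmarks_right,
                pair.roi_left,
                pair.roi_right,
            )
        )
        if assessors >= 2:
            repeat[case_id] = assessor_landmarks(
                spec, pair.landmarks_left_exact, pair.landmarks_right_exact, assessor=2
            )
    return cases, (repeat or None)


def assessor_landmarks(
    spec: PhantomSpec,
    lm_left: np.ndarray,
    lm_right: np.ndarray,
    assessor: int = 1,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Landmark sets for one simulated assessor.

    With ``landmark_jitter_sd > 0`` each assessor perturbs the analytic
    landmark positions independently (seeded), emulating manual input
    variability; assessors share the same underlying anatomical points.
    """
    labels = ["rim_0", "rim_120", "rim_240", "pole"]
    left = np.asarray(lm_left, dtype=np.float64).copy()
    right = np.asarray(lm_right, dtype=np.float64).copy()
    if spec.landmark_jitter_sd > 0:
        rng = np.random.default_rng([spec.seed, 1000 + assessor])
        left = left + rng.normal(0.0, spec.landmark_jitter_sd, left.shape)
        right = right + rng.normal(0.0, spec.landmark_jitter_sd, right.shape)
    return LandmarkSet(left, labels=list(labels)), LandmarkSet(right, labels=list(labels))


def save_pair(pair: CupPair, outdir, dialect: str = "binary") -> dict:
    """Write STL pair, landmark CSVs, ROI files and a ground-truth manifest.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_stl(pair.left, out / "left.stl", dialect=dialect)
    write_stl(pair.right, out / "right.stl", dialect=dialect)
    write_landmarks(pair.landmarks_left, out / "landmarks_left.csv")
    write_landmarks(pair.landmarks_right, out / "landmarks_right.csv")
    write_roi(pair.roi_left, out / "roi_left.txt")
    write_roi(pair.roi_right, out / "roi_right.txt")
    gt = pair.ground_truth
    manifest = {
        "seed": gt.seed,
        "dilation_delta_mm": gt.dilation_delta,
        "noise_sd_mm": gt.noise_sd,
        "patch_defect": None if gt.patch_defect is None else asdict(gt.patch_defect),
        "transform_lm2ro": json.loads(gt.transform_lm2ro.to_json()),
        "transform_rm2lo": json.loads(gt.transform_rm2lo.to_json()),
        "files": {
            "left": "left.stl",
            "right": "right.stl",
            "landmarks_left": "landmarks_left.csv",
            "landmarks_right": "landmarks_right.csv",
            "roi_left": "roi_left.txt",
            "roi_right": "roi_right.txt",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
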