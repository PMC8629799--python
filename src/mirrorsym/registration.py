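"""Mirroring and rigid registration of contralateral surface models.

The workflow mirrors one side (reflection across a plane), pre-registers it
to the unmirrored counterpart with ≥3 corresponding landmarks (least-squares
proper rigid fit, Kabsch/SVD), and refines the alignment with an iterative
closest point (ICP) scheme using point-to-surface correspondences.  Both
solvers force a proper rotation (det = +1): reflection enters the pipeline
only through :func:`mirror_mesh`, never through registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .distance_map import SurfaceIndex
from .mesh_core import LandmarkSet, MeshError, TriangleMesh

__all__ = [
    "RigidTransform",
    "IcpParams",
    "IcpTrace",
    "RegistrationError",
    "mirror_mesh",
    "mirror_points",
    "apply_transform",
    "landmark_register",
    "icp_refine",
]

_ORTHO_TOL = 1e-9

_NAMED_PLANES = {"x=0": 0, "y=0": 1, "z=0": 2}


class RegistrationError(ValueError):
    """Raised for degenerate landmark configurations or failed ICP setups."""


@dataclass
class RigidTransform:
    """Orthogonal linear part + translation, with an explicit proper flag.

    ``proper`` is True iff det(linear) = +1 (a rotation); False marks a
    rotoreflection such as the mirroring operator.
    """

    linear: np.ndarray
    translation: np.ndarray
    proper: bool = True

    def __post_init__(self) -> None:
        self.linear = np.ascontiguousarray(self.linear, dtype=np.float64).reshape(3, 3)
        self.translation = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        self.validate()

    def validate(self) -> None:
        if not np.isfinite(self.linear).all() or not np.isfinite(self.translation).all():
            raise RegistrationError("non-finite transform")
        err = np.abs(self.linear.T @ self.linear - np.eye(3)).max()
        if err > 1e-6:
            raise RegistrationError(f"linear part is not orthogonal (|R'R - I| = {err:.2e})")
        det = np.linalg.det(self.linear)
        expected = 1.0 if self.proper else -1.0
        if abs(det - expected) > 1e-6:
            raise RegistrationError(
                f"det(linear) = {det:.6f} inconsistent with proper={self.proper}"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), proper=True)

    @classmethod
    def from_rotvec_deg(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (Rodrigues), then translation."""
        axis = np.asarray(axis, dtype=np.float64)
        n = np.linalg.norm(axis)
        if n == 0:
            raise RegistrationError("zero rotation axis")
        k = axis / n
        th = np.deg2rad(angle_deg)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)
        return cls(rot, np.asarray(translation, dtype=np.float64), proper=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.linear.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
            proper=(self.proper == other.proper),
        )

    def inverse(self) -> "RigidTransform":
        rt = self.linear.T
        return RigidTransform(rt, -rt @ self.translation, proper=self.proper)

    def rotation_angle_deg(self) -> float:
        """Rotation angle of a proper transform, in degrees."""
        if not self.proper:
            raise RegistrationError("rotation angle undefined for improper transform")
        c = (np.trace(self.linear) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path=None) -> str:
        payload = {
            "linear_row_major": [float(v) for v in self.linear.ravel()],
            "translation": [float(v) for v in self.translation],
            "proper": bool(self.proper),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RigidTransform":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            np.asarray(payload["linear_row_major"], dtype=np.float64).reshape(3, 3),
            np.asarray(payload["translation"], dtype=np.float64),
            proper=bool(payload["proper"]),
        )


@dataclass
class IcpParams:
    """ICP stopping rules and the optional correspondence-distance gate.

    The surface-matching description leaves the stopping rules open; these
    defaults run the refinement to numerical convergence.
    """

    max_iterations: int = 100
    rms_change_tolerance: float = 1e-6
    max_correspondence_distance: float = np.inf

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rms_change_tolerance <= 0:
            raise ValueError("rms_change_tolerance must be > 0")


@dataclass
class IcpTrace:
    """RMS correspondence distance per iteration (diagnostics)."""

    rms_per_iteration: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def _plane_reflection(plane) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Return (point, unit normal, axis) for a mirror plane.

    ``axis`` is set for the named coordinate planes, where the reflection is
    applied as an exact sign flip (an exact involution in floating point).
    """
    if isinstance(plane, str):
        if plane not in _NAMED_PLANES:
            raise ValueError(f"unknown mirror plane {plane!r}; use 'x=0', 'y=0', 'z=0' or (point, normal)")
        axis = _NAMED_PLANES[plane]
        normal = np.zeros(3)
        normal[axis] = 1.0
        return np.zeros(3), normal, axis
    point, normal = plane
    normal = np.asarray(normal, dtype=np.float64)
    n = np.linalg.norm(normal)
    if n == 0:
        raise ValueError("mirror plane normal must be non-zero")
    return np.asarray(point, dtype=np.float64), normal / n, None


def mirror_points(points: np.ndarray, plane="x=0") -> np.ndarray:
    """Reflect points across a plane ('x=0'/'y=0'/'z=0' or (point, normal))."""
    point, normal, axis = _plane_reflection(plane)
    pts = np.asarray(points, dtype=np.float64).copy()
    if axis is not None:
        pts[..., axis] = -pts[..., axis]
        return pts
    d = (pts - point) @ normal
    return pts - 2.0 * d[..., None] * normal


def mirror_mesh(mesh: TriangleMesh, plane="x=0") -> TriangleMesh:
    """Reflect a mesh across a plane, reversing face winding so outward
    normals stay outward.  Axis-aligned named planes use an exact sign flip,
    making double mirroring an exact involution."""
    vertices = mirror_points(mesh.vertices, plane)
    faces = mesh.faces[:, [0, 2, 1]].copy()
    return TriangleMesh(vertices, faces, provenance=f"mirrored|{mesh.provenance}")


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Apply a rigid (or mirroring) transform to every vertex; winding is
    reversed for improper transforms so normals remain outward."""
    transform.validate()
    vertices = transform.apply(mesh.vertices)
    faces = mesh.faces if transform.proper else mesh.faces[:, [0, 2, 1]]
    return TriangleMesh(vertices, faces.copy(), provenance=mesh.provenance)


def landmark_register(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Least-squares proper rigid transform mapping source landmarks onto
    target landmarks (point-based pre-registration).

    Ordered correspondence is assumed.  The rotation is solved with the
    SVD (Kabsch) construction and sign-corrected so no reflection or scaling
    can leak in.  Raises :class:`RegistrationError` for < 3 points or a
    collinear configuration.
    """
    src = source.points
    tgt = target.points
    if len(src) != len(tgt):
        raise RegistrationError("source and target landmark counts differ")
    if len(src) < 3:
        raise RegistrationError("at least 3 landmark pairs are required")
    src_mean = src.mean(axis=0)
    tgt_mean = tgt.mean(axis=0)
    src_c = src - src_mean
    tgt_c = tgt - tgt_mean
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise RegistrationError("degenerate (collinear) landmark configuration")
    h = src_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # re-orthonormalise to keep |R'R - I| at machine precision
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    t = tgt_mean - rot @ src_mean
    return RigidTransform(rot, t, proper=True)


def icp_refine(
    moving_region: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform,
    params: IcpParams | None = None,
) -> tuple[RigidTransform, IcpTrace]:
    """Refine ``init`` by iterative closest point on the articular region.

    Each iteration (a) finds, for every vertex of ``moving_region`` under
    the current transform, the exact closest point on the ``target``
    surface, discarding pairs beyond ``max_correspondence_distance``;
    (b) solves the least-squares proper rigid update for the surviving
    pairs; (c) composes it into the running transform.  Iteration stops when
    the RMS correspondence distance changes by less than
    ``rms_change_tolerance`` or ``max_iterations`` is reached.  The returned
    transform includes ``init``.
    """
    if params is None:
        params = IcpParams()
    if moving_region.n_vertices == 0:
        raise RegistrationError("empty moving region")
    init.validate()
    if not init.proper:
        raise RegistrationError("ICP initialisation must be a proper rigid transform")

    index = SurfaceIndex(target)
    pts0 = moving_region.vertices
    total = init
    trace = IcpTrace()
    prev_rms: float | None = None
    for _ in range(params.max_iterations):
        pts = total.apply(pts0)
        dist, closest, _ = index.query(pts)
        keep = dist <= params.max_correspondence_distance
        if not keep.any():
            raise RegistrationError(
                "no correspondences within max_correspondence_distance (no overlap)"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.rms_per_iteration.append(rms)
        trace.iterations_run += 1
        if prev_rms is not None and abs(prev_rms - rms) < params.rms_change_tolerance:
            trace.converged = True
            break
        prev_rms = rms
        step = landmark_register(LandmarkSet(pts[keep]), LandmarkSet(closest[keep]))
        total = step.compose(total)
    return total, trace
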