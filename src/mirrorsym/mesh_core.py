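"""Indexed triangle surface meshes and STL / landmark / ROI file handling.

STL files store an unindexed soup of triangles; :func:`read_stl` rebuilds
shared-vertex connectivity by merging duplicated corner points.  All
coordinates are millimetres (CT native unit) and all vertex indexing is
0-based, both in memory and in the plain-text ROI files.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TriangleMesh",
    "RegionOfInterest",
    "LandmarkSet",
    "STLFormatError",
    "MeshError",
    "read_stl",
    "write_stl",
    "clean_mesh",
    "extract_region",
    "read_roi",
    "write_roi",
    "read_landmarks",
    "write_landmarks",
]

_DEGENERATE_AREA_MM2 = 1e-12


class MeshError(ValueError):
    """Raised for structurally invalid meshes or regions."""


class STLFormatError(MeshError):
    """Raised when an STL file is missing, truncated or malformed.

    The message names the byte offset (binary) or line number (ASCII) at
    which parsing failed.
    """


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Counter-clockwise face winding (seen from outside) defines the outward
    normal.  ``vertex_map`` is populated by :func:`extract_region` and maps
    each vertex of the submesh back to its index in the parent mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""
    vertex_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        """Check the structural invariants, raising :class:`MeshError`."""
        if not np.isfinite(self.vertices).all():
            raise MeshError("non-finite vertex coordinates")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise MeshError("face index out of range")
        if self.n_faces:
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise MeshError("degenerate face with repeated vertex index")

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        """Normals recomputed from winding; file normals are never trusted."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            ln = np.linalg.norm(n, axis=1)
            ln[ln == 0.0] = 1.0
            n = n / ln[:, None]
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.provenance,
            None if self.vertex_map is None else self.vertex_map.copy(),
        )


@dataclass
class RegionOfInterest:
    """A set of vertex indices into a named mesh (e.g. the articular surface)."""

    vertex_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.vertex_indices, dtype=np.int64))
        self.vertex_indices = idx

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def validate(self, mesh: TriangleMesh) -> None:
        if len(self) == 0:
            raise MeshError("empty region of interest")
        if self.vertex_indices.min() < 0 or self.vertex_indices.max() >= mesh.n_vertices:
            raise MeshError("ROI vertex index out of range")


@dataclass
class LandmarkSet:
    """Ordered 3D points (mm) with optional labels; order defines correspondence."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("landmark points must be an (k, 3) array")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise MeshError("labels length must match points")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# STL reading / writing
# ---------------------------------------------------------------------------

def _merge_soup(corners: np.ndarray, merge_tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicated corner points of a triangle soup into shared vertices.

    With ``merge_tolerance == 0`` only bit-identical coordinates merge.  A
    positive tolerance quantises coordinates onto a grid of that pitch, which
    merges points whose coordinates jitter by less than roughly half a cell.
    """
    n_tri = len(corners) // 3
    if merge_tolerance > 0:
        keys = np.round(corners / merge_tolerance)
    else:
        keys = corners
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    inverse = inverse.reshape(-1)
    # representative coordinates: first occurrence of each key
    first = np.full(len(uniq), -1, dtype=np.int64)
    order = np.arange(len(corners))
    # reversed so the smallest original index wins
    first[inverse[::-1]] = order[::-1]
    vertices = corners[first]
    faces = inverse.reshape(n_tri, 3).astype(np.int64)
    return vertices, faces


def _read_stl_binary(raw: bytes, path: str) -> np.ndarray:
    if len(raw) < 84:
        raise STLFormatError(
            f"{path}: binary STL header truncated at byte {len(raw)} (need 84)"
        )
    (count,) = struct.unpack_from("<I", raw, 80)
    if count == 0:
        raise STLFormatError(f"{path}: zero triangles declared at byte 80")
    expected = 84 + 50 * count
    if len(raw) < expected:
        # which triangle record is incomplete
        tri_idx = (len(raw) - 84) // 50
        raise STLFormatError(
            f"{path}: truncated mid-triangle {tri_idx} at byte {len(raw)} "
            f"(expected {expected} bytes for {count} triangles)"
        )
    rec = np.dtype(
        [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
    )
    body = np.frombuffer(raw, dtype=rec, count=count, offset=84)
    return body["v"].reshape(-1, 3).astype(np.float64)


def _read_stl_ascii(raw: bytes, path: str) -> np.ndarray:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise STLFormatError(f"{path}: undecodable ASCII STL at byte {exc.start}") from exc
    corners: list[list[float]] = []
    in_solid = False
    for lineno, line in enumerate(io.StringIO(text), start=1):
        tokens = line.split()
        if not tokens:
            continue
        kw = tokens[0].lower()
        if kw == "solid":
            in_solid = True
        elif kw == "vertex":
            if len(tokens) != 4:
                raise STLFormatError(f"{path}: malformed vertex at line {lineno}")
            try:
                corners.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise STLFormatError(f"{path}: bad coordinate at line {lineno}") from exc
        elif kw == "endsolid":
            break
    if not in_solid:
        raise STLFormatError(f"{path}: missing 'solid' header at line 1")
    if not corners:
        raise STLFormatError(f"{path}: zero triangles")
    if len(corners) % 3 != 0:
        raise STLFormatError(
            f"{path}: truncated facet — {len(corners)} vertex lines is not a multiple of 3"
        )
    return np.asarray(corners, dtype=np.float64)


def _looks_ascii(raw: bytes) -> bool:
    if not raw.lstrip()[:5].lower() == b"solid":
        return False
    # Binary files sometimes start with 'solid' too; require an ASCII keyword
    # in the head of the file before committing to the text parser.
    return b"facet" in raw[:1024].lower() or b"endsolid" in raw[:1024].lower()


def read_stl(path, merge_tolerance: float = 0.0) -> TriangleMesh:
    """Read a binary or ASCII STL file into an indexed :class:`TriangleMesh`.

    Dialect is auto-detected.  Raw triangle corner points within
    ``merge_tolerance`` (mm) of each other are merged into shared vertices;
    the default 0 merges only exact coordinate matches.
    """
    if merge_tolerance < 0:
        raise ValueError("merge_tolerance must be >= 0")
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except FileNotFoundError:
        raise STLFormatError(f"{path}: file not found") from None
    if _looks_ascii(raw):
        corners = _read_stl_ascii(raw, str(path))
    else:
        corners = _read_stl_binary(raw, str(path))
    vertices, faces = _merge_soup(corners, merge_tolerance)
    mesh = TriangleMesh(vertices, faces, provenance=str(path))
    mesh.validate()
    return mesh


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL.  Binary output is exactly 84 + 50·n_faces bytes.

    Face normals are recomputed from winding.  Coordinates are stored as
    float32, the STL native precision.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    mesh.validate()
    tri = mesh.triangles().astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if dialect == "binary":
        with open(path, "wb") as fh:
            fh.write(b"mirrorsym binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", mesh.n_faces))
            rec = np.zeros(
                mesh.n_faces,
                dtype=np.dtype(
                    [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
                ),
            )
            rec["normal"] = normals
            rec["v"] = tri
            fh.write(rec.tobytes())
    else:
        name = mesh.provenance.replace("\n", " ") or "mesh"
        with open(path, "w", encoding="ascii") as fh:
            fh.write(f"solid {name}\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n")
                fh.write("  endfacet\n")
            fh.write(f"endsolid {name}\n")


# ---------------------------------------------------------------------------
# Cleaning and subsetting
# ---------------------------------------------------------------------------

def _drop_unreferenced(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces], used


def clean_mesh(mesh: TriangleMesh, min_component_fraction: float = 0.01) -> TriangleMesh:
    """Remove small disconnected fragments and degenerate faces.

    Face-connected components whose face count falls below
    ``min_component_fraction`` times the largest component's face count are
    dropped (artefact fragments, soft-tissue remnants).  The largest
    component is always kept.  Degenerate faces (repeated indices or area
    below 1e-12 mm²) are removed and unreferenced vertices pruned.
    """
    if not 0 <= min_component_fraction < 1:
        raise ValueError("min_component_fraction must be in [0, 1)")
    if mesh.n_faces == 0:
        raise MeshError("cannot clean an empty mesh")
    f = mesh.faces
    nondegenerate = (
        (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    )
    nondegenerate &= mesh.face_areas() > _DEGENERATE_AREA_MM2
    f = f[nondegenerate]
    if len(f) == 0:
        raise MeshError("mesh has no non-degenerate faces")

    # vertex connectivity through shared face edges
    nv = mesh.n_vertices
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nv, nv)
    )
    _, vlabel = connected_components(adj, directed=False)
    flabel = vlabel[f[:, 0]]
    labels, counts = np.unique(flabel, return_counts=True)
    largest = counts.max()
    keep_labels = labels[counts >= min_component_fraction * largest]
    f = f[np.isin(flabel, keep_labels)]

    vertices, faces, _ = _drop_unreferenced(mesh.vertices, f)
    out = TriangleMesh(vertices, faces, provenance=mesh.provenance)
    out.validate()
    return out


def extract_region(mesh: TriangleMesh, roi: RegionOfInterest) -> TriangleMesh:
    """Submesh of the faces whose three vertices all lie in ``roi``.

    Vertices are re-indexed; the mapping from new to original vertex indices
    is kept on the returned mesh as ``vertex_map`` (and named in
    ``provenance``).
    """
    roi.validate(mesh)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[roi.vertex_indices] = True
    keep = mask[mesh.faces].all(axis=1)
    if not keep.any():
        raise MeshError("ROI selects zero complete faces")
    vertices, faces, vmap = _drop_unreferenced(mesh.vertices, mesh.faces[keep])
    label = roi.label or "region"
    out = TriangleMesh(
        vertices,
        faces,
        provenance=f"{mesh.provenance}|extract:{label}",
        vertex_map=vmap,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# ROI and landmark files
# ---------------------------------------------------------------------------

def read_roi(path, label: str = "") -> RegionOfInterest:
    """Read a plain-text ROI file: one 0-based vertex index per line."""
    idx = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            try:
                idx.append(int(s))
            except ValueError:
                raise MeshError(f"{path}: bad vertex index at line {lineno}") from None
    return RegionOfInterest(np.asarray(idx, dtype=np.int64), label=label or str(path))


def write_roi(roi: RegionOfInterest, path) -> None:
    np.savetxt(path, roi.vertex_indices, fmt="%d")


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV with columns label,x,y,z (mm)."""
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise MeshError(f"{path}: landmark CSV missing columns {sorted(missing)}")
    return LandmarkSet(
        df[["x", "y", "z"]].to_numpy(dtype=np.float64),
        labels=[str(v) for v in df["label"]],
    )


def write_landmarks(lms: LandmarkSet, path) -> None:
    labels = lms.labels or [f"p{i}" for i in range(len(lms))]
    pd.DataFrame(
        {
            "label": labels,
            "x": lms.points[:, 0],
            "y": lms.points[:, 1],
            "z": lms.points[:, 2],
        }
    ).to_csv(path, index=False)
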