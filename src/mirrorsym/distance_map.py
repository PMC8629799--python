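"""Closest-point Euclidean distance maps between triangle surfaces.

For every query vertex the exact closest point over *all* target triangles
is found.  A KD-tree is used only to prune candidates: the nearest target
vertex gives an upper bound on the closest-surface distance, and every
triangle whose centroid lies within (bound + max triangle circumradius) is
then tested exactly, so the accelerated result equals the exhaustive scan.
Distances are unsigned (absolute); ties between equidistant faces resolve
to the lowest face index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from numba import njit

from .mesh_core import MeshError, RegionOfInterest, TriangleMesh

__all__ = [
    "DistanceMap",
    "SurfaceIndex",
    "point_triangle_distance",
    "surface_distance_map",
    "write_distance_csv",
    "write_distance_ply",
]

_DEGENERATE_AREA_MM2 = 1e-12


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised closest point on triangle (a, b, c) for each point p.

    Standard Voronoi-region case analysis (vertex / edge / interior) in
    barycentric form; exact for non-degenerate triangles.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~done
        out[m] = value[m] if value.shape == out.shape else value
        done[m] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    settle((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)

    # edge AC
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)

    # edge BC
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))

    # interior
    rest = ~done
    if rest.any():
        denom = va[rest] + vb[rest] + vc[rest]
        v = (vb[rest] / denom)[:, None]
        w = (vc[rest] / denom)[:, None]
        out[rest] = a[rest] + v * ab[rest] + w * ac[rest]
    return out


@njit(cache=True)
def _best_per_query(pts, qidx, fidx, face_orig, tri, nq):  # pragma: no cover - jitted
    """Running per-query minimum over candidate (point, triangle) pairs.

    Scalar closest-point-on-triangle (vertex / edge / interior Voronoi
    regions), with ties between exactly equidistant faces broken toward the
    lowest original face index.  Shared by the accelerated and exhaustive
    paths so both produce identical floating-point results.
    """
    best_d2 = np.full(nq, np.inf)
    best_face = np.full(nq, np.int64(2**62), dtype=np.int64)
    best_c = np.zeros((nq, 3))
    for t in range(qidx.shape[0]):
        qi = qidx[t]
        fi = fidx[t]
        px, py, pz = pts[qi, 0], pts[qi, 1], pts[qi, 2]
        ax, ay, az = tri[fi, 0, 0], tri[fi, 0, 1], tri[fi, 0, 2]
        bx, by, bz = tri[fi, 1, 0], tri[fi, 1, 1], tri[fi, 1, 2]
        cx, cy, cz = tri[fi, 2, 0], tri[fi, 2, 1], tri[fi, 2, 2]

        abx, aby, abz = bx - ax, by - ay, bz - az
        acx, acy, acz = cx - ax, cy - ay, cz - az
        apx, apy, apz = px - ax, py - ay, pz - az
        d1 = abx * apx + aby * apy + abz * apz
        d2 = acx * apx + acy * apy + acz * apz
        if d1 <= 0.0 and d2 <= 0.0:
            ox, oy, oz = ax, ay, az
        else:
            bpx, bpy, bpz = px - bx, py - by, pz - bz
            d3 = abx * bpx + aby * bpy + abz * bpz
            d4 = acx * bpx + acy * bpy + acz * bpz
            if d3 >= 0.0 and d4 <= d3:
                ox, oy, oz = bx, by, bz
            else:
                vc = d1 * d4 - d3 * d2
                if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                    v = d1 / (d1 - d3)
                    ox, oy, oz = ax + v * abx, ay + v * aby, az + v * abz
                else:
                    cpx, cpy, cpz = px - cx, py - cy, pz - cz
                    d5 = abx * cpx + aby * cpy + abz * cpz
                    d6 = acx * cpx + acy * cpy + acz * cpz
                    if d6 >= 0.0 and d5 <= d6:
                        ox, oy, oz = cx, cy, cz
                    else:
                        vb = d5 * d2 - d1 * d6
                        if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                            w = d2 / (d2 - d6)
                            ox, oy, oz = ax + w * acx, ay + w * acy, az + w * acz
                        else:
                            va = d3 * d6 - d5 * d4
                            if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
                                w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                ox = bx + w * (cx - bx)
                                oy = by + w * (cy - by)
                                oz = bz + w * (cz - bz)
                            else:
                                denom = 1.0 / (va + vb + vc)
                                v = vb * denom
                                w = vc * denom
                                ox = ax + v * abx + w * acx
                                oy = ay + v * aby + w * acy
                                oz = az + v * abz + w * acz
        dx, dy, dz = px - ox, py - oy, pz - oz
        dist2 = dx * dx + dy * dy + dz * dz
        fo = face_orig[fi]
        if dist2 < best_d2[qi] or (dist2 == best_d2[qi] and fo < best_face[qi]):
            best_d2[qi] = dist2
            best_face[qi] = fo
            best_c[qi, 0] = ox
            best_c[qi, 1] = oy
            best_c[qi, 2] = oz
    return best_d2, best_c, best_face


def point_triangle_distance(p, triangle) -> tuple[float, np.ndarray]:
    """Minimum distance from point ``p`` to the closed triangle, with the
    attaining point.  Raises :class:`MeshError` for degenerate triangles
    (area below 1e-12 mm²)."""
    p = np.asarray(p, dtype=np.float64).reshape(1, 3)
    tri = np.asarray(triangle, dtype=np.float64).reshape(3, 3)
    area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area <= _DEGENERATE_AREA_MM2:
        raise MeshError("degenerate triangle (area <= 1e-12 mm^2)")
    closest = _closest_on_triangles(p, tri[0:1], tri[1:2], tri[2:3])[0]
    return float(np.linalg.norm(p[0] - closest)), closest


@dataclass
class DistanceMap:
    """Per-query-vertex absolute closest-point distances to a target surface."""

    query_vertex_indices: np.ndarray
    distances: np.ndarray
    closest_points: np.ndarray
    target_face_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.distances)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_index": self.query_vertex_indices,
                "distance_mm": self.distances,
                "cx": self.closest_points[:, 0],
                "cy": self.closest_points[:, 1],
                "cz": self.closest_points[:, 2],
                "face_index": self.target_face_indices,
            }
        )


class SurfaceIndex:
    """Spatially indexed target surface supporting exact closest-point queries."""

    def __init__(self, target: TriangleMesh):
        if target.n_faces == 0:
            raise MeshError("empty target surface")
        target.validate()
        self.mesh = target
        areas = target.face_areas()
        self.face_ids = np.flatnonzero(areas > _DEGENERATE_AREA_MM2)
        if len(self.face_ids) == 0:
            raise MeshError("target surface has no non-degenerate faces")
        tri = target.triangles()[self.face_ids]
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        self._radii = np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max(axis=1)
        # bound tree over vertices of valid faces only, so the upper bound
        # always refers to a face that is actually searchable
        used = np.unique(target.faces[self.face_ids])
        self._vertex_tree = cKDTree(target.vertices[used])
        # Faces are split into a bulk tier and a small large-circumradius
        # tier, each searched with its own tier-wide radius bound: a single
        # oversized triangle would otherwise inflate every pruning ball.
        cut = np.quantile(self._radii, 0.95)
        self._tiers = []
        for sel in (self._radii <= cut, self._radii > cut):
            idx = np.flatnonzero(sel)
            if len(idx) == 0:
                continue
            self._tiers.append(
                (
                    idx,
                    cKDTree(self._centroids[idx]),
                    self._radii[idx],
                    float(self._radii[idx].max()),
                )
            )

    def _select(self, pts, qidx, fidx):
        """Per-query minimum distance, ties to the lowest original face index."""
        d2, closest, face = _best_per_query(
            pts,
            np.ascontiguousarray(qidx, dtype=np.int64),
            np.ascontiguousarray(fidx, dtype=np.int64),
            self.face_ids,
            self._tri,
            len(pts),
        )
        if (face >= 2**62).any():
            raise MeshError("internal error: query point with no candidate face")
        return np.sqrt(d2), closest, face

    _KNN = 24

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact closest point on the surface for each query point.

        Candidate triangles are every face whose centroid lies within
        (nearest-vertex distance + max triangle circumradius) of the query;
        that ball provably contains the closest face.  The k nearest
        centroids serve the common case; queries whose ball the k-NN cannot
        certify as covered fall back to an explicit ball search.

        Returns (distances, closest_points, face_indices).
        """
        pts = np.ascontiguousarray(points, dtype=np.float64)
        ub, _ = self._vertex_tree.query(pts)

        qidx: list[np.ndarray] = []
        fidx: list[np.ndarray] = []
        for tier_ids, tree, radii, max_radius in self._tiers:
            nf = len(tier_ids)
            bound = ub + max_radius + 1e-9
            rest = np.arange(len(pts))
            for k in (self._KNN, 8 * self._KNN):
                k = min(k, nf)
                dcent, icent = tree.query(pts[rest], k=k)
                dcent = dcent.reshape(len(rest), k)
                icent = icent.reshape(len(rest), k)
                covered = (dcent[:, -1] >= bound[rest]) | (k == nf)
                # a face can only attain the minimum if its centroid lies
                # within (upper bound + its own circumradius) of the query
                mask = dcent <= ub[rest, None] + radii[icent] + 1e-9
                mask[~covered] = False
                qi, kj = np.nonzero(mask)
                qidx.append(rest[qi])
                fidx.append(tier_ids[icent[qi, kj]])
                rest = rest[~covered]
                if len(rest) == 0 or k == nf:
                    rest = rest[:0]
                    break
            if len(rest):
                cand = tree.query_ball_point(pts[rest], bound[rest])
                counts = np.fromiter(
                    (len(c) for c in cand), dtype=np.int64, count=len(rest)
                )
                qidx.append(np.repeat(rest, counts))
                fidx.append(
                    tier_ids[np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])]
                    if counts.sum()
                    else np.empty(0, dtype=np.int64)
                )
        return self._select(pts, np.concatenate(qidx), np.concatenate(fidx))

    def query_exhaustive(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest point by scanning every face; the acceleration oracle."""
        pts = np.ascontiguousarray(points, dtype=np.float64)
        nf = len(self.face_ids)
        qidx = np.repeat(np.arange(len(pts)), nf)
        fidx = np.tile(np.arange(nf), len(pts))
        return self._select(pts, qidx, fidx)


def surface_distance_map(
    query: TriangleMesh,
    roi: RegionOfInterest,
    target: TriangleMesh,
    mode: str = "surface",
    exhaustive: bool = False,
) -> DistanceMap:
    """Distance map from the ROI vertices of ``query`` to the ``target`` surface.

    ``mode='surface'`` (default) measures to the closest point anywhere on
    the target triangles; ``mode='vertex'`` measures to the closest target
    vertex only (a diagnostic that overestimates on coarse meshes).
    """
    roi.validate(query)
    idx = roi.vertex_indices
    pts = query.vertices[idx]
    if mode == "vertex":
        tree = cKDTree(target.vertices)
        d, vi = tree.query(pts)
        return DistanceMap(idx, d, target.vertices[vi], np.full(len(idx), -1, dtype=np.int64))
    if mode != "surface":
        raise ValueError(f"unknown distance mode {mode!r}")
    index = SurfaceIndex(target)
    if exhaustive:
        d, c, f = index.query_exhaustive(pts)
    else:
        d, c, f = index.query(pts)
    return DistanceMap(idx, d, c, f)


def write_distance_csv(dmap: DistanceMap, path) -> None:
    """CSV export: vertex_index,distance_mm,cx,cy,cz,face_index."""
    dmap.to_dataframe().to_csv(path, index=False)


def write_distance_ply(dmap: DistanceMap, query: TriangleMesh, path) -> None:
    """ASCII PLY of the query mesh with a per-vertex scalar ``distance_mm``.

    Vertices outside the mapped region carry -1, so external viewers can
    grey them out (the excluded, non-articular surface).
    """
    scalar = np.full(query.n_vertices, -1.0)
    scalar[dmap.query_vertex_indices] = dmap.distances
    with open(path, "w", encoding="ascii") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {query.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float distance_mm\n")
        fh.write(f"element face {query.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v, s in zip(query.vertices, scalar):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {s:.6f}\n")
        for f in query.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
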