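"""Triangle-mesh container and geometry kernel.

All downstream geometry (guide design, phantom construction, error
simulation) runs on one minimal representation: vertices in millimetres
plus triangular faces.  The kernel provides the queries those modules
need — watertightness, enclosed volume, closest point / signed distance
(angle-weighted pseudonormal sign), surface sampling, geodesic distance
(heat method), and remeshing of implicit fields via marching cubes.

Meshes are treated as oriented 2-manifolds: a mesh flagged watertight has
every edge shared by exactly two faces, and outward orientation is the
convention under which the divergence-theorem volume is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "SurfaceMesh",
    "MeshQuery",
    "mesh_from_field",
    "sample_field",
    "make_box",
    "make_icosphere",
    "geodesic_distances",
    "farthest_point_indices",
]


def farthest_point_indices(points: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy max-min subset of ``n`` indices, seeded by a random start."""
    points = np.asarray(points, dtype=float)
    if n > len(points):
        raise ValueError("cannot pick more points than available")
    chosen = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


@dataclass
class SurfaceMesh:
    """Triangle mesh in millimetre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Indices into ``vertices``; counter-clockwise seen from outside for
        closed, outward-oriented solids.
    label : str, optional
        Semantic role (``"bone"``, ``"tumor"``, ``"guide"`` ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64).reshape(-1, 3))
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # ------------------------------------------------------------------
    # basic measures
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalized:
            ln = np.linalg.norm(n, axis=1, keepdims=True)
            ln[ln == 0] = 1.0
            n = n / ln
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalized=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length; zero-rows averaged over 1-ring)."""
        fn = self.face_normals(normalized=False)  # area weighting
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        ln = np.linalg.norm(vn, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        return vn / ln

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward-oriented closed meshes."""
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        t = self.triangles()
        w = self.face_areas()
        return (t.mean(axis=1) * w[:, None]).sum(axis=0) / w.sum()

    def solid_centroid(self) -> np.ndarray:
        """Centre of mass of the enclosed solid (uniform density).

        Signed-tetrahedron decomposition against the origin; valid for
        closed, consistently oriented meshes.
        """
        t = self.triangles()
        vols = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
        cents = t.sum(axis=1) / 4.0  # tet centroid with 4th vertex at origin
        V = vols.sum()
        if abs(V) < 1e-12:
            raise ValueError("mesh encloses no volume")
        return (cents * vols[:, None]).sum(axis=0) / V

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def extents(self) -> np.ndarray:
        b = self.bounds()
        return b[1] - b[0]

    # ------------------------------------------------------------------
    # topology
    # ------------------------------------------------------------------
    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0) if unique else e

    def edge_face_counts(self) -> tuple[np.ndarray, np.ndarray]:
        e = self.edges(unique=False)
        return np.unique(e, axis=0, return_counts=True)

    def is_watertight(self) -> bool:
        """True iff every edge is shared by exactly two faces (per component)."""
        if self.n_faces == 0:
            return False
        _, counts = self.edge_face_counts()
        return bool((counts == 2).all())

    def boundary_edges(self) -> np.ndarray:
        e, counts = self.edge_face_counts()
        return e[counts == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops along open boundaries."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        # orient boundary edges consistently with face winding
        directed = {}
        face_edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        bset = {tuple(x) for x in be}
        for a, b in face_edges:
            key = (a, b) if a < b else (b, a)
            if key in bset:
                # boundary edge appears in exactly one face; walk opposite
                # to the face direction so loops wind consistently
                directed[int(b)] = int(a)
        loops = []
        remaining = dict(directed)
        while remaining:
            start = next(iter(remaining))
            loop = [start]
            cur = remaining.pop(start)
            while cur != start and cur in remaining:
                loop.append(cur)
                cur = remaining.pop(cur)
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Sparse adjacency with edge lengths as weights."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        m = sparse.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        return m.tocsr()

    def face_connected_components(self) -> np.ndarray:
        """Component label per face (faces connected when they share an edge)."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        fidx = np.tile(np.arange(self.n_faces), 3)[order]
        es = e[order]
        same = (np.diff(es, axis=0) == 0).all(axis=1)
        a = fidx[:-1][same]
        b = fidx[1:][same]
        g = sparse.coo_matrix((np.ones(len(a)), (a, b)), shape=(self.n_faces, self.n_faces))
        _, labels = csgraph.connected_components(g, directed=False)
        return labels

    def submesh(self, face_mask: np.ndarray, label: str | None = None) -> "SurfaceMesh":
        """Extract the faces selected by ``face_mask``, compacting vertices."""
        f = self.faces[np.asarray(face_mask)]
        used, inv = np.unique(f, return_inverse=True)
        return SurfaceMesh(self.vertices[used], inv.reshape(-1, 3), label or self.label)

    # ------------------------------------------------------------------
    # transforms & editing
    # ------------------------------------------------------------------
    def transformed(self, transform) -> "SurfaceMesh":
        """Apply a :class:`~arguide.transforms.RigidTransform`."""
        return replace(self, vertices=transform.apply(self.vertices))

    def translated(self, offset) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, dtype=float))

    def flipped(self) -> "SurfaceMesh":
        """Reverse face winding (inward <-> outward orientation)."""
        return replace(self, faces=self.faces[:, ::-1].copy())

    def concatenated(self, other: "SurfaceMesh", label: str | None = None) -> "SurfaceMesh":
        return SurfaceMesh(
            np.vstack([self.vertices, other.vertices]),
            np.vstack([self.faces, other.faces + self.n_vertices]),
            label or self.label,
        )

    # ------------------------------------------------------------------
    # sampling
    # ------------------------------------------------------------------
    def sample_surface(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Area-uniform random points on the surface.

        Returns (points (n,3), face indices (n,)).
        """
        w = self.face_areas()
        probs = w / w.sum()
        fi = rng.choice(self.n_faces, size=n, p=probs)
        t = self.triangles()[fi]
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        pts = (1 - r1)[:, None] * t[:, 0] + (r1 * (1 - r2))[:, None] * t[:, 1] + (r1 * r2)[:, None] * t[:, 2]
        return pts, fi


# ----------------------------------------------------------------------
# closest point / signed distance
# ----------------------------------------------------------------------

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle to each query (Ericson's region test).

    p : (q, 3); tri : (q, 3, 3).  Returns (closest (q,3), barycentric (q,3)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    bary = np.zeros_like(p)
    done = np.zeros(len(p), dtype=bool)

    def setv(mask, pts, bar):
        m = mask & ~done
        out[m] = pts[m]
        bary[m] = bar[m]
        done[m] = True

    # vertex regions
    setv((d1 <= 0) & (d2 <= 0), a, np.tile([1.0, 0.0, 0.0], (len(p), 1)))
    setv((d3 >= 0) & (d4 <= d3), b, np.tile([0.0, 1.0, 0.0], (len(p), 1)))
    setv((d6 >= 0) & (d5 <= d6), c, np.tile([0.0, 0.0, 1.0], (len(p), 1)))

    # edge AB
    vc = d1 * d4 - d3 * d2
    v = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    pts = a + v[:, None] * ab
    setv(mask, pts, np.stack([1 - v, v, np.zeros_like(v)], axis=1))

    # edge AC
    vb = d5 * d2 - d1 * d6
    w = np.where(d2 - d6 == 0, 0.0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6))
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    pts = a + w[:, None] * ac
    setv(mask, pts, np.stack([1 - w, np.zeros_like(w), w], axis=1))

    # edge BC
    va = d3 * d6 - d5 * d4
    denom = (d4 - d3) + (d5 - d6)
    w2 = np.where(denom == 0, 0.0, (d4 - d3) / np.where(denom == 0, 1.0, denom))
    mask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    pts = b + w2[:, None] * (c - b)
    setv(mask, pts, np.stack([np.zeros_like(w2), 1 - w2, w2], axis=1))

    # interior
    denom2 = va + vb + vc
    denom2 = np.where(denom2 == 0, 1.0, denom2)
    v2 = vb / denom2
    w3 = vc / denom2
    pts = a + v2[:, None] * ab + w3[:, None] * ac
    setv(np.ones(len(p), dtype=bool), pts, np.stack([1 - v2 - w3, v2, w3], axis=1))
    return out, bary


class MeshQuery:
    """Accelerated closest-point and signed-distance queries on one mesh.

    Sign uses the angle-weighted pseudonormal of the closest feature
    (face, edge, or vertex), which is exact for watertight meshes.
    """

    _K = 8  # candidate triangles per query

    def __init__(self, mesh: SurfaceMesh):
        self.mesh = mesh
        t = mesh.triangles()
        self._tri = t
        self._centroid_tree = cKDTree(t.mean(axis=1))
        self._vertex_tree = cKDTree(mesh.vertices)
        # vertex -> incident faces map
        n = mesh.n_vertices
        order = np.argsort(mesh.faces.ravel(), kind="stable")
        vf_faces = (order // 3).astype(np.int64)
        starts = np.searchsorted(mesh.faces.ravel()[order], np.arange(n + 1))
        counts = np.diff(starts)
        maxdeg = int(min(counts.max(initial=1), 8))
        vf_pad = np.zeros((n, maxdeg), dtype=np.int64)
        vertex_of = np.repeat(np.arange(n), counts)
        pos = np.arange(len(vf_faces)) - starts[vertex_of]
        ok = pos < maxdeg
        # pad unused slots with the vertex's first incident face
        first = np.zeros(n, dtype=np.int64)
        has = counts > 0
        first[has] = vf_faces[starts[:-1][has]]
        vf_pad[:] = first[:, None]
        vf_pad[vertex_of[ok], pos[ok]] = vf_faces[ok]
        self._vf_pad = vf_pad
        self._face_normals = mesh.face_normals()
        self._pseudo = self._build_pseudonormals()

    def _build_pseudonormals(self):
        m = self.mesh
        fn = self._face_normals
        # edge pseudonormals: sum of adjacent face normals
        e_all = np.concatenate([m.faces[:, [0, 1]], m.faces[:, [1, 2]], m.faces[:, [2, 0]]])
        e_sorted = np.sort(e_all, axis=1)
        uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
        edge_n = np.zeros((len(uniq), 3))
        face_of_edge = np.tile(np.arange(m.n_faces), 3)
        np.add.at(edge_n, inv, fn[face_of_edge])
        # vertex pseudonormals: angle-weighted face normals
        t = self._tri
        vert_n = np.zeros((m.n_vertices, 3))
        for k in range(3):
            u = t[:, (k + 1) % 3] - t[:, k]
            v = t[:, (k + 2) % 3] - t[:, k]
            cu = u / np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-30)
            cv = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-30)
            ang = np.arccos(np.clip(np.einsum("ij,ij->i", cu, cv), -1.0, 1.0))
            np.add.at(vert_n, m.faces[:, k], fn * ang[:, None])
        edge_key = {tuple(e): i for i, e in enumerate(map(tuple, uniq))}
        return {"edge_normals": edge_n, "edge_key": edge_key, "vertex_normals": vert_n}

    def _candidates(self, points: np.ndarray) -> np.ndarray:
        k = min(self._K, self.mesh.n_faces)
        _, fi = self._centroid_tree.query(points, k=k)
        fi = fi.reshape(len(points), -1)
        if self.mesh.n_faces <= self._K:
            return fi  # already exhaustive
        _, vi = self._vertex_tree.query(points)
        return np.hstack([fi, self._vf_pad[np.atleast_1d(vi)]])

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Returns (distance, closest point, face index, barycentric) per query."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        nq = len(points)
        best_d = np.full(nq, np.inf)
        best_p = np.zeros((nq, 3))
        best_f = np.zeros(nq, dtype=np.int64)
        best_b = np.zeros((nq, 3))
        fi = self._candidates(points)
        for col in range(fi.shape[1]):
            f = fi[:, col]
            cp, bb = _closest_on_triangles(points, self._tri[f])
            d = np.linalg.norm(points - cp, axis=1)
            m = d < best_d
            best_d[m] = d[m]
            best_p[m] = cp[m]
            best_f[m] = f[m]
            best_b[m] = bb[m]
        return best_d, best_p, best_f, best_b

    def signed_distance(self, points: np.ndarray, chunk: int = 65536) -> np.ndarray:
        """Signed distance, negative inside (watertight, outward-oriented mesh)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(points))
        for s in range(0, len(points), chunk):
            blk = points[s : s + chunk]
            d, cp, f, b = self.closest(blk)
            normal = self._feature_normal(f, b)
            sign = np.sign(np.einsum("ij,ij->i", blk - cp, normal))
            sign[sign == 0] = 1.0
            out[s : s + chunk] = d * sign
        return out

    def _feature_normal(self, f: np.ndarray, b: np.ndarray) -> np.ndarray:
        eps = 1e-9
        faces = self.mesh.faces[f]
        normal = self._face_normals[f].copy()
        nzero = (b < eps).sum(axis=1)
        # edge feature: one barycentric coordinate ~ 0
        em = nzero == 1
        if em.any():
            idx = np.where(em)[0]
            zi = np.argmin(b[idx], axis=1)
            key = self._pseudo["edge_key"]
            en = self._pseudo["edge_normals"]
            for j, z in zip(idx, zi):
                vv = np.delete(faces[j], z)
                k = (int(vv.min()), int(vv.max()))
                if k in key:
                    normal[j] = en[key[k]]
        # vertex feature: two barycentric coordinates ~ 0
        vm = nzero >= 2
        if vm.any():
            idx = np.where(vm)[0]
            vi = np.argmax(b[idx], axis=1)
            normal[idx] = self._pseudo["vertex_normals"][faces[idx, vi]]
        return normal

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) < 0


# ----------------------------------------------------------------------
# implicit fields <-> meshes
# ----------------------------------------------------------------------

def sample_field(sdf, bounds: np.ndarray, pitch: float, pad: float = 2.0):
    """Sample a callable signed-distance field on a regular grid.

    Returns (field (nx,ny,nz), origin (3,)).  ``bounds`` is (2, 3); the
    grid extends ``pad`` mm beyond it so the zero level set is closed.
    """
    lo = np.asarray(bounds[0], dtype=float) - pad
    hi = np.asarray(bounds[1], dtype=float) + pad
    # tiny irrational shift avoids grid nodes landing exactly on the surface
    lo = lo - pitch * np.array([0.0314, 0.0271, 0.0173])
    ns = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    axes = [lo[k] + pitch * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    vals = sdf(pts).reshape(ns)
    return vals, lo


def mesh_from_field(field: np.ndarray, origin: np.ndarray, pitch: float, level: float = 0.0,
                    label: str | None = None) -> SurfaceMesh:
    """Marching-cubes extraction of the ``level`` iso-surface, outward-oriented.

    Negative field values are inside.
    """
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=(pitch, pitch, pitch))
    m = SurfaceMesh(verts + np.asarray(origin, dtype=float), faces, label)
    if m.signed_volume() < 0:
        m = m.flipped()
    return m


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def make_box(extents: Sequence[float], center: Sequence[float] = (0.0, 0.0, 0.0),
             label: str | None = None) -> SurfaceMesh:
    """Axis-aligned box (12 triangles, outward-oriented)."""
    e = np.asarray(extents, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
    v = corners * e + c
    # index (sx, sy, sz) with bits: x*4 + y*2 + z
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
        (1, 5, 7, 3),  # +z
    ]
    faces = []
    for a, b, cc, d in quads:
        faces.append([a, b, cc])
        faces.append([a, cc, d])
    m = SurfaceMesh(v, np.array(faces), label)
    if m.signed_volume() < 0:
        m = m.flipped()
    return m


def make_icosphere(radius: float = 1.0, subdivisions: int = 3,
                   center: Sequence[float] = (0.0, 0.0, 0.0), label: str | None = None) -> SurfaceMesh:
    """Geodesic sphere by icosahedron subdivision; watertight, outward-oriented."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}
        verts = list(v)
        new_faces = []

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                p = (verts[i] + verts[j]) / 2
                p = p / np.linalg.norm(p)
                midpoint[key] = len(verts)
                verts.append(p)
            return midpoint[key]

        for a, b, c in f:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_faces)
    m = SurfaceMesh(v * radius + np.asarray(center, dtype=float), f, label)
    if m.signed_volume() < 0:
        m = m.flipped()
    return m


# ----------------------------------------------------------------------
# geodesic distance (heat method)
# ----------------------------------------------------------------------

def _cotan_laplacian(mesh: SurfaceMesh) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Weak cotangent Laplacian (positive semi-definite) and lumped vertex areas."""
    t = mesh.triangles()
    f = mesh.faces
    n = mesh.n_vertices
    I, J, W = [], [], []
    areas = mesh.face_areas()
    varea = np.zeros(n)
    for k in range(3):
        np.add.at(varea, f[:, k], areas / 3.0)
    for k in range(3):
        i = f[:, (k + 1) % 3]
        j = f[:, (k + 2) % 3]
        o = f[:, k]
        u = t[:, (k + 1) % 3] - t[:, k]
        v = t[:, (k + 2) % 3] - t[:, k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-30)
        I += [i, j]
        J += [j, i]
        W += [0.5 * cot, 0.5 * cot]
    I = np.concatenate(I)
    J = np.concatenate(J)
    W = np.concatenate(W)
    Wm = sparse.coo_matrix((W, (I, J)), shape=(n, n)).tocsr()
    L = sparse.diags(np.asarray(Wm.sum(axis=1)).ravel()) - Wm
    return L.tocsr(), varea


def geodesic_distances(mesh: SurfaceMesh, source_vertex: int) -> np.ndarray:
    """Geodesic distance from one vertex to all vertices (heat method).

    Falls back to Dijkstra edge-graph distances when the linear solves fail
    (degenerate triangulations).  Vertices in other connected components
    get ``inf``.
    """
    adj = mesh.vertex_adjacency()
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    reachable = comp == comp[source_vertex]
    try:
        phi = _heat_geodesic(mesh, source_vertex)
    except Exception:
        phi = csgraph.dijkstra(adj, indices=source_vertex)
    phi = np.asarray(phi, dtype=float)
    phi[~reachable] = np.inf
    return phi


def _heat_geodesic(mesh: SurfaceMesh, source: int) -> np.ndarray:
    L, varea = _cotan_laplacian(mesh)
    e = mesh.edges()
    h = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean()
    tstep = h * h
    M = sparse.diags(varea)
    A = (M + tstep * L).tocsc()
    rhs = np.zeros(mesh.n_vertices)
    rhs[source] = 1.0
    u = factorized(A)(rhs)

    # per-face normalized negative gradient of u
    t = mesh.triangles()
    f = mesh.faces
    fn = mesh.face_normals()
    areas = np.maximum(mesh.face_areas(), 1e-30)
    grad = np.zeros((mesh.n_faces, 3))
    for k in range(3):
        # edge opposite vertex k, rotated into the triangle plane
        ei = t[:, (k + 2) % 3] - t[:, (k + 1) % 3]
        grad += u[f[:, k], None] * np.cross(fn, ei)
    grad /= (2.0 * areas)[:, None]
    gn = np.linalg.norm(grad, axis=1, keepdims=True)
    X = -grad / np.maximum(gn, 1e-30)

    # integrated divergence per vertex
    div = np.zeros(mesh.n_vertices)
    for k in range(3):
        i = f[:, k]
        e1 = t[:, (k + 1) % 3] - t[:, k]
        e2 = t[:, (k + 2) % 3] - t[:, k]
        opp = t[:, (k + 2) % 3] - t[:, (k + 1) % 3]
        # cotangents of the angles opposite e1 and e2
        u1 = -e2
        v1 = -opp
        cot1 = np.einsum("ij,ij->i", u1, v1) / np.maximum(np.linalg.norm(np.cross(u1, v1), axis=1), 1e-30)
        u2 = -e1
        v2 = opp
        cot2 = np.einsum("ij,ij->i", u2, v2) / np.maximum(np.linalg.norm(np.cross(u2, v2), axis=1), 1e-30)
        np.add.at(div, i, 0.5 * (cot1 * np.einsum("ij,ij->i", e1, X) + cot2 * np.einsum("ij,ij->i", e2, X)))

    Areg = (L + 1e-10 * sparse.identity(mesh.n_vertices)).tocsc()
    phi = factorized(Areg)(div)
    phi = phi - phi[source]
    return np.abs(phi)
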