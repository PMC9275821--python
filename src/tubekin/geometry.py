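"""Core mesh geometry for tube-like epithelial surfaces.

A midgut-like organ surface is represented as an oriented triangle mesh of a
topological cylinder carrying a per-vertex chart ``(s, phi)``: ``s`` is a
longitudinal (anterior-posterior) coordinate and ``phi`` a periodic
circumferential angle.  All operators here follow one sign convention:

* face windings are chosen so normals point *inward*, toward the lumen;
* consequently the mean curvature ``H`` is positive on a cylinder
  (``H = 1/2R``) and negative in sharp neck regions whose axial curvature
  exceeds the circumferential one;
* normal velocities measured against these normals are positive for inward
  (constricting) motion.

Lengths are in micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TubeSurface",
    "SurfaceSequence",
    "Centerline",
    "MeshTopologyError",
    "DegenerateFaceError",
    "cotangent_laplacian",
    "vertex_areas",
    "face_areas",
    "face_normals",
    "vertex_normals",
    "mean_curvature",
    "surface_area",
    "enclosed_volume",
    "boundary_loops",
    "centerline",
    "harmonic_cylinder_chart",
    "tangent_directions",
    "face_chart_coords",
]


class MeshTopologyError(ValueError):
    """The mesh does not have the topology an operation requires."""


class DegenerateFaceError(ValueError):
    """Zero-area or chart-degenerate triangles block an operation."""


@dataclass
class TubeSurface:
    """Oriented triangle mesh of a topological cylinder with an (s, phi) chart.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in micrometres.
    faces : (m, 3) int array
        Triangle vertex indices, wound so that face normals point inward.
    s : (n,) float array, optional
        Longitudinal chart coordinate per vertex.
    phi : (n,) float array, optional
        Circumferential chart coordinate per vertex, periodic with period 2*pi.
    seam : (k, 2) int array, optional
        Pairs of vertex indices identified across the branch cut, when the
        chart was produced by cutting the cylinder open.
    """

    vertices: np.ndarray
    faces: np.ndarray
    s: np.ndarray | None = None
    phi: np.ndarray | None = None
    seam: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.s is not None:
            self.s = np.asarray(self.s, dtype=float)
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def has_chart(self) -> bool:
        return self.s is not None and self.phi is not None

    def require_chart(self) -> None:
        if not self.has_chart:
            raise ValueError("surface has no (s, phi) chart; chart required")

    def with_vertices(self, vertices: np.ndarray) -> "TubeSurface":
        """Same connectivity and chart, new embedding."""
        return replace(self, vertices=np.asarray(vertices, dtype=float))

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + self.n_faces

    def validate(self) -> None:
        """Check manifoldness, consistent orientation, and cylinder topology."""
        edges = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        key = np.sort(edges, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        if counts.max() > 2:
            raise MeshTopologyError("non-manifold edge (shared by >2 faces)")
        # consistent orientation: every interior edge appears once per direction
        directed = {}
        for a, b in edges:
            directed[(a, b)] = directed.get((a, b), 0) + 1
        if max(directed.values()) > 1:
            raise MeshTopologyError("inconsistent face orientation")
        loops = boundary_loops(self.faces)
        if len(loops) not in (0, 2):
            raise MeshTopologyError(
                f"expected 0 or 2 boundary loops, found {len(loops)} "
                f"(Euler characteristic {self.euler_characteristic()})"
            )


@dataclass
class SurfaceSequence:
    """Time series of surfaces sharing vertex identity (Lagrangian frames).

    ``surfaces[k].vertices[i]`` is the same material point for every ``k``.
    Timestamps are in minutes.
    """

    surfaces: list[TubeSurface]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(len(self.surfaces), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.surfaces):
            raise ValueError("times and surfaces length mismatch")
        n = {s.n_vertices for s in self.surfaces}
        if len(n) > 1:
            raise ValueError("vertex count must be constant over time")

    def __len__(self) -> int:
        return len(self.surfaces)

    def __getitem__(self, k: int) -> TubeSurface:
        return self.surfaces[k]

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class Centerline:
    """Ordered centerline points (one per hoop) and polyline length (um)."""

    points: np.ndarray
    length: float


# ---------------------------------------------------------------------------
# elementary measures


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit face normals following the winding (inward for valid surfaces)."""
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    n = np.cross(v1 - v0, v2 - v0)
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms <= 0):
        bad = np.flatnonzero(norms <= 0)
        raise DegenerateFaceError(f"zero-area faces at indices {bad[:10].tolist()}")
    return n / norms[:, None]


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric vertex areas (one third of incident triangle areas)."""
    fa = face_areas(vertices, faces)
    va = np.zeros(len(vertices))
    np.add.at(va, faces.ravel(), np.repeat(fa / 3.0, 3))
    return va


def vertex_areas_mixed(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Meyer mixed (Voronoi-safe) vertex areas.

    Voronoi weights on non-obtuse triangles; obtuse triangles contribute half
    their area to the obtuse corner and a quarter to the others.  Pairs with
    the cotangent Laplacian for pointwise curvature estimates (barycentric
    areas bias low-valence vertices, e.g. the twelve icosahedral vertices of
    a subdivided sphere).
    """
    fa = face_areas(vertices, faces)
    va = np.zeros(len(vertices))
    corners = [vertices[faces[:, k]] for k in range(3)]
    cots = []
    for k in range(3):
        u = corners[(k + 1) % 3] - corners[k]
        v = corners[(k + 2) % 3] - corners[k]
        cots.append(np.einsum("ij,ij->i", u, v) / (2.0 * fa))
    cots = np.stack(cots, axis=1)  # cot of angle at corner k
    obtuse = cots < 0  # (m, 3)
    any_obtuse = obtuse.any(axis=1)
    for k in range(3):
        e1 = corners[(k + 1) % 3] - corners[k]
        e2 = corners[(k + 2) % 3] - corners[k]
        voronoi = (
            np.einsum("ij,ij->i", e1, e1) * cots[:, (k + 2) % 3]
            + np.einsum("ij,ij->i", e2, e2) * cots[:, (k + 1) % 3]
        ) / 8.0
        fallback = np.where(obtuse[:, k], fa / 2.0, fa / 4.0)
        np.add.at(va, faces[:, k], np.where(any_obtuse, fallback, voronoi))
    return va


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = face_normals(vertices, faces)
    fa = face_areas(vertices, faces)
    vn = np.zeros_like(vertices)
    w = (fn * fa[:, None])
    for k in range(3):
        np.add.at(vn, faces[:, k], w)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    return vn / norms[:, None]


def cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sp.csr_matrix:
    """Cotangent-weighted Laplace-Beltrami operator (negative semidefinite).

    Off-diagonal weight ``w_ij = (cot a + cot b)/2``; rows sum to zero.
    Degenerate triangles are rejected.
    """
    fa = face_areas(vertices, faces)
    if np.any(fa <= 1e-14):
        bad = np.flatnonzero(fa <= 1e-14)
        raise DegenerateFaceError(f"zero-area faces at indices {bad[:10].tolist()}")
    ii, jj, ww = [], [], []
    for k in range(3):
        i = faces[:, k]
        j = faces[:, (k + 1) % 3]
        opp = faces[:, (k + 2) % 3]
        u = vertices[i] - vertices[opp]
        v = vertices[j] - vertices[opp]
        cot = np.einsum("ij,ij->i", u, v) / (2.0 * fa)
        ii.append(i)
        jj.append(j)
        ww.append(0.5 * cot)
    i = np.concatenate(ii + jj)
    j = np.concatenate(jj + ii)
    w = np.concatenate(ww + ww)
    n = len(vertices)
    L = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L.tocsr()


def boundary_vertex_mask(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    mask = np.zeros(n_vertices, dtype=bool)
    for loop in boundary_loops(faces):
        mask[loop] = True
    return mask


def mean_curvature(surface: TubeSurface) -> np.ndarray:
    """Per-vertex mean curvature H (1/um), positive on a cylinder.

    Uses the discrete Laplace-Beltrami of the embedding, ``Laplace(X) = 2 H n``,
    projected on the inward vertex normal.  Values on boundary vertices are
    one-sided and unreliable; mask them for quantitative use.
    """
    V, F = surface.vertices, surface.faces
    L = cotangent_laplacian(V, F)
    A = vertex_areas_mixed(V, F)
    lap = (L @ V) / A[:, None]
    n_in = vertex_normals(V, F)
    return 0.5 * np.einsum("ij,ij->i", lap, n_in)


def surface_area(surface: TubeSurface) -> float:
    """Total surface area (um^2): sum of triangle areas."""
    return float(face_areas(surface.vertices, surface.faces).sum())


def enclosed_volume(surface: TubeSurface) -> float:
    """Enclosed volume (um^3) via the divergence theorem.

    Open boundary loops are capped by fan triangulation to their centroids
    before integrating; the result is reported positive.
    """
    V = surface.vertices
    F = surface.faces
    loops = boundary_loops(F)
    verts = [V]
    tris = [F]
    n = len(V)
    for loop in loops:
        c = V[loop].mean(axis=0)
        idx = np.asarray(loop)
        nxt = np.roll(idx, -1)
        cap = np.column_stack(
            [np.full(len(idx), n), idx, nxt]
        )
        verts.append(c[None, :])
        tris.append(cap)
        n += 1
    Vc = np.vstack(verts)
    Fc = np.vstack(tris)
    v0, v1, v2 = (Vc[Fc[:, k]] for k in range(3))
    vol = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
    return float(abs(vol))


# ---------------------------------------------------------------------------
# boundary loops


def boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Ordered boundary loops, following the induced orientation.

    A boundary edge of an oriented mesh appears in exactly one face; the loop
    direction is the direction induced by that face's winding.
    """
    edges = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    key = [tuple(sorted(e)) for e in edges]
    from collections import Counter

    counts = Counter(key)
    succ: dict[int, int] = {}
    for (a, b), k in zip(edges, key):
        if counts[k] == 1:
            # boundary loop runs opposite to the face's edge direction
            succ[b] = a
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in list(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ[cur]
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# centerline


def centerline(surface: TubeSurface, n_hoops: int = 100) -> Centerline:
    """Centerline from hoop averages.

    Vertices are binned into ``n_hoops`` equal-width bands of the chart
    coordinate ``s``; the mean 3D position of each band is one centerline
    point, and the polyline through consecutive points defines the organ's
    effective length.
    """
    surface.require_chart()
    if n_hoops < 2:
        raise ValueError("n_hoops must be >= 2")
    s = surface.s
    edges = np.linspace(s.min(), s.max(), n_hoops + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_hoops - 1)
    pts = np.empty((n_hoops, 3))
    for b in range(n_hoops):
        sel = idx == b
        if not sel.any():
            raise ValueError(
                f"empty hoop bin {b}; use a coarser n_hoops (< {n_hoops})"
            )
        pts[b] = surface.vertices[sel].mean(axis=0)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return Centerline(points=pts, length=length)


# ---------------------------------------------------------------------------
# harmonic cylinder chart


def _solve_dirichlet(L: sp.csr_matrix, fixed: np.ndarray, values: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    free = np.setdiff1d(np.arange(n), fixed)
    x = np.zeros(n)
    x[fixed] = values
    A = L[free][:, free]
    b = -L[free][:, fixed] @ values
    x[free] = spla.spsolve(A.tocsc(), b)
    return x


def _cut_along_path(faces: np.ndarray, path: list[int], n_vertices: int):
    """Duplicate the vertices of ``path`` so the mesh opens along it.

    Returns ``(faces_cut, dup_orig, dup_new)`` where ``dup_orig[k]`` is the
    original index whose copy is ``dup_new[k]``.  Faces on one consistent side
    of the path are re-indexed to the copies.
    """
    path_edges = {frozenset(e) for e in zip(path[:-1], path[1:])}
    # incident faces per path vertex
    incident: dict[int, list[int]] = {v: [] for v in path}
    for fi, f in enumerate(faces):
        for v in f:
            if v in incident:
                incident[v].append(fi)
    edge_faces: dict[frozenset, list[int]] = {}
    for fi, f in enumerate(faces):
        for k in range(3):
            e = frozenset((f[k], f[(k + 1) % 3]))
            edge_faces.setdefault(e, []).append(fi)

    def components(v: int) -> list[set[int]]:
        """Wedges of faces around v, not crossing path edges."""
        fs = incident[v]
        parent = {f: f for f in fs}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for fi in fs:
            f = faces[fi]
            for k in range(3):
                e = frozenset((f[k], f[(k + 1) % 3]))
                if v in e and e not in path_edges and len(edge_faces[e]) == 2:
                    a, b = edge_faces[e]
                    parent[find(a)] = find(b)
        comps: dict[int, set[int]] = {}
        for fi in fs:
            comps.setdefault(find(fi), set()).add(fi)
        return list(comps.values())

    # choose, consistently along the path, which wedge is "side B" (duplicated)
    side_b: dict[int, set[int]] = {}
    first_edge = frozenset((path[0], path[1]))
    f_pair = edge_faces[first_edge]
    if len(f_pair) < 2:
        raise MeshTopologyError("cut path runs along a boundary edge")
    comps0 = components(path[0])
    if len(comps0) < 2:
        raise MeshTopologyError("cannot split fan at cut-path endpoint")
    side_b[path[0]] = next(c for c in comps0 if f_pair[1] in c)
    for a, b in zip(path[:-1], path[1:]):
        e = frozenset((a, b))
        fa_, fb_ = edge_faces[e]
        marker = fb_ if fb_ in side_b[a] else (fa_ if fa_ in side_b[a] else None)
        if marker is None:
            raise MeshTopologyError("inconsistent wedge propagation along cut")
        comps = components(b)
        side_b[b] = next(c for c in comps if marker in c)

    faces_cut = faces.copy()
    dup_orig, dup_new = [], []
    new_idx = n_vertices
    for v in path:
        dup_orig.append(v)
        dup_new.append(new_idx)
        for fi in side_b[v]:
            f = faces_cut[fi]
            faces_cut[fi] = np.where(f == v, new_idx, f)
        new_idx += 1
    return faces_cut, np.asarray(dup_orig), np.asarray(dup_new)


def harmonic_cylinder_chart(surface: TubeSurface) -> TubeSurface:
    """Compute an (s, phi) chart for a chartless topological cylinder.

    ``s`` is the harmonic function with the two boundary loops held at 0 and
    1.  The mesh is then cut open along a boundary-to-boundary path and
    ``phi`` is the harmonic function with the two copies of the cut held at 0
    and ``2*pi``, which winds exactly once around every hoop.  On a right
    circular cylinder this recovers the axial/angular coordinates up to an
    affine reparameterization.
    """
    V, F = surface.vertices, surface.faces
    loops = boundary_loops(F)
    if len(loops) != 2:
        raise MeshTopologyError(
            f"harmonic chart requires a cylinder with 2 boundary loops; "
            f"found {len(loops)} (Euler characteristic "
            f"{surface.euler_characteristic()})"
        )
    L = cotangent_laplacian(V, F)
    fixed = np.concatenate([loops[0], loops[1]])
    vals = np.concatenate([np.zeros(len(loops[0])), np.ones(len(loops[1]))])
    s = _solve_dirichlet(L, fixed, vals)

    # cut path: shortest interior path between the boundary loops
    G = nx.Graph()
    edges = np.sort(F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    lengths = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    boundary_set = set(loops[0]) | set(loops[1])
    for (a, b), w in zip(edges, lengths):
        # discourage running along the boundaries
        pen = 10.0 if (a in boundary_set and b in boundary_set) else 1.0
        G.add_edge(int(a), int(b), weight=float(w) * pen)
    path = nx.shortest_path(G, loops[0][0], loops[1][0], weight="weight")

    F_cut, dup_orig, dup_new = _cut_along_path(F, path, len(V))
    V_cut = np.vstack([V, V[dup_orig]])
    L_cut = cotangent_laplacian(V_cut, F_cut)
    fixed = np.concatenate([dup_orig, dup_new])
    vals = np.concatenate([np.zeros(len(dup_orig)), np.full(len(dup_new), 2 * np.pi)])
    phi_cut = _solve_dirichlet(L_cut, fixed, vals)
    phi = np.mod(phi_cut[: len(V)], 2 * np.pi)

    out = replace(
        surface,
        s=s,
        phi=phi,
        seam=np.column_stack([dup_orig, dup_new]),
    )
    # orient the chart right-handed with the inward normal:
    # grad(phi) should align with n_in x s_hat
    sc = face_chart_coords(out)
    gs, gphi = _face_chart_gradients(out, sc)
    n_in = face_normals(V, F)
    shat = _normalize_rows(gs)
    ref = np.cross(n_in, shat)
    if np.median(np.einsum("ij,ij->i", gphi, ref)) < 0:
        out = replace(out, phi=np.mod(2 * np.pi - phi, 2 * np.pi))
    return out


# ---------------------------------------------------------------------------
# chart helpers and tangent frames


def face_chart_coords(surface: TubeSurface) -> np.ndarray:
    """Per-face (3, 2) chart coordinates with phi unwrapped within each face.

    Faces straddling the periodic seam get local phi copies shifted by 2*pi so
    that within one face all phi values lie within pi of the first corner.
    """
    surface.require_chart()
    s = surface.s[surface.faces]
    phi = surface.phi[surface.faces].copy()
    ref = phi[:, :1]
    phi += 2 * np.pi * np.round((ref - phi) / (2 * np.pi))
    return np.stack([s, phi], axis=-1)


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=1)
    if np.any(n <= 1e-300):
        raise DegenerateFaceError("degenerate chart gradient on some faces")
    return x / n[:, None]


def _face_chart_gradients(surface: TubeSurface, chart: np.ndarray):
    """3D gradients of the chart functions s and phi restricted to each face."""
    V, F = surface.vertices, surface.faces
    v0, v1, v2 = (V[F[:, k]] for k in range(3))
    n = face_normals(V, F)
    a2 = 2.0 * face_areas(V, F)

    def grad(vals: np.ndarray) -> np.ndarray:
        # standard P1 gradient: sum_k vals_k * (n x e_opp_k) / (2A)
        e0 = v2 - v1
        e1 = v0 - v2
        e2 = v1 - v0
        g = (
            vals[:, 0, None] * np.cross(n, e0)
            + vals[:, 1, None] * np.cross(n, e1)
            + vals[:, 2, None] * np.cross(n, e2)
        )
        return g / a2[:, None]

    return grad(chart[:, :, 0]), grad(chart[:, :, 1])


def tangent_directions(surface: TubeSurface):
    """Per-face orthonormal tangent frame (s_hat, phi_hat).

    ``s_hat`` is the in-plane direction of increasing ``s`` (Gram-Schmidt
    first); ``phi_hat = n_in x s_hat`` completes a right-handed frame with the
    inward normal, so on a straight tube it points along the circumferential
    direction of increasing phi.
    """
    chart = face_chart_coords(surface)
    gs, _ = _face_chart_gradients(surface, chart)
    n_in = face_normals(surface.vertices, surface.faces)
    shat = _normalize_rows(gs)
    phihat = np.cross(n_in, shat)
    return shat, phihat
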