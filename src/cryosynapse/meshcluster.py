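"""Geodesic DBSCAN clustering of receptors on membrane meshes.

Receptor-to-receptor distances are measured ALONG the membrane, not
through space: a membrane mesh is reconstructed from the segmented
postsynaptic point cloud, receptors are projected to their nearest mesh
vertex, and pairwise distances are shortest paths (Dijkstra) on the
edge-weighted mesh graph. DBSCAN (eps 70 nm, min size 4) on those
distances then finds receptor clusters; each cluster is classed as
cleft / boundary / perisynaptic by whether all, some, or none of its
members sit on in-cleft membrane. Surface distance matters because two
receptor groups on opposite faces of a folded membrane can be close in
3-space yet far apart along the membrane.

Surface reconstruction here is crust-style in behaviour: sheet-like
clouds (the common case for a segmented membrane patch) are triangulated
by 2D Delaunay in the cloud's principal plane; closed convex clouds fall
back to the convex hull. Meshes are simplified by quadric edge collapse
with a link-condition guard so topology survives.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from sklearn.cluster import DBSCAN

from .cleft import CleftZone
from .volio import MeshFile, PointTable, _triangle_areas

DEFAULT_EPS_NM = 70.0      # max surface distance between clustered receptors
DEFAULT_MIN_SIZE = 4       # minimal cluster size
DEFAULT_TARGET_FACES = 10_000


class GeometryError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


# ---------------------------------------------------------------- meshes

@dataclass
class SurfaceMesh:
    """Triangle mesh with its edge-weighted graph."""

    vertices: np.ndarray                 # (V, 3) nm
    faces: np.ndarray                    # (F, 3) int
    edges: np.ndarray = field(init=False)        # (E, 2) int, sorted pairs
    edge_lengths: np.ndarray = field(init=False)  # (E,) nm
    component_id: np.ndarray = field(init=False)  # (V,) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        e = np.sort(np.vstack([self.faces[:, [0, 1]],
                               self.faces[:, [1, 2]],
                               self.faces[:, [0, 2]]]), axis=1)
        self.edges = np.unique(e, axis=0) if len(e) else e.reshape(0, 2)
        self.edge_lengths = np.linalg.norm(
            self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]],
            axis=1) if len(self.edges) else np.zeros(0)
        if len(self.edge_lengths) and self.edge_lengths.min() <= 0:
            raise GeometryError("mesh has a zero-length edge")
        g = self.graph()
        n_comp, comp = connected_components(g, directed=False)
        self.component_id = comp

    def graph(self):
        n = len(self.vertices)
        if not len(self.edges):
            return coo_matrix((n, n)).tocsr()
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.edge_lengths
        return coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n)).tocsr()

    @property
    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.faces)

    @property
    def area(self) -> float:
        return float(_triangle_areas(self.vertices, self.faces).sum())

    def as_meshfile(self) -> MeshFile:
        return MeshFile(vertices=self.vertices, faces=self.faces)


def build_mesh(
    points: PointTable | np.ndarray,
    target_faces: int = DEFAULT_TARGET_FACES,
) -> SurfaceMesh:
    """Reconstruct a surface mesh interpolating a membrane point cloud.

    Sheet-like clouds (smallest principal extent well below the lateral
    ones) are triangulated by Delaunay in the principal plane — exact for
    planar data. Clouds that are 3D-extended (e.g. spherical shells) use
    the convex hull. The result is quadric-decimated to <= target_faces.
    """
    pts = points.coordinates if isinstance(points, PointTable) else \
        np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise GeometryError("need >= 3 points to mesh")
    centred = pts - pts.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise GeometryError("point cloud is collinear; cannot mesh")
    sheet_like = len(pts) < 4 or s[2] < 0.25 * s[1]
    if sheet_like:
        uv = centred @ vt[:2].T
        tri = Delaunay(uv)
        faces = tri.simplices
        areas = _triangle_areas(pts, faces)
        faces = faces[areas > 1e-12]
        mesh = SurfaceMesh(vertices=pts, faces=faces)
    else:
        hull = ConvexHull(pts)
        faces = _orient_outward(pts, hull.simplices, pts.mean(axis=0))
        mesh = SurfaceMesh(vertices=pts, faces=faces)
    if len(mesh.faces) > target_faces:
        v, f = quadric_decimate(mesh.vertices, mesh.faces, target_faces)
        mesh = SurfaceMesh(vertices=v, faces=f)
    return mesh


def grid_mesh(vertex_grid: np.ndarray) -> SurfaceMesh:
    """Triangulate an (nu, nv, 3) array of surface samples in parameter
    order. Use for explicitly parametrised surfaces (e.g. folded sheets)
    that point-cloud reconstruction cannot disambiguate."""
    vg = np.asarray(vertex_grid, dtype=float)
    if vg.ndim != 3 or vg.shape[2] != 3:
        raise GeometryError("vertex_grid must be (nu, nv, 3)")
    nu, nv = vg.shape[:2]
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([
        np.column_stack([a, b, c]), np.column_stack([b, d, c])])
    return SurfaceMesh(vertices=vg.reshape(-1, 3), faces=faces)


def _orient_outward(pts, faces, centroid):
    a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
    n = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", n, a - centroid) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


# ------------------------------------------------- quadric decimation

def quadric_decimate(
    vertices: np.ndarray, faces: np.ndarray, target_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Garland–Heckbert edge-collapse simplification.

    Collapses the cheapest edge (summed vertex quadrics, optimal or
    midpoint placement) until the face count reaches ``target_faces``.
    Collapses violating the link condition are rejected, which preserves
    the mesh topology (Euler characteristic).
    """
    V = np.asarray(vertices, dtype=float).copy()
    F = np.asarray(faces, dtype=int).copy()
    n = len(V)
    quadrics = np.zeros((n, 4, 4))
    for f in F:
        p0, p1, p2 = V[f]
        nrm = np.cross(p1 - p0, p2 - p0)
        a = np.linalg.norm(nrm)
        if a == 0:
            continue
        nrm = nrm / a
        d = -nrm @ p0
        plane = np.append(nrm, d)
        q = np.outer(plane, plane) * (a / 2.0)
        for vi in f:
            quadrics[vi] += q

    neighbors: list[set[int]] = [set() for _ in range(n)]
    vert_faces: list[set[int]] = [set() for _ in range(n)]
    for fi, f in enumerate(F):
        for a_, b_ in ((0, 1), (1, 2), (0, 2)):
            neighbors[f[a_]].add(f[b_])
            neighbors[f[b_]].add(f[a_])
        for vi in f:
            vert_faces[vi].add(fi)

    alive_v = np.ones(n, dtype=bool)
    alive_f = np.ones(len(F), dtype=bool)
    n_faces = len(F)

    def is_boundary(x: int) -> bool:
        return any(len(vert_faces[x] & vert_faces[w]) == 1
                   for w in neighbors[x])

    def collapse_cost(u: int, v: int) -> tuple[float, np.ndarray]:
        Q = quadrics[u] + quadrics[v]
        A = Q[:3, :3]
        b = -Q[:3, 3]
        try:
            pos = np.linalg.solve(A + 1e-9 * np.eye(3), b)
            if not np.all(np.isfinite(pos)) or \
               np.linalg.norm(pos - V[u]) > 3 * np.linalg.norm(V[u] - V[v]) + 1e-9:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[u] + V[v])
        h = np.append(pos, 1.0)
        return float(h @ Q @ h), pos

    heap: list[tuple[float, int, int]] = []
    for u in range(n):
        for v in neighbors[u]:
            if u < v:
                cost, _ = collapse_cost(u, v)
                heapq.heappush(heap, (cost, u, v))

    while n_faces > target_faces and heap:
        cost, u, v = heapq.heappop(heap)
        if not (alive_v[u] and alive_v[v]) or v not in neighbors[u]:
            continue
        cur_cost, pos = collapse_cost(u, v)
        if cur_cost > cost + 1e-12:      # stale entry
            heapq.heappush(heap, (cur_cost, u, v))
            continue
        # link condition: shared neighbours must all form a face with (u,v)
        shared = neighbors[u] & neighbors[v]
        uv_faces = vert_faces[u] & vert_faces[v]
        wing = set()
        for fi in uv_faces:
            wing.update(F[fi])
        wing -= {u, v}
        if shared != wing or not (1 <= len(uv_faces) <= 2):
            continue
        # collapsing an interior edge between two boundary vertices would
        # pinch the surface and change its topology
        if len(uv_faces) == 2 and is_boundary(u) and is_boundary(v):
            continue
        # collapse v into u at pos
        V[u] = pos
        quadrics[u] = quadrics[u] + quadrics[v]
        alive_v[v] = False
        for fi in uv_faces:
            if alive_f[fi]:
                alive_f[fi] = False
                n_faces -= 1
                for w in F[fi]:
                    vert_faces[w].discard(fi)
        for fi in list(vert_faces[v]):
            F[fi][F[fi] == v] = u
            vert_faces[u].add(fi)
            if len(set(F[fi])) < 3 and alive_f[fi]:
                alive_f[fi] = False
                n_faces -= 1
                for w in set(F[fi]):
                    vert_faces[w].discard(fi)
        vert_faces[v] = set()
        for w in neighbors[v]:
            neighbors[w].discard(v)
            if w != u:
                neighbors[w].add(u)
                neighbors[u].add(w)
        neighbors[u].discard(u)
        neighbors[u].discard(v)
        neighbors[v] = set()
        for w in neighbors[u]:
            c, _ = collapse_cost(*sorted((u, w)))
            heapq.heappush(heap, (c, *sorted((u, w))))

    keep = np.nonzero(alive_v)[0]
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(len(keep))
    new_faces = remap[F[alive_f]]
    # drop any residual degenerate faces
    ok = (new_faces[:, 0] != new_faces[:, 1]) & \
         (new_faces[:, 1] != new_faces[:, 2]) & \
         (new_faces[:, 0] != new_faces[:, 2])
    return V[keep], new_faces[ok]


# ------------------------------------------------------------ receptors

@dataclass
class ReceptorSet:
    positions: np.ndarray            # (n, 3) nm membrane-insertion points
    projected_vertex: np.ndarray     # (n,) vertex index
    projection_residual: np.ndarray  # (n,) nm

    def __len__(self) -> int:
        return len(self.positions)


def project_receptors(
    receptors: PointTable | np.ndarray, mesh: SurfaceMesh
) -> ReceptorSet:
    """Assign each receptor its Euclidean-nearest mesh vertex.

    Ties resolve to the lowest vertex index (KD-tree convention), so the
    assignment is deterministic.
    """
    pos = receptors.coordinates if isinstance(receptors, PointTable) else \
        np.asarray(receptors, dtype=float).reshape(-1, 3)
    if len(mesh.vertices) == 0:
        raise GeometryError("empty mesh")
    d, idx = cKDTree(mesh.vertices).query(pos) if len(pos) else \
        (np.zeros(0), np.zeros(0, dtype=int))
    return ReceptorSet(positions=pos, projected_vertex=np.atleast_1d(idx),
                       projection_residual=np.atleast_1d(d))


def geodesic_matrix(mesh: SurfaceMesh, vertex_ids: np.ndarray) -> np.ndarray:
    """Pairwise shortest-path distances along mesh edges (Dijkstra).

    Entries between different mesh components are +inf; the diagonal is 0.
    """
    vertex_ids = np.asarray(vertex_ids, dtype=int)
    if vertex_ids.size == 0:
        raise ValueError("vertex_ids must be non-empty")
    if vertex_ids.min() < 0 or vertex_ids.max() >= len(mesh.vertices):
        raise ValueError("vertex id out of range")
    full = dijkstra(mesh.graph(), directed=False, indices=vertex_ids)
    mat = full[:, vertex_ids]
    return 0.5 * (mat + mat.T)  # symmetrise exact float asymmetries


@dataclass
class ClusterParams:
    eps: float = DEFAULT_EPS_NM
    min_size: int = DEFAULT_MIN_SIZE

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.min_size < 1:
            raise ValueError("eps must be > 0 and min_size >= 1")


def cluster_receptors(
    distances: np.ndarray, params: ClusterParams | None = None
) -> np.ndarray:
    """DBSCAN on a precomputed (geodesic) distance matrix.

    eps is the core-neighbourhood radius and min_size the minPts count
    (standard DBSCAN semantics, so every cluster has >= min_size members);
    +inf entries mean "never neighbours" (distinct mesh components).
    Returns one label per row, -1 for noise.
    """
    if params is None:
        params = ClusterParams()
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.array_equal(np.isinf(D), np.isinf(D.T)):
        raise ValueError("distance matrix not symmetric within 1e-9")
    with np.errstate(invalid="ignore"):
        diff = np.abs(D - D.T)
    fin = np.isfinite(diff)
    if fin.any() and diff[fin].max() > 1e-9:
        raise ValueError("distance matrix not symmetric within 1e-9")
    if len(D) == 0:
        return np.zeros(0, dtype=int)
    finite = D[np.isfinite(D)]
    sentinel = max(finite.max() if finite.size else 0.0, params.eps) * 10 + 1.0
    Dw = np.where(np.isfinite(D), D, sentinel)
    np.fill_diagonal(Dw, 0.0)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_size,
                    metric="precomputed").fit_predict(Dw)
    return labels


# -------------------------------------------------------------- classes

@dataclass
class ClusterReport:
    labels: np.ndarray
    clusters: pd.DataFrame       # cluster, size, location_class, members
    n_clusters: int
    n_noise: int
    class_counts: dict[str, int]

    @property
    def sizes(self) -> np.ndarray:
        return self.clusters["size"].to_numpy()


def vertex_cleft_mask(
    mesh: SurfaceMesh, posm: PointTable, zone: CleftZone
) -> np.ndarray:
    """Transfer the in-cleft mask from PoSM points to mesh vertices by
    nearest-point vote (each vertex inherits its nearest PoSM point's flag)."""
    if len(zone) != len(posm):
        raise ConsistencyError("zone and PoSM table lengths differ")
    _, idx = cKDTree(posm.coordinates).query(mesh.vertices)
    return zone.in_cleft[idx]


def classify_clusters(
    labels: np.ndarray,
    receptorset: ReceptorSet,
    vertex_in_cleft: np.ndarray,
) -> ClusterReport:
    """Class each cluster by its members' membrane location.

    cleft: every member projects to in-cleft membrane; perisynaptic: none
    do; boundary: the cluster straddles the cleft edge.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(receptorset):
        raise ConsistencyError("labels and receptor set lengths differ")
    rows = []
    for lab in sorted(set(labels) - {-1}):
        members = np.nonzero(labels == lab)[0]
        in_cleft = vertex_in_cleft[receptorset.projected_vertex[members]]
        if in_cleft.all():
            cls = "cleft"
        elif not in_cleft.any():
            cls = "perisynaptic"
        else:
            cls = "boundary"
        rows.append({"cluster": lab, "size": len(members),
                     "location_class": cls, "members": members.tolist()})
    clusters = pd.DataFrame(
        rows, columns=["cluster", "size", "location_class", "members"])
    counts = {c: int((clusters["location_class"] == c).sum())
              for c in ("cleft", "boundary", "perisynaptic")}
    return ClusterReport(
        labels=labels,
        clusters=clusters,
        n_clusters=len(rows),
        n_noise=int((labels == -1).sum()),
        class_counts=counts,
    )


def analyze_receptor_clusters(
    posm: PointTable,
    receptors: PointTable,
    zone: CleftZone,
    params: ClusterParams | None = None,
    target_faces: int = DEFAULT_TARGET_FACES,
) -> tuple[ClusterReport, SurfaceMesh]:
    """End-to-end: mesh the PoSM, project, geodesic DBSCAN, classify."""
    mesh = build_mesh(posm, target_faces=target_faces)
    recs = project_receptors(receptors, mesh)
    if len(recs) == 0:
        empty = ClusterReport(
            labels=np.zeros(0, dtype=int),
            clusters=pd.DataFrame(
                columns=["cluster", "size", "location_class", "members"]),
            n_clusters=0, n_noise=0,
            class_counts={"cleft": 0, "boundary": 0, "perisynaptic": 0})
        return empty, mesh
    D = geodesic_matrix(mesh, recs.projected_vertex)
    labels = cluster_receptors(D, params)
    mask = vertex_cleft_mask(mesh, posm, zone)
    return classify_clusters(labels, recs, mask), mesh
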