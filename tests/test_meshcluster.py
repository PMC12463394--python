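"""Mesh reconstruction, geodesics, DBSCAN, cluster location classes."""

import numpy as np
import pytest
import trimesh

from conftest import brute_force_dbscan, floyd_warshall_oracle
from cryosynapse import cleft, meshcluster, synth
from cryosynapse.meshcluster import (ClusterParams, SurfaceMesh, build_mesh,
                                     cluster_receptors, classify_clusters,
                                     geodesic_matrix, grid_mesh,
                                     project_receptors, quadric_decimate)
from cryosynapse.volio import PointTable


def _icosphere_mesh(subdivisions=2, radius=200.0):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices),
                       faces=np.asarray(ico.faces))


class TestBuildMesh:
    def test_planar_cloud_interpolated_exactly(self, rng):
        pts = np.column_stack([rng.uniform(0, 100, (200, 2)), np.zeros(200)])
        mesh = build_mesh(PointTable(pts, label="PoSM"))
        assert np.allclose(mesh.vertices[:, 2], 0.0, atol=1e-9)
        assert len(mesh.vertices) == 200

    def test_sphere_area_within_5pct(self):
        r = 200.0
        sc = synth.make_synapse_scene(geometry="sphere", sphere_radius=r,
                                      spacing=14.0, n_clusters=0, seed=0)
        assert len(sc.presm_points) >= 2000
        mesh = build_mesh(sc.presm_points, target_faces=50_000)
        assert mesh.area == pytest.approx(4 * np.pi * r**2, rel=0.05)

    def test_decimation_preserves_sphere_topology(self):
        mesh = _icosphere_mesh(subdivisions=3)
        assert mesh.euler_characteristic == 2
        v, f = quadric_decimate(mesh.vertices, mesh.faces, 200)
        dec = SurfaceMesh(vertices=v, faces=f)
        assert len(dec.faces) <= 200
        assert dec.euler_characteristic == 2

    def test_decimated_sphere_stays_spherical(self):
        mesh = _icosphere_mesh(subdivisions=3, radius=100.0)
        v, f = quadric_decimate(mesh.vertices, mesh.faces, 300)
        radii = np.linalg.norm(v, axis=1)
        assert np.all(np.abs(radii - 100.0) < 5.0)

    def test_decimation_preserves_disk_topology(self, rng):
        """A planar patch is a disk (Euler 1) and must stay one."""
        pts = np.column_stack([rng.uniform(0, 300, (1500, 2)),
                               np.zeros(1500)])
        mesh = build_mesh(PointTable(pts, label="PoSM"), target_faces=10**6)
        assert mesh.euler_characteristic == 1
        v, f = quadric_decimate(mesh.vertices, mesh.faces, 800)
        dec = SurfaceMesh(vertices=v, faces=f)
        assert len(dec.faces) <= 800
        assert dec.euler_characteristic == 1

    def test_collinear_cloud_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(meshcluster.GeometryError):
            build_mesh(PointTable(pts, label="PoSM"))


class TestProjection:
    def test_receptor_on_vertex_projects_to_it(self, small_scene):
        mesh = build_mesh(small_scene.posm_points)
        rs = project_receptors(mesh.vertices[[7]], mesh)
        assert rs.projected_vertex[0] == 7
        assert rs.projection_residual[0] == 0.0

    def test_ectodomain_offset_gives_expected_residual(self):
        sc = synth.make_synapse_scene(extent=200, spacing=5.0, n_clusters=0,
                                      seed=0)
        mesh = build_mesh(sc.posm_points)
        foot = sc.posm_points.coordinates[50]
        rec = foot + np.array([0.0, 0.0, -14.0])  # ectodomain into the cleft
        rs = project_receptors(rec[None], mesh)
        assert rs.projection_residual[0] == pytest.approx(14.0, abs=0.5)
        assert np.allclose(mesh.vertices[rs.projected_vertex[0]], foot)

    def test_matches_exhaustive_search(self, rng):
        mesh = _icosphere_mesh(subdivisions=4)  # ~5k vertices
        recs = rng.normal(0, 1, (100, 3))
        recs = 205.0 * recs / np.linalg.norm(recs, axis=1, keepdims=True)
        rs = project_receptors(recs, mesh)
        d = np.linalg.norm(recs[:, None, :] - mesh.vertices[None], axis=2)
        assert np.array_equal(rs.projected_vertex, d.argmin(axis=1))


class TestGeodesics:
    def test_diagonal_zero_and_path_graph(self):
        v = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0], [5, 5, 0.0]])
        f = np.array([[0, 1, 3], [1, 2, 3]])
        mesh = SurfaceMesh(vertices=v, faces=f)
        D = geodesic_matrix(mesh, np.arange(4))
        assert np.allclose(np.diag(D), 0.0)
        assert D[0, 2] == pytest.approx(10.0)  # 0-1-2 along the x axis

    def test_matches_floyd_warshall_on_random_meshes(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.column_stack([r.uniform(0, 100, (r.integers(20, 150), 2))])
            pts = np.column_stack([pts, np.zeros(len(pts))])
            mesh = build_mesh(PointTable(pts, label="PoSM"))
            D = geodesic_matrix(mesh, np.arange(len(mesh.vertices)))
            oracle = floyd_warshall_oracle(
                len(mesh.vertices), mesh.edges, mesh.edge_lengths)
            assert np.allclose(D, oracle, atol=1e-9)

    def test_geodesic_bounded_below_by_euclidean(self, rng):
        mesh = _icosphere_mesh(subdivisions=2)
        ids = rng.choice(len(mesh.vertices), 30, replace=False)
        D = geodesic_matrix(mesh, ids)
        E = np.linalg.norm(mesh.vertices[ids][:, None]
                           - mesh.vertices[ids][None], axis=2)
        assert np.all(D >= E - 1e-9)

    def test_disconnected_components_are_infinite(self):
        v = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0],
                      [100, 0, 0], [105, 0, 0], [100, 5, 0.0]])
        f = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = SurfaceMesh(vertices=v, faces=f)
        D = geodesic_matrix(mesh, np.arange(6))
        assert np.isinf(D[0, 3])
        assert np.isfinite(D[0, 1]) and np.isfinite(D[3, 4])
        assert len(set(mesh.component_id)) == 2

    def test_refinement_convergence_on_sphere(self):
        """Halving edge length changes fixed-point geodesics by <= 5%."""
        anchors = np.array([[0, 0, 200.0], [200.0, 0, 0], [0, 200.0, 0],
                            [0, 0, -200.0]])
        dists = []
        for sub in (3, 4):
            mesh = _icosphere_mesh(subdivisions=sub, radius=200.0)
            ids = project_receptors(anchors, mesh).projected_vertex
            D = geodesic_matrix(mesh, ids)
            iu = np.triu_indices(len(anchors), 1)
            dists.append(D[iu])
        assert np.all(np.abs(dists[1] - dists[0]) / dists[0] <= 0.05)


class TestDBSCAN:
    def test_defaults_match_convention(self):
        p = ClusterParams()
        assert p.eps == 70.0 and p.min_size == 4

    def test_three_points_below_min_size_are_noise(self):
        D = np.array([[0, 10, 10], [10, 0, 10], [10, 10, 0.0]])
        labels = cluster_receptors(D)
        assert np.all(labels == -1)

    def test_two_well_separated_groups(self, rng):
        pts = np.vstack([rng.normal(0, 5, (6, 2)),
                         rng.normal([300, 0], 5, (6, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        labels = cluster_receptors(D)
        oracle = brute_force_dbscan(D, 70.0, 4)
        assert len(set(labels)) == 2 and -1 not in labels
        assert np.array_equal(labels, oracle)

    def test_asymmetric_matrix_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = 5.0
        with pytest.raises(ValueError, match="symmetric"):
            cluster_receptors(D)

    def test_infinite_entries_never_join_clusters(self):
        n = 8
        D = np.full((n, n), np.inf)
        np.fill_diagonal(D, 0.0)
        for i in range(4):
            for j in range(4):
                D[i, j] = abs(i - j) * 10.0
                D[i + 4, j + 4] = abs(i - j) * 10.0
        labels = cluster_receptors(D)
        assert labels[0] != labels[4]
        assert (labels[:4] == labels[0]).all()

    def test_flat_sheet_geodesic_equals_euclidean_dbscan(self):
        """On densely meshed planar sheets the two metrics give identical
        labels (clusters far from the eps boundary)."""
        for seed in range(20):
            sc = synth.make_synapse_scene(
                extent=900, spacing=12.0, n_clusters=3,
                receptors_per_cluster=7, cluster_sigma=15.0,
                guard_distance=280.0, seed=seed)
            mesh = build_mesh(sc.posm_points, target_faces=100_000)
            rs = project_receptors(sc.receptor_truth, mesh)
            D = geodesic_matrix(mesh, rs.projected_vertex)
            geo = cluster_receptors(D)
            rec = sc.receptor_truth.coordinates
            E = np.linalg.norm(rec[:, None] - rec[None], axis=2)
            eu = brute_force_dbscan(E, 70.0, 4)
            assert _same_partition(geo, eu)

    def test_fold_separates_euclidean_neighbours(self):
        """Two receptor groups on opposite faces of a folded sheet: one
        Euclidean cluster, two geodesic clusters — the reason clustering
        uses surface distance."""
        # U-fold: two parallel sheets 30 nm apart joined by a half-cylinder
        u = np.linspace(0, 300, 61)       # arc length along the unrolled sheet
        y = np.linspace(0, 200, 41)
        uu, yy = np.meshgrid(u, y, indexing="ij")
        r = 15.0
        flat_len = (300 - np.pi * r) / 2.0
        x = np.where(uu < flat_len, flat_len - uu,
                     np.where(uu > 300 - flat_len, uu - (300 - flat_len),
                              -r * np.sin((uu - flat_len) / r)))
        z = np.where(uu < flat_len, 0.0,
                     np.where(uu > 300 - flat_len, 2 * r,
                              r - r * np.cos((uu - flat_len) / r)))
        mesh = grid_mesh(np.stack([x, yy, z], axis=-1))
        bottom = np.array([[100.0, 100.0, 0.0], [110, 100, 0], [100, 110, 0],
                           [110, 110, 0]])
        top = bottom + [0, 0, 2 * r]
        rec = np.vstack([bottom, top])
        rs = project_receptors(rec, mesh)
        D = geodesic_matrix(mesh, rs.projected_vertex)
        geo = cluster_receptors(D)
        E = np.linalg.norm(rec[:, None] - rec[None], axis=2)
        eu = brute_force_dbscan(E, 70.0, 4)
        assert len(set(eu) - {-1}) == 1          # Euclidean merges the faces
        assert len(set(geo) - {-1}) == 2         # geodesic keeps them apart


def _same_partition(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    m = a != -1
    pairs_a = a[m][:, None] == a[m][None]
    pairs_b = b[m][:, None] == b[m][None]
    return np.array_equal(pairs_a, pairs_b)


class TestClassification:
    def _setup(self, in_cleft_mask, labels):
        n = len(labels)
        rs = meshcluster.ReceptorSet(
            positions=np.zeros((n, 3)),
            projected_vertex=np.arange(n),
            projection_residual=np.zeros(n))
        return classify_clusters(np.asarray(labels), rs,
                                 np.asarray(in_cleft_mask))

    def test_all_in_cleft(self):
        rep = self._setup([True] * 5, [0] * 5)
        assert rep.clusters["location_class"].iloc[0] == "cleft"

    def test_none_in_cleft(self):
        rep = self._setup([False] * 5, [0] * 5)
        assert rep.clusters["location_class"].iloc[0] == "perisynaptic"

    def test_straddling_cluster_is_boundary(self):
        rep = self._setup([True, True, False, False, False], [0] * 5)
        assert rep.clusters["location_class"].iloc[0] == "boundary"
        assert rep.class_counts == {"cleft": 0, "boundary": 1,
                                    "perisynaptic": 0}

    def test_length_mismatch_raises(self):
        rs = meshcluster.ReceptorSet(np.zeros((3, 3)), np.arange(3),
                                     np.zeros(3))
        with pytest.raises(meshcluster.ConsistencyError):
            classify_clusters(np.zeros(5, dtype=int), rs, np.ones(3, bool))

    def test_end_to_end_scene_classes(self):
        sc = synth.make_synapse_scene(extent=500, spacing=10.0, n_clusters=2,
                                      receptors_per_cluster=8,
                                      guard_distance=150.0, seed=11)
        cm = cleft.cleft_distances(sc.presm_points, sc.posm_points)
        zone = cleft.cleft_zone(sc.posm_points, cm)
        rep, _ = meshcluster.analyze_receptor_clusters(
            sc.posm_points, sc.receptor_truth, zone)
        assert rep.n_clusters == 2
        # flat parallel planes at 33 nm: everything is in-cleft membrane
        assert set(rep.clusters["location_class"]) == {"cleft"}
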