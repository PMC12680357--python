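import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from cranioplan.mesh import (
    TriangleMesh,
    cranial_index,
    flatten_shape,
    load_stl,
    mesh_volume,
    offset_mesh,
    save_stl,
    surface_distance,
    unflatten_shape,
    volume_match_scale,
    _closest_on_triangles,
)
from tests.conftest import icosphere

TETRA = TriangleMesh(
    np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
    np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]),
)


class TestStlIO:
    def test_roundtrip_identity(self, tmp_path):
        path = tmp_path / "tet.stl"
        save_stl(TETRA, path)
        back = load_stl(path)
        assert back.n_vertices == 4 and back.n_faces == 4
        # vertex order may change through the triangle soup; compare as sets
        got = set(map(tuple, np.round(back.vertices, 9)))
        want = set(map(tuple, TETRA.vertices))
        assert got == want

    def test_ascii_binary_equivalence(self, tmp_path):
        mesh = icosphere(30.0, 1)
        save_stl(mesh, tmp_path / "b.stl")
        save_stl(mesh, tmp_path / "a.stl", ascii=True)
        vb = np.sort(load_stl(tmp_path / "b.stl").vertices.ravel())
        va = np.sort(load_stl(tmp_path / "a.stl").vertices.ravel())
        np.testing.assert_allclose(va, vb, atol=1e-5)

    def test_empty_stl_rejected(self, tmp_path):
        path = tmp_path / "empty.stl"
        # valid binary STL header declaring zero triangles
        path.write_bytes(b"\0" * 80 + (0).to_bytes(4, "little"))
        with pytest.raises(ValueError):
            load_stl(path)

    def test_malformed_stl_rejected(self, tmp_path):
        path = tmp_path / "garbage.stl"
        path.write_bytes(b"not a mesh at all")
        with pytest.raises(ValueError):
            load_stl(path)


class TestShapeVector:
    def test_flatten_ordering(self):
        mesh = TriangleMesh(np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]]),
                            np.array([[0, 1, 2]]))
        np.testing.assert_array_equal(flatten_shape(mesh),
                                      [1, 2, 3, 4, 5, 6, 7, 8, 9])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_flatten_unflatten_bijection(self, seed):
        rng = np.random.default_rng(seed)
        verts = rng.normal(0, 50, (100, 3))
        faces = rng.integers(0, 100, (150, 3))
        ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
        faces = faces[ok][:50]
        mesh = TriangleMesh(verts, faces)
        back = unflatten_shape(flatten_shape(mesh), mesh.faces)
        assert (back.vertices == mesh.vertices).all()
        assert (back.faces == mesh.faces).all()

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            unflatten_shape(np.arange(7.0), TETRA.faces)


class TestSurfaceDistance:
    def test_identical_meshes_zero(self):
        mesh = icosphere(40.0, 2)
        d = surface_distance(mesh, mesh)
        assert d.max < 1e-9 and d.mean <= d.max

    def test_concentric_spheres(self):
        d = surface_distance(icosphere(50.0, 3), icosphere(52.0, 3))
        assert d.mean == pytest.approx(2.0, rel=0.01)

    def test_point_to_triangle_against_dense_sampling(self):
        # unit triangle in the plane x = 0; query from (10, 0.3, 0.3)
        tri = np.array([[[0.0, 0, 0], [0, 1, 0], [0, 0, 1]]])
        p = np.array([[10.0, 0.3, 0.3]])
        u = np.linspace(0, 1, 500)
        uu, vv = np.meshgrid(u, u)
        mask = uu + vv <= 1
        samples = np.stack([np.zeros(mask.sum()), uu[mask], vv[mask]], axis=1)
        oracle = np.linalg.norm(samples - p, axis=1).min()
        assert _closest_on_triangles(p, tri[None])[0, 0] == pytest.approx(oracle, abs=1e-4)

    def test_outside_edge_region_against_dense_sampling(self):
        tri = np.array([[[0.0, 0, 0], [0, 1, 0], [0, 0, 1]]])
        p = np.array([[2.0, 2.0, 2.0]])
        u = np.linspace(0, 1, 800)
        uu, vv = np.meshgrid(u, u)
        mask = uu + vv <= 1
        samples = np.stack([np.zeros(mask.sum()), uu[mask], vv[mask]], axis=1)
        oracle = np.linalg.norm(samples - p, axis=1).min()
        assert _closest_on_triangles(p, tri[None])[0, 0] == pytest.approx(oracle, abs=1e-4)

    def test_bounded_by_nearest_vertex_distance(self):
        rng = np.random.default_rng(1)
        query = icosphere(45.0, 2)
        ref = icosphere(50.0, 1)
        d = surface_distance(query, ref).distances
        from scipy.spatial import cKDTree

        dv, _ = cKDTree(ref.vertices).query(query.vertices)
        assert (d >= -1e-12).all()
        assert (d <= dv + 1e-9).all()

    def test_csv_export(self, tmp_path):
        d = surface_distance(icosphere(50.0, 1), icosphere(52.0, 1))
        d.to_csv(tmp_path / "d.csv")
        arr = np.loadtxt(tmp_path / "d.csv", delimiter=",", skiprows=1)
        assert arr.shape == (len(d.distances), 2)

    def test_heatmap_ply_export(self, tmp_path):
        from cranioplan.mesh import export_heatmap_ply

        mesh = icosphere(50.0, 1)
        d = surface_distance(mesh, icosphere(52.0, 1))
        export_heatmap_ply(mesh, d.distances, tmp_path / "heat.ply")
        back = trimesh.load(str(tmp_path / "heat.ply"), process=False)
        assert len(back.vertices) == mesh.n_vertices
        assert len(back.faces) == mesh.n_faces
        with pytest.raises(ValueError):
            export_heatmap_ply(mesh, d.distances[:-1], tmp_path / "bad.ply")


def _ellipsoid(a, b, c, sub=3):
    tm = trimesh.creation.icosphere(sub, 1.0)
    verts = np.array(tm.vertices) * [a, b, c]
    return TriangleMesh(verts, np.array(tm.faces))


class TestCranialIndex:
    def test_ellipsoid(self):
        assert cranial_index(_ellipsoid(50, 62.5, 45)) == pytest.approx(80.0, rel=1e-6)

    def test_sphere(self):
        assert cranial_index(icosphere(50.0, 2)) == pytest.approx(100.0, rel=1e-6)

    def test_elongation_scaling_law(self):
        base = _ellipsoid(50, 62.5, 45)
        longer = base.with_vertices(base.vertices * [1, 1.25, 1])
        assert cranial_index(longer) == pytest.approx(cranial_index(base) / 1.25, rel=1e-9)

    def test_invariance_scale_translation(self):
        mesh = _ellipsoid(48, 60, 44)
        ci = cranial_index(mesh)
        moved = mesh.with_vertices(mesh.vertices * 3.7 + [10, -4, 2])
        assert cranial_index(moved) == pytest.approx(ci, rel=1e-12)

    def test_zero_length_rejected(self):
        flat = TriangleMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 1]]),
                            np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            cranial_index(flat)


class TestVolume:
    def test_unit_cube(self):
        tm = trimesh.creation.box((1.0, 1.0, 1.0))
        mesh = TriangleMesh(np.array(tm.vertices), np.array(tm.faces))
        assert mesh_volume(mesh) == pytest.approx(1.0, rel=1e-12)

    def test_sphere_volume(self):
        v = mesh_volume(icosphere(10.0, 4))
        assert v == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.01)

    def test_inverted_orientation_absolute(self):
        tm = trimesh.creation.box((1.0, 1.0, 1.0))
        faces = np.array(tm.faces)[:, ::-1]
        mesh = TriangleMesh(np.array(tm.vertices), faces)
        assert mesh_volume(mesh) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("s", [0.5, 2.0, 3.1])
    def test_cubic_scaling(self, s):
        mesh = icosphere(10.0, 2)
        scaled = mesh.with_vertices(mesh.vertices * s)
        assert mesh_volume(scaled) == pytest.approx(mesh_volume(mesh) * s ** 3, rel=1e-10)

    def test_open_mesh_warns(self, skull):
        with pytest.warns(UserWarning):
            mesh_volume(skull.mesh)


class TestOffset:
    def test_sphere_inward(self):
        mesh = icosphere(50.0, 3)
        inner = offset_mesh(mesh, 3.42, "inward")
        radii = np.linalg.norm(inner.vertices, axis=1)
        assert np.abs(radii - 46.58).max() / 46.58 < 0.02

    def test_zero_distance_identity(self):
        mesh = icosphere(50.0, 2)
        out = offset_mesh(mesh, 0.0, "outward")
        np.testing.assert_array_equal(out.vertices, mesh.vertices)

    def test_roundtrip_on_smooth_mesh(self):
        mesh = icosphere(50.0, 3)
        back = offset_mesh(offset_mesh(mesh, 2.02, "inward"), 2.02, "outward")
        assert surface_distance(back, mesh).mean < 0.05

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            offset_mesh(icosphere(50.0, 1), -1.0)


class TestVolumeMatch:
    def test_cube_root_law(self):
        mesh = icosphere(20.0, 2)
        ref = icosphere(10.0, 2)     # V_mesh = 8 V_ref
        scaled = volume_match_scale(mesh, ref)
        extent = np.ptp(scaled.vertices, axis=0) / np.ptp(mesh.vertices, axis=0)
        np.testing.assert_allclose(extent, 0.5, rtol=1e-6)

    def test_identity(self):
        mesh = icosphere(10.0, 2)
        np.testing.assert_allclose(volume_match_scale(mesh, mesh.copy()).vertices,
                                   mesh.vertices, atol=1e-9)

    def test_sphere_radius_after_match(self):
        scaled = volume_match_scale(icosphere(10.0, 3), icosphere(12.0, 3))
        radii = np.linalg.norm(scaled.vertices - scaled.vertices.mean(axis=0), axis=1)
        assert radii.mean() == pytest.approx(12.0, rel=1e-3)
        assert mesh_volume(scaled) == pytest.approx(mesh_volume(icosphere(12.0, 3)), rel=1e-3)
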