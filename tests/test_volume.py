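"""Reconstruction, segmentation, meshing and the signed distance field."""

import numpy as np
import pytest

from usnav.errors import (NoObjectError, NonWatertightMeshError, OutOfFieldError)
from usnav.phantom import (NoiseModel, PhantomSpec, SweepTrajectory,
                           make_phantom, sweep_scan)
from usnav.transforms import Point3, RigidTransform, USImageGeometry
from usnav.volume import (SurfaceMesh, USFrame, Volume, brute_force_mesh_distance,
                          build_sdf, extract_surface, mesh_measures,
                          query_distance, reconstruct_volume, segment_threshold,
                          unsigned_mesh_distance)

from conftest import icosphere_mesh


def identity_frame(image, spacing=1.0, y_offset=0.0):
    geom = USImageGeometry(spacing_row=spacing, spacing_col=spacing,
                           rows=image.shape[0], cols=image.shape[1])
    kTu = RigidTransform.identity(target="K", source="U")
    cTk = RigidTransform.identity(target="C", source="K")
    nTc = RigidTransform(np.eye(3), [0.0, y_offset, 0.0], source="C", target="N")
    return USFrame(image=image, geom=geom, kTu=kTu, cTk=cTk, nTc=nTc)


class TestReconstruction:
    def test_single_frame_reproduces_image(self):
        rng = np.random.default_rng(40)
        img = rng.uniform(0, 1, (8, 6))
        vol = reconstruct_volume([identity_frame(img)], voxel=1.0)
        # frame plane: x = col, y = row, z = 0 -> occupied slab at z index 0
        occ = vol.occupied
        assert occ.sum() == img.size
        for r in range(8):
            for c in range(6):
                idx = tuple(((np.array([c, r, 0.0]) - vol.origin) / vol.spacing
                             ).round().astype(int))
                assert vol.data[idx] == pytest.approx(img[r, c])

    def test_two_parallel_frames_adjacent_slabs(self):
        img = np.ones((4, 4))
        f1 = identity_frame(img, y_offset=0.0)
        f2 = identity_frame(img, y_offset=0.0)
        # shift the second frame 1 mm along z via the aid pose
        f2 = USFrame(image=img, geom=f2.geom, kTu=f2.kTu, cTk=f2.cTk,
                     nTc=RigidTransform(np.eye(3), [0, 0, 1.0], source="C",
                                        target="N"))
        vol = reconstruct_volume([f1, f2], voxel=1.0)
        zs = np.unique(np.nonzero(vol.occupied)[2])
        assert list(zs) == [0, 1]

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_volume([], voxel=1.0)

    def test_sphere_sweep_recovers_interior(self):
        """A fan of frames through a 10 mm sphere labels >= 95% of the
        interior dark, checked against the analytic sphere."""
        ph = make_phantom(PhantomSpec(speckle_sd=0.0))
        frames = sweep_scan(ph, SweepTrajectory(-12, 12, 25), seed=41)
        vol = reconstruct_volume(frames, voxel=1.0)
        centers = (np.stack(np.meshgrid(*[np.arange(s) for s in vol.shape],
                                        indexing="ij"), axis=-1)
                   * vol.spacing + vol.origin)
        r = np.linalg.norm(centers - np.array([0, 0, 20.0]), axis=-1)
        interior = (r <= 10.0 - vol.spacing) & vol.occupied
        dark = vol.data < 0.45
        assert (dark & interior).sum() / interior.sum() >= 0.95


class TestSegmentation:
    def _sphere_volume(self, voxel=0.5):
        ph = make_phantom(PhantomSpec(speckle_sd=0.0))
        frames = sweep_scan(ph, SweepTrajectory(-14, 14, int(28 / voxel) + 1),
                            seed=42)
        return reconstruct_volume(frames, voxel=voxel)

    def test_uniform_bright_volume_has_no_object(self):
        vol = Volume(data=np.full((5, 5, 5), 0.8), spacing=1.0,
                     origin=np.zeros(3))
        with pytest.raises(NoObjectError):
            segment_threshold(vol, 0.8)

    def test_threshold_outside_range_rejected(self):
        vol = Volume(data=np.full((5, 5, 5), 0.8), spacing=1.0,
                     origin=np.zeros(3))
        with pytest.raises(ValueError):
            segment_threshold(vol, 2.0)

    def test_sphere_voxel_count_matches_analytic(self):
        vol = self._sphere_volume(voxel=0.5)
        mask = segment_threshold(vol, 0.45)
        count = mask.data.sum()
        analytic = (4 / 3) * np.pi * 10 ** 3 / 0.5 ** 3
        assert abs(count - analytic) / analytic < 0.05

    def test_largest_component_survives(self):
        data = np.full((20, 20, 20), 1.0)
        data[2:5, 2:5, 2:5] = 0.0       # 27 voxels
        data[10:16, 10:16, 10:16] = 0.0  # 216 voxels
        vol = Volume(data=data, spacing=1.0, origin=np.zeros(3))
        mask = segment_threshold(vol, 0.5)
        assert mask.data.sum() == 216
        assert mask.data[3, 3, 3] == 0


class TestSurfaceExtraction:
    def test_digitized_sphere_volume_and_centroid(self):
        # digitize a radius-10 sphere at 0.5 mm voxels around centre (0,0,20)
        ax = np.arange(-12, 12.01, 0.5)
        az = np.arange(8, 32.01, 0.5)
        X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
        mask = (X ** 2 + Y ** 2 + (Z - 20) ** 2) <= 100.0
        vol = Volume(data=mask.astype(float), spacing=0.5,
                     origin=np.array([-12.0, -12.0, 8.0]))
        mesh = extract_surface(vol)
        assert mesh.watertight
        centroid, volume, radius = mesh_measures(mesh)
        assert abs(volume - (4 / 3) * np.pi * 1000) / ((4 / 3) * np.pi * 1000) < 0.02
        assert np.linalg.norm(centroid.coordinates - [0, 0, 20]) < 0.1
        assert abs(radius - 10) / 10 < 0.02

    def test_single_voxel_closes(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        vol = Volume(data=data, spacing=1.0, origin=np.zeros(3))
        mesh = extract_surface(vol)
        assert mesh.watertight
        _, volume, _ = mesh_measures(mesh)
        assert volume > 0

    def test_empty_mask_rejected(self):
        vol = Volume(data=np.zeros((4, 4, 4)), spacing=1.0, origin=np.zeros(3))
        with pytest.raises(NoObjectError):
            extract_surface(vol)


class TestMeshMeasures:
    def test_unit_cube(self):
        import trimesh

        box = trimesh.creation.box(extents=(1, 1, 1))
        box.apply_translation([0.5, 0.5, 0.5])
        mesh = SurfaceMesh(vertices=np.asarray(box.vertices),
                           triangles=np.asarray(box.faces))
        centroid, volume, radius = mesh_measures(mesh)
        assert volume == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(centroid.coordinates, [0.5, 0.5, 0.5],
                                   atol=1e-12)
        assert radius == pytest.approx((3 / (4 * np.pi)) ** (1 / 3), abs=1e-12)

    def test_agrees_with_trimesh(self, sphere_mesh):
        import trimesh

        tm = sphere_mesh.as_trimesh()
        _, volume, _ = mesh_measures(sphere_mesh)
        assert volume == pytest.approx(tm.volume, rel=1e-10)

    def test_open_mesh_rejected_naming_edges(self, coarse_sphere_mesh):
        open_mesh = SurfaceMesh(vertices=coarse_sphere_mesh.vertices,
                                triangles=coarse_sphere_mesh.triangles[1:])
        with pytest.raises(NonWatertightMeshError, match="edge"):
            mesh_measures(open_mesh)


class TestSignedDistanceField:
    def test_sphere_analytic_values(self, sphere_sdf):
        assert query_distance(sphere_sdf, np.zeros(3)) == pytest.approx(
            -10.0, abs=0.5)
        assert query_distance(sphere_sdf, np.array([15.0, 0, 0])) == pytest.approx(
            5.0, abs=0.5)

    def test_default_margin_bounds_grid(self, sphere_mesh, sphere_sdf):
        lo = sphere_mesh.vertices.min(axis=0)
        hi = sphere_mesh.vertices.max(axis=0)
        assert np.all(sphere_sdf.origin <= lo - 10.0 + 1e-9)
        assert np.all(sphere_sdf.upper >= hi + 10.0 - 1.0)

    def test_node_and_midpoint_interpolation(self, sphere_sdf):
        node = sphere_sdf.origin + sphere_sdf.spacing * np.array([3, 4, 5])
        idx = (3, 4, 5)
        assert query_distance(sphere_sdf, node) == sphere_sdf.data[idx]
        nxt = sphere_sdf.origin + sphere_sdf.spacing * np.array([4, 4, 5])
        mid = 0.5 * (node + nxt)
        expect = 0.5 * (sphere_sdf.data[3, 4, 5] + sphere_sdf.data[4, 4, 5])
        assert query_distance(sphere_sdf, mid) == pytest.approx(expect, abs=1e-12)

    def test_brute_force_oracle_agreement(self, coarse_sphere_mesh):
        sdf = build_sdf(coarse_sphere_mesh, voxel=1.0, margin=10.0)
        rng = np.random.default_rng(43)
        pts = rng.uniform(-14, 14, (200, 3))
        oracle = brute_force_mesh_distance(pts, coarse_sphere_mesh)
        got = np.abs(np.array([query_distance(sdf, p) for p in pts]))
        assert np.abs(got - oracle).max() <= 1.0  # one voxel

    def test_broadphase_matches_brute_force_exactly(self, coarse_sphere_mesh):
        rng = np.random.default_rng(44)
        pts = rng.uniform(-15, 15, (100, 3))
        fast = unsigned_mesh_distance(pts, coarse_sphere_mesh)
        slow = brute_force_mesh_distance(pts, coarse_sphere_mesh)
        assert np.abs(fast - slow).max() < 1e-9

    def test_gradient_magnitude_near_one(self, sphere_sdf):
        g = np.gradient(sphere_sdf.data, sphere_sdf.spacing)
        gm = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
        sel = np.abs(sphere_sdf.data) < 8.0  # away from centre medial point
        p5, p95 = np.percentile(gm[sel], [5, 95])
        assert 0.9 <= p5 and p95 <= 1.1

    def test_out_of_grid_query_is_an_error(self, sphere_sdf):
        with pytest.raises(OutOfFieldError):
            query_distance(sphere_sdf, np.array([100.0, 0, 0]))

    def test_open_mesh_rejected(self, coarse_sphere_mesh):
        open_mesh = SurfaceMesh(vertices=coarse_sphere_mesh.vertices,
                                triangles=coarse_sphere_mesh.triangles[:-1])
        with pytest.raises(NonWatertightMeshError):
            build_sdf(open_mesh, voxel=1.0)


class TestSerialization:
    def test_metaimage_roundtrip(self, tmp_path):
        rng = np.random.default_rng(45)
        vol = Volume(data=rng.uniform(0, 1, (6, 7, 8)), spacing=0.5,
                     origin=np.array([-1.0, 2.0, 3.0]))
        path = tmp_path / "vol.mha"
        vol.save_mhd(path)
        back = Volume.load_mhd(path)
        np.testing.assert_allclose(back.data, vol.data)
        assert back.spacing == vol.spacing
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_sdf_roundtrip_with_sidecar(self, tmp_path, coarse_sphere_mesh):
        sdf = build_sdf(coarse_sphere_mesh, voxel=2.0, margin=10.0)
        path = tmp_path / "field.mha"
        sdf.save(path)
        back = type(sdf).load(path)
        np.testing.assert_allclose(back.data, sdf.data)
        assert back.margin == 10.0

    def test_mesh_stl_and_ply_roundtrip(self, tmp_path, coarse_sphere_mesh):
        for ext in ("stl", "ply"):
            path = tmp_path / f"m.{ext}"
            coarse_sphere_mesh.save(path)
            back = SurfaceMesh.load(path)
            _, v1, _ = mesh_measures(coarse_sphere_mesh)
            _, v2, _ = mesh_measures(back)
            assert v2 == pytest.approx(v1, rel=1e-5)
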