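"""Rigid-transform algebra, projection and the coordinate chains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usnav.errors import BehindCameraError, FrameMismatchError
from usnav.transforms import (CameraModel, Point3, RigidTransform,
                              USImageGeometry, compose, instrument_to_aid,
                              invert, project, transform_point, us_pixel_to_aid)


def random_transform(rng, source="B", target="A"):
    return RigidTransform.random(rng, source=source, target=target)


class TestCompose:
    def test_identity_relabels_frames(self):
        rng = np.random.default_rng(0)
        T = random_transform(rng, source="C", target="B")
        out = compose(RigidTransform.identity(target="A", source="B"), T)
        assert out.source == "C" and out.target == "A"
        np.testing.assert_allclose(out.as_matrix(), T.as_matrix(), atol=1e-15)

    def test_pure_translations_add(self):
        T1 = RigidTransform(np.eye(3), [1, 0, 0], source="B", target="A")
        T2 = RigidTransform(np.eye(3), [0, 2, 0], source="C", target="B")
        out = compose(T1, T2)
        np.testing.assert_allclose(out.translation, [1, 2, 0])

    def test_matches_homogeneous_matrix_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            A = random_transform(rng, source="B", target="A")
            B = random_transform(rng, source="C", target="B")
            oracle = A.as_matrix() @ B.as_matrix()
            assert np.abs(compose(A, B).as_matrix() - oracle).max() < 1e-12

    def test_frame_mismatch_names_both_transforms(self):
        rng = np.random.default_rng(2)
        A = random_transform(rng, source="B", target="A")
        C = random_transform(rng, source="D", target="C")
        with pytest.raises(FrameMismatchError, match="A<-B.*C<-D"):
            compose(A, C)

    def test_associativity(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            A = random_transform(rng, source="B", target="A")
            B = random_transform(rng, source="C", target="B")
            C = random_transform(rng, source="D", target="C")
            left = compose(compose(A, B), C).as_matrix()
            right = compose(A, compose(B, C)).as_matrix()
            assert np.abs(left - right).max() < 1e-12


class TestInvert:
    def test_identity(self):
        T = RigidTransform.identity(target="A", source="A")
        np.testing.assert_allclose(invert(T).as_matrix(), np.eye(4))

    def test_pure_translation_negates(self):
        T = RigidTransform(np.eye(3), [1, 2, 3], source="B", target="A")
        np.testing.assert_allclose(invert(T).translation, [-1, -2, -3])
        assert invert(T).source == "A" and invert(T).target == "B"

    def test_matches_matrix_inverse_and_roundtrips(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            T = random_transform(rng)
            oracle = np.linalg.inv(T.as_matrix())
            assert np.abs(invert(T).as_matrix() - oracle).max() < 1e-12
            rt = compose(T, invert(T)).as_matrix()
            assert np.abs(rt - np.eye(4)).max() < 1e-12


class TestTransformPoint:
    def test_identity_and_rotation(self):
        p = Point3([1.0, 0.0, 0.0], frame="B")
        I = RigidTransform.identity(target="A", source="B")
        np.testing.assert_allclose(transform_point(I, p).coordinates, [1, 0, 0])
        Rz = RigidTransform([[0, -1, 0], [1, 0, 0], [0, 0, 1]], [0, 0, 0],
                            source="B", target="A")
        np.testing.assert_allclose(transform_point(Rz, p).coordinates, [0, 1, 0],
                                   atol=1e-15)

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            T = random_transform(rng)
            x = rng.uniform(-50, 50, 3)
            oracle = (T.as_matrix() @ np.append(x, 1.0))[:3]
            got = transform_point(T, Point3(x, frame="B")).coordinates
            assert np.abs(got - oracle).max() < 1e-12

    def test_frame_mismatch(self):
        T = RigidTransform.identity(target="A", source="B")
        with pytest.raises(FrameMismatchError):
            transform_point(T, Point3([0, 0, 0], frame="C"))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigidity_preserves_distances(self, seed):
        rng = np.random.default_rng(seed)
        T = random_transform(rng)
        p, q = rng.uniform(-100, 100, (2, 3))
        before = np.linalg.norm(p - q)
        after = np.linalg.norm(T.apply(p) - T.apply(q))
        assert abs(before - after) < 1e-9


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, width=1000, height=1000)
        u, v = project(cam, Point3([0, 0, 37.0], frame="C"))
        assert (u, v) == (500.0, 500.0)

    def test_pinhole_arithmetic(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, width=1024, height=1024)
        u, v = project(cam, Point3([0.01, 0.0, 1.0], frame="C"))
        np.testing.assert_allclose([u, v], [510.0, 500.0])

    def test_distortion_matches_direct_polynomial(self):
        cam = CameraModel(fx=900, fy=950, cx=640, cy=360, k1=-0.2, k2=0.05,
                          p1=1e-3, p2=-5e-4, width=1280, height=720)
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = np.append(rng.uniform(-20, 20, 2), rng.uniform(40, 120))
            x, y = p[0] / p[2], p[1] / p[2]
            r2 = x * x + y * y
            rad = 1 + cam.k1 * r2 + cam.k2 * r2 ** 2
            xd = x * rad + 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
            yd = y * rad + cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
            expect = (cam.fx * xd + cam.cx, cam.fy * yd + cam.cy)
            got = project(cam, Point3(p, frame="C"))
            np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_behind_camera_is_an_error(self):
        cam = CameraModel(fx=1000, fy=1000, cx=500, cy=500, width=1000, height=1000)
        with pytest.raises(BehindCameraError):
            project(cam, Point3([0, 0, -1.0], frame="C"))

    def test_undistort_inverts_distort(self):
        cam = CameraModel(fx=900, fy=950, cx=640, cy=360, k1=-0.2, k2=0.05,
                          width=1280, height=720)
        xy = np.random.default_rng(7).uniform(-0.3, 0.3, (40, 2))
        back = cam.undistort(cam.distort(xy))
        assert np.abs(back - xy).max() < 1e-10


class TestChains:
    geom = USImageGeometry(spacing_row=1.0, spacing_col=1.0, rows=10, cols=10)

    def _identity_chain(self):
        return (RigidTransform.identity(target="K", source="U"),
                RigidTransform.identity(target="C", source="K"),
                RigidTransform.identity(target="N", source="C"))

    def test_identity_chain_pixel_convention(self):
        kTu, cTk, nTc = self._identity_chain()
        p = us_pixel_to_aid((2, 3), self.geom, kTu, cTk, nTc)
        # (row, col) -> (x = col * spacing, y = row * spacing, 0)
        np.testing.assert_allclose(p.coordinates, [3.0, 2.0, 0.0])
        assert p.frame == "N"

    def test_translation_chain_adds(self):
        kTu = RigidTransform(np.eye(3), [1, 0, 0], source="U", target="K")
        cTk = RigidTransform(np.eye(3), [0, 2, 0], source="K", target="C")
        nTc = RigidTransform(np.eye(3), [0, 0, 3], source="C", target="N")
        p = us_pixel_to_aid((0, 0), self.geom, kTu, cTk, nTc)
        np.testing.assert_allclose(p.coordinates, [1.0, 2.0, 3.0])

    def test_random_chain_matches_matrix_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            kTu = random_transform(rng, source="U", target="K")
            cTk = random_transform(rng, source="K", target="C")
            nTc = random_transform(rng, source="C", target="N")
            pix = (rng.integers(0, 10), rng.integers(0, 10))
            M = nTc.as_matrix() @ cTk.as_matrix() @ kTu.as_matrix()
            plane = np.array([pix[1] * 1.0, pix[0] * 1.0, 0.0, 1.0])
            oracle = (M @ plane)[:3]
            got = us_pixel_to_aid(pix, self.geom, kTu, cTk, nTc).coordinates
            assert np.abs(got - oracle).max() < 1e-9

    def test_out_of_bounds_pixel(self):
        kTu, cTk, nTc = self._identity_chain()
        with pytest.raises(ValueError):
            us_pixel_to_aid((11, 0), self.geom, kTu, cTk, nTc)

    def test_instrument_chain(self):
        rng = np.random.default_rng(9)
        lTi = random_transform(rng, source="I", target="L")
        cTl = random_transform(rng, source="L", target="C")
        nTc = random_transform(rng, source="C", target="N")
        p = rng.uniform(-30, 30, 3)
        M = nTc.as_matrix() @ cTl.as_matrix() @ lTi.as_matrix()
        oracle = (M @ np.append(p, 1.0))[:3]
        got = instrument_to_aid(Point3(p, frame="I"), lTi, cTl, nTc)
        assert got.frame == "N"
        assert np.abs(got.coordinates - oracle).max() < 1e-9

    def test_identity_instrument_chain(self):
        lTi = RigidTransform.identity(target="L", source="I")
        cTl = RigidTransform.identity(target="C", source="L")
        nTc = RigidTransform.identity(target="N", source="C")
        p = instrument_to_aid(Point3([1, 2, 3], frame="I"), lTi, cTl, nTc)
        np.testing.assert_allclose(p.coordinates, [1, 2, 3])


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        T = random_transform(rng, source="L", target="C")
        path = tmp_path / "cTl.json"
        T.save(path)
        back = RigidTransform.load(path)
        assert back.source == "L" and back.target == "C"
        np.testing.assert_allclose(back.as_matrix(), T.as_matrix(), atol=1e-12)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
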