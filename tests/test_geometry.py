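"""Voxel-to-world affines, rigid-transform algebra, and mask resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navseg import (
    GeometryError,
    GridSpec,
    RigidTransform,
    affine_from_dicom_geometry,
    apply_to_points,
    compose,
    resample_mask,
)
from navseg.masks import mask_volume

from conftest import make_cube_mask


def random_rigid(seed: int) -> RigidTransform:
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    r = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    return RigidTransform.from_rotation_translation(r, rng.uniform(-20, 20, 3))


class TestDicomAffine:
    def test_identity_geometry_gives_identity_affine(self):
        a = affine_from_dicom_geometry((1, 0, 0, 0, 1, 0), (0, 0, 0), (1, 1), 1.0, +1)
        np.testing.assert_allclose(a, np.eye(4))

    def test_diagonal_scaling_and_translation(self):
        a = affine_from_dicom_geometry(
            (1, 0, 0, 0, 1, 0), (10, 20, 30), (0.5, 0.5), 2.0, +1
        )
        expected = np.diag([0.5, 0.5, 2.0, 1.0])
        expected[:3, 3] = (10, 20, 30)
        np.testing.assert_allclose(a, expected)

    def test_swapped_axes_flip_slice_normal(self):
        # cross((0,1,0),(1,0,0)) = (0,0,-1): hand-checked oracle
        a = affine_from_dicom_geometry((0, 1, 0, 1, 0, 0), (0, 0, 0), (1, 1), 2.0, +1)
        np.testing.assert_allclose(a[:3, 2], (0, 0, -2.0))
        np.testing.assert_allclose(a[:3, 0], (0, 1, 0))
        np.testing.assert_allclose(a[:3, 1], (1, 0, 0))

    def test_non_unit_orientation_rejected(self):
        with pytest.raises(GeometryError):
            affine_from_dicom_geometry((2, 0, 0, 0, 1, 0), (0, 0, 0), (1, 1), 1.0)

    def test_non_orthogonal_orientation_rejected(self):
        v = 1 / np.sqrt(2)
        with pytest.raises(GeometryError):
            affine_from_dicom_geometry((1, 0, 0, v, v, 0), (0, 0, 0), (1, 1), 1.0)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            affine_from_dicom_geometry((1, 0, 0, 0, 1, 0), (0, 0, 0), (1, -1), 1.0)
        with pytest.raises(ValueError):
            affine_from_dicom_geometry((1, 0, 0, 0, 1, 0), (0, 0, 0), (1, 1), 0.0)


class TestRigidTransform:
    def test_invariants_enforced(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(GeometryError):
            RigidTransform(bad)
        reflect = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(GeometryError):
            RigidTransform(reflect)

    def test_compose_identities(self):
        eye = RigidTransform.identity()
        np.testing.assert_allclose(compose([eye, eye]).matrix, np.eye(4))

    def test_compose_with_inverse_is_identity(self):
        t = random_rigid(3)
        np.testing.assert_allclose(compose([t, t.inverse()]).matrix, np.eye(4), atol=1e-9)

    def test_translations_commute_and_add(self):
        t1 = RigidTransform.from_rotation_translation(np.eye(3), (1, 0, 0))
        t2 = RigidTransform.from_rotation_translation(np.eye(3), (0, 2, 0))
        np.testing.assert_allclose(compose([t1, t2]).translation, (1, 2, 0))

    def test_compose_empty_rejected(self):
        with pytest.raises(ValueError):
            compose([])

    @pytest.mark.parametrize("seeds", [(1, 2, 3), (4, 5, 6), (7, 8, 9)])
    def test_compose_is_associative(self, seeds):
        a, b, c = (random_rigid(s) for s in seeds)
        left = compose([a, compose([b, c])])
        right = compose([compose([a, b]), c])
        np.testing.assert_allclose(left.matrix, right.matrix, atol=1e-9)

    def test_compose_matches_elementwise_application(self):
        chain = [random_rigid(s) for s in (10, 11, 12)]
        pts = np.random.default_rng(0).uniform(-30, 30, (8, 3))
        stepwise = pts
        for t in chain:
            stepwise = apply_to_points(t, stepwise)
        np.testing.assert_allclose(apply_to_points(compose(chain), pts), stepwise, atol=1e-9)


class TestApplyToPoints:
    def test_identity_and_translation(self):
        pts = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(apply_to_points(RigidTransform.identity(), pts), pts)
        t = RigidTransform.from_rotation_translation(np.eye(3), (4, 5, 6))
        np.testing.assert_allclose(apply_to_points(t, [[0, 0, 0]]), [[4, 5, 6]])

    def test_quarter_turn_about_z(self):
        t = RigidTransform.from_euler_deg((0, 0, 90))
        np.testing.assert_allclose(apply_to_points(t, [[1, 0, 0]]), [[0, 1, 0]], atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_rigidity_preserves_pairwise_distances(self, seed):
        t = random_rigid(seed)
        pts = np.random.default_rng(seed).uniform(-50, 50, (10, 3))
        out = apply_to_points(t, pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_nonfinite_points_rejected(self):
        with pytest.raises(ValueError):
            apply_to_points(RigidTransform.identity(), [[np.nan, 0, 0]])


class TestResampleMask:
    def test_identity_onto_same_grid_is_bit_exact(self, cube_mask):
        out = resample_mask(cube_mask, RigidTransform.identity(), cube_mask.geometry)
        assert np.array_equal(out.data, cube_mask.data)
        assert out.geometry.same_geometry(cube_mask.geometry)

    def test_one_voxel_translation_shifts_without_wrap(self, unit_grid, cube_mask):
        t = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 1))  # +1 mm = +1 voxel
        out = resample_mask(cube_mask, t, unit_grid)
        expected = np.zeros(unit_grid.shape, dtype=bool)
        expected[5:13, 5:13, 6:14] = True  # index-shift oracle
        assert np.array_equal(out.data, expected)

    def test_translation_off_grid_end_is_clipped_not_wrapped(self, unit_grid):
        edge = make_cube_mask(unit_grid, (0, 0, 18), (3, 3, 20))
        t = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 3))
        out = resample_mask(edge, t, unit_grid)
        assert out.data[:, :, :3].sum() == 0  # nothing wrapped to the start
        assert out.data.sum() == 0  # fully shifted off the grid

    def test_upsampling_preserves_volume_within_one_source_voxel(self, cube_mask):
        fine = GridSpec(shape=(40, 40, 40), spacing=(0.5, 0.5, 0.5), origin=(-0.25, -0.25, -0.25))
        out = resample_mask(cube_mask, RigidTransform.identity(), fine)
        assert abs(mask_volume(out) - mask_volume(cube_mask)) <= cube_mask.geometry.voxel_volume_mm3 / 1000.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_round_trip_recovers_interior_foreground(self, seed):
        """Resampling under T then inverse(T) keeps >= 99% of the foreground.

        The mask sits well away from the grid border and is large enough that
        the one-voxel nearest-neighbour jitter at the surface stays below 1%.
        """
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation

        grid = GridSpec(shape=(30, 30, 30), spacing=(1, 1, 1), origin=(0, 0, 0))
        mask = make_cube_mask(grid, (8, 8, 8), (22, 22, 22))  # 14^3, 8 voxels off-border
        r = Rotation.from_euler("xyz", rng.uniform(-5, 5, 3), degrees=True).as_matrix()
        t = RigidTransform.from_rotation_translation(r, rng.uniform(-2, 2, 3))
        big = GridSpec(shape=(60, 60, 60), spacing=(1, 1, 1), origin=(-15, -15, -15))
        there = resample_mask(mask, t, big)
        back = resample_mask(there, t.inverse(), grid)
        recovered = (back.data & mask.data).sum() / mask.data.sum()
        assert recovered >= 0.99

    def test_resample_agrees_with_simpleitk(self, cube_mask):
        """Independent oracle: SimpleITK nearest-neighbour resampling."""
        sitk = pytest.importorskip("SimpleITK")
        t = RigidTransform.from_euler_deg((2, -3, 4), (1.2, -0.7, 2.4))
        dest = GridSpec(shape=(24, 24, 24), spacing=(1, 1, 1), origin=(-2, -2, -2))
        ours = resample_mask(cube_mask, t, dest)

        img = sitk.GetImageFromArray(cube_mask.data.astype(np.uint8))
        # our array axes are (slice,row,col) = sitk (z,y,x); spacing/origin reversed
        img.SetSpacing(tuple(cube_mask.geometry.spacing[::-1]))
        img.SetOrigin(tuple(cube_mask.geometry.origin[::-1]))
        st_t = sitk.AffineTransform(3)
        inv = t.inverse()
        # sitk transforms map destination to source; axes x,y,z = our reversed
        p = np.eye(3)[::-1]
        rot_xyz = p @ inv.rotation @ p
        st_t.SetMatrix(rot_xyz.ravel())
        st_t.SetTranslation(tuple(inv.translation[::-1]))
        ref = sitk.Image(*[int(s) for s in dest.shape[::-1]], sitk.sitkUInt8)
        ref.SetSpacing(tuple(dest.spacing[::-1]))
        ref.SetOrigin(tuple(dest.origin[::-1]))
        out = sitk.Resample(img, ref, st_t, sitk.sitkNearestNeighbor, 0)
        theirs = sitk.GetArrayFromImage(out).astype(bool)
        # voxels whose pull-back lands within 1e-6 of a cell boundary may round
        # differently; demand near-perfect agreement
        disagree = np.logical_xor(ours.data, theirs).sum()
        assert disagree / max(ours.data.sum(), 1) < 0.02

    def test_zero_extent_destination_rejected(self, cube_mask):
        with pytest.raises(ValueError):
            GridSpec(shape=(0, 5, 5), spacing=(1, 1, 1), origin=(0, 0, 0))


class TestGridSpec:
    def test_metadata_invariants_enforced(self):
        with pytest.raises(ValueError):
            GridSpec(shape=(5, 5, 5), spacing=(1, 0, 1), origin=(0, 0, 0))
        with pytest.raises(GeometryError):
            GridSpec(shape=(5, 5, 5), spacing=(1, 1, 1), origin=(0, 0, 0), direction=np.ones((3, 3)))

    def test_voxel_world_round_trip(self):
        g = GridSpec(
            shape=(8, 9, 10),
            spacing=(1.5, 0.5, 2.0),
            origin=(3, -4, 5),
            direction=np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=float).T,
        )
        idx = np.array([[0, 0, 0], [3, 4, 5], [7, 8, 9]], dtype=float)
        np.testing.assert_allclose(g.world_to_voxel(g.voxel_to_world(idx)), idx, atol=1e-12)
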