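"""Centroids, inertia frames, sagittal correction and the disk measures,
checked against closed forms and ground-truth phantoms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import digitize
from discmorph.geometry import (DiscFrame, Plane, build_disc_frame,
                                cross_sectional_area, disc_height,
                                mask_centroid, mask_volume, nucleus_offset,
                                orient_axes, patient_sagittal_plane,
                                principal_axes, slenderness)
from discmorph.io import directions_from_axcodes
from discmorph.phantom import sample_disc_params
from discmorph.validation import measure_single_disc, random_rotation

LAS = directions_from_axcodes(("L", "A", "S"))
SP = (0.5, 0.5, 0.5)


def _axis_aligned_frame(origin=(0.0, 0.0, 0.0)):
    return DiscFrame(origin=np.asarray(origin),
                     x=np.array([1.0, 0, 0]), y=np.array([0, 1.0, 0]),
                     z=np.array([0, 0, 1.0]))


class TestCentroidAndVolume:
    def test_single_voxel_is_its_centre(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = True
        assert np.allclose(mask_centroid(m, (1, 1, 1)), (0, 0, 0))

    def test_cuboid_centroid_and_volume(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[2:12, 1:11, 3:8] = True
        assert np.allclose(mask_centroid(m, (1, 1, 1)), (6.5, 5.5, 5.0))
        assert mask_volume(m, (1, 1, 1)) == pytest.approx(500.0)

    def test_hemisphere_centroid_closed_form(self):
        # flat face at z=0, dome upward: centroid at 3R/8 above the face
        R = 20.0
        m, c = digitize(lambda x, y, z: (x**2 + y**2 + z**2 <= R**2) & (z >= 0),
                        SP, R + 1)
        got = mask_centroid(m, SP) - c
        assert got[2] == pytest.approx(3 * R / 8, rel=0.01)
        assert abs(got[0]) < 0.1 and abs(got[1]) < 0.1

    def test_digitized_sphere_volume(self):
        r = 10.0
        m, _ = digitize(lambda x, y, z: x**2 + y**2 + z**2 <= r**2,
                        (0.25, 0.25, 0.25), r + 1)
        assert mask_volume(m, (0.25,) * 3) == pytest.approx(4 / 3 * np.pi * r**3,
                                                            rel=0.01)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mask_volume(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            mask_centroid(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestPrincipalAxes:
    def test_axis_aligned_ellipsoid(self):
        a, b, c = 15.0, 10.0, 4.0
        m, _ = digitize(lambda x, y, z: (x/a)**2 + (y/b)**2 + (z/c)**2 <= 1,
                        SP, 16.0)
        pa = principal_axes(m, SP)
        assert not pa.degenerate
        for row, e in zip(pa.axes, np.eye(3)):
            ang = np.degrees(np.arccos(min(1.0, abs(np.dot(row, e)))))
            assert ang < 1.0
        # spectral oracle: central moments of a solid ellipsoid are
        # diag(a^2, b^2, c^2) / 5
        assert np.allclose(pa.moments, np.array([a, b, c]) ** 2 / 5, rtol=0.01)

    def test_cube_is_degenerate(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[4:16, 4:16, 4:16] = True
        assert principal_axes(m, (1, 1, 1)).degenerate

    def test_rotation_equivariance(self):
        a, b, c = 15.0, 10.0, 4.0
        R = Rotation.from_euler("xyz", (12, -8, 25), degrees=True).as_matrix()

        def rotated(x, y, z):
            pts = np.stack([x, y, z], axis=-1) @ R  # world -> body coords
            return ((pts[..., 0]/a)**2 + (pts[..., 1]/b)**2
                    + (pts[..., 2]/c)**2 <= 1)

        m0, _ = digitize(lambda x, y, z: (x/a)**2 + (y/b)**2 + (z/c)**2 <= 1,
                         SP, 16.0)
        m1, _ = digitize(rotated, SP, 16.0)
        ax0 = principal_axes(m0, SP).axes
        ax1 = principal_axes(m1, SP).axes
        for i in range(3):
            expect = R @ ax0[i]
            ang = np.degrees(np.arccos(min(1.0, abs(np.dot(ax1[i], expect)))))
            assert ang < 2.0

    def test_too_few_voxels(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        with pytest.raises(ValueError, match="4 voxels"):
            principal_axes(m, (1, 1, 1))


class TestOrientAxes:
    def test_anatomical_axes_fixed_point(self):
        axes = np.eye(3)  # rows: x (largest), y, z (smallest extent)
        x, y, z = orient_axes(axes, LAS)
        assert np.allclose(x, [1, 0, 0]) and np.allclose(y, [0, 1, 0])
        assert np.allclose(z, [0, 0, 1])

    def test_anticranial_z_flipped(self):
        axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, -1.0]])
        _, _, z = orient_axes(axes, LAS)
        assert np.allclose(z, [0, 0, 1])

    def test_property_sweep_within_30_deg(self, rng):
        """Any right-handed frame within 30 deg of anatomical orients to a
        valid right-handed triad with z cranial and y anterior."""
        for _ in range(200):
            R = random_rotation(rng, 30.0)
            axes = R.T  # rows are the rotated basis vectors
            x, y, z = orient_axes(axes, LAS)
            assert np.dot(z, LAS.cranial) > 0
            assert np.dot(y, LAS.anterior) > 0
            assert np.dot(np.cross(x, y), z) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_tilt_errors(self):
        axes = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])  # z->anterior
        with pytest.raises(ValueError, match="orthogonal"):
            orient_axes(axes, LAS)


class TestSagittalPlane:
    def _centroids(self, n=17, posterior_shift=None):
        # straight cranio-caudal stack in grid coords; y is anterior
        cents = {k: np.array([10.0, 20.0, 100.0 - 5.0 * k]) for k in range(1, n + 1)}
        if posterior_shift:
            lvl, mm = posterior_shift
            cents[lvl] = cents[lvl] + np.array([0.0, -mm, 0.0])
        return cents

    def test_plane_contains_defining_centroids(self):
        cents = self._centroids(posterior_shift=(7, 5.0))
        plane = patient_sagittal_plane(cents, LAS)
        for k in (1, 13, 7):
            assert abs(plane.signed_distance(cents[k])) < 1e-9

    def test_collinear_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            patient_sagittal_plane(self._centroids(), LAS)

    def test_posterior_tiebreak_skips_anchors(self):
        # most posterior is L1 itself -> second-most posterior must be used
        cents = self._centroids(posterior_shift=(13, 5.0))
        cents[9] = cents[9] + np.array([0.0, -2.0, 0.0])
        plane = patient_sagittal_plane(cents, LAS)
        assert abs(plane.signed_distance(cents[9])) < 1e-9

    def test_normal_points_left(self):
        cents = self._centroids(posterior_shift=(7, 5.0))
        plane = patient_sagittal_plane(cents, LAS)
        assert np.dot(plane.normal, LAS.left) > 0

    def test_recovers_posed_plane(self, table):
        """Axially rotated spine: the recovered plane normal tracks the
        posed left-right axis within a degree."""
        from discmorph.phantom import PhantomSpec, generate_phantom
        from discmorph.io import LabelSchema, extract_disc_masks

        spec = PhantomSpec(age_years=10.0, sex="M", pose_deg=(0, 0, 10), seed=5)
        vol, truths = generate_phantom(table, spec)
        pairs = extract_disc_masks(vol, LabelSchema.default())
        cents = {p.level_index: mask_centroid(p.af_mask, vol.spacing_mm)
                 for p in pairs}
        plane = patient_sagittal_plane(cents, vol.directions())
        true_normal = truths[0].frame_true.x
        ang = np.degrees(np.arccos(min(1.0, abs(np.dot(plane.normal, true_normal)))))
        assert ang < 1.0


class TestDiscFrameConstruction:
    def test_zero_rotation_when_y_in_plane(self, table):
        truth = sample_disc_params(table, 12.0, "M", 6)
        from discmorph.phantom import rasterize_single_disc, true_sagittal_plane
        vol, posed = rasterize_single_disc(truth, SP)
        frame = build_disc_frame(vol.data > 0, SP, true_sagittal_plane(posed),
                                 vol.directions())
        assert abs(np.dot(frame.y, posed.frame_true.x)) < 1e-6  # y in plane
        ang = np.degrees(np.arccos(min(1.0, np.dot(frame.y, posed.frame_true.y))))
        assert ang < 2.0

    def test_yaw_recovered_by_sagittal_correction(self, table):
        truth = sample_disc_params(table, 12.0, "M", 15)
        from discmorph.phantom import rasterize_single_disc, true_sagittal_plane
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        vol, posed = rasterize_single_disc(truth, SP, rotation=rot)
        frame = build_disc_frame(vol.data > 0, SP, true_sagittal_plane(posed),
                                 vol.directions())
        ang = np.degrees(np.arccos(min(1.0, np.dot(frame.y, posed.frame_true.y))))
        assert ang < 2.0

    def test_y_kept_anterior(self, table):
        truth = sample_disc_params(table, 12.0, "M", 6)
        from discmorph.phantom import rasterize_single_disc, true_sagittal_plane
        vol, posed = rasterize_single_disc(truth, SP)
        frame = build_disc_frame(vol.data > 0, SP, true_sagittal_plane(posed),
                                 vol.directions())
        assert np.dot(frame.y, LAS.anterior) > 0


class TestMeasures:
    def _cylinder(self, a=15.0, b=10.0, h=8.0, spacing=SP):
        m, c = digitize(lambda x, y, z: ((x/a)**2 + (y/b)**2 <= 1)
                        & (np.abs(z) <= h/2), spacing, 19.0)
        return m, c

    def test_height_of_axis_aligned_cylinder(self):
        m, c = self._cylinder()
        f = _axis_aligned_frame(c)
        assert disc_height(m, SP, f) == pytest.approx(8.0, abs=0.25)

    def test_height_bounded_by_diameter(self):
        m, c = self._cylinder()
        f = _axis_aligned_frame(c)
        assert disc_height(m, SP, f) <= 2 * np.sqrt(15**2 + 10**2 + 4**2)

    def test_csa_of_elliptic_cylinder(self):
        m, c = self._cylinder()
        f = _axis_aligned_frame(c)
        assert cross_sectional_area(m, SP, f) == pytest.approx(np.pi * 150,
                                                               rel=0.02)

    def test_height_and_csa_rotation_invariant(self, table):
        truth = sample_disc_params(table, 14.0, "M", 15)
        base = measure_single_disc(truth, SP)
        rot = Rotation.from_euler("x", 15, degrees=True).as_matrix()
        rec = measure_single_disc(truth, SP, rotation=rot)
        assert rec.height_mm == pytest.approx(base.height_mm, rel=0.02)
        assert rec.csa_mm2 == pytest.approx(base.csa_mm2, rel=0.02)

    def test_slenderness_formula_and_scale_invariance(self):
        assert slenderness(5.0, 400.0) == pytest.approx(0.25)
        assert slenderness(10.0, 100.0) == pytest.approx(1.0)
        lam = 3.7
        assert slenderness(5.0 * lam, 400.0 * lam**2) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            slenderness(-1.0, 10.0)

    def test_concentric_nucleus_offset_is_zero(self, table):
        from dataclasses import replace
        truth = replace(sample_disc_params(table, 12.0, "F", 6),
                        np_offset_mm=(0.0, 0.0, 0.0))
        rec = measure_single_disc(truth, SP)
        assert np.all(np.abs(rec.offset_mm) < 0.15)

    def test_anterior_shift_recovered(self, table):
        from dataclasses import replace
        truth = replace(sample_disc_params(table, 14.0, "M", 15),
                        np_offset_mm=(0.0, 2.0, 0.0))
        rec = measure_single_disc(truth, SP)
        assert rec.offset_mm[1] == pytest.approx(2.0, abs=0.2)
        assert abs(rec.offset_mm[0]) < 0.2 and abs(rec.offset_mm[2]) < 0.2

    def test_offset_rotation_invariant(self, table, rng):
        from dataclasses import replace
        truth = replace(sample_disc_params(table, 14.0, "M", 15),
                        np_offset_mm=(0.0, 1.5, 0.0))
        base = np.array(measure_single_disc(truth, SP).offset_mm)
        rec = np.array(measure_single_disc(
            truth, SP, rotation=random_rotation(rng, 20.0)).offset_mm)
        assert np.all(np.abs(rec - base) < 0.2)

    def test_volume_additivity_exact(self, table):
        rec = measure_single_disc(sample_disc_params(table, 9.0, "F", 11), SP)
        assert rec.v_ivd_mm3 == rec.v_af_mm3 + rec.v_np_mm3
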