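"""Registration stack: similarity alignment, mutual information,
B-spline deformation recovery and transform application."""

import numpy as np
import pytest

from lamina import register as rg
from lamina import synthdata as sd
from lamina.images import image_array


class TestRigidAlignTwoPoint:
    def test_identical_points_give_identity(self, reference_image):
        pts = [(10.0, 10.0), (50.0, 80.0)]
        _, t = rg.rigid_align_two_point(reference_image, pts, pts)
        assert t.angle == pytest.approx(0.0, abs=1e-12)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(t.translation, (0.0, 0.0), atol=1e-9)

    def test_pure_shift_recovered(self, reference_image):
        src = [(5.0, 5.0), (20.0, 30.0)]
        dst = [(10.0, 8.0), (25.0, 33.0)]
        _, t = rg.rigid_align_two_point(reference_image, src, dst)
        assert np.allclose(t.translation, (5.0, 3.0), atol=1e-9)
        assert t.scale == pytest.approx(1.0)

    def test_doubled_separation_gives_scale_two(self, reference_image):
        # solving the 2-point similarity equations by hand: same orientation,
        # separations 10 and 20 px -> scale exactly 2
        src = [(10.0, 10.0), (10.0, 20.0)]
        dst = [(10.0, 10.0), (10.0, 30.0)]
        _, t = rg.rigid_align_two_point(reference_image, src, dst)
        assert t.scale == pytest.approx(2.0)
        assert t.angle == pytest.approx(0.0, abs=1e-12)

    def test_landmarks_map_exactly(self, reference_image):
        src = np.array([(12.0, 40.0), (70.0, 110.0)])
        dst = np.array([(20.0, 44.0), (66.0, 140.0)])
        _, t = rg.rigid_align_two_point(reference_image, src, dst)
        assert np.allclose(t.apply_points(src), dst, atol=1e-9)

    def test_coincident_points_rejected(self, reference_image):
        with pytest.raises(ValueError):
            rg.rigid_align_two_point(reference_image,
                                     [(5.0, 5.0), (5.0, 5.0)],
                                     [(1.0, 1.0), (2.0, 2.0)])

    def test_inverse_composes_to_identity_on_frame_corners(self, reference_image):
        src = [(5.0, 5.0), (40.0, 90.0)]
        dst = [(9.0, 2.0), (50.0, 80.0)]
        _, t = rg.rigid_align_two_point(reference_image, src, dst)
        corners = np.array([(0.0, 0.0), (0.0, 299.0), (224.0, 0.0),
                            (224.0, 299.0)])
        back = t.inverse().apply_points(t.apply_points(corners))
        assert np.abs(back - corners).max() < 1e-9


class TestMutualInformation:
    @pytest.mark.parametrize("bins", [8, 32, 64, 256])
    def test_self_information_equals_entropy(self, reference_image, bins):
        arr = image_array(reference_image)
        hist, _ = np.histogram(arr, bins=bins, range=(0, 256))
        p = hist / hist.sum()
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert rg.mutual_information(arr, arr, bins) == pytest.approx(entropy)

    def test_symmetric_and_nonnegative(self, reference_image):
        rng = np.random.default_rng(0)
        other = rng.integers(0, 255, reference_image.data.shape).astype(np.uint8)
        a = rg.mutual_information(reference_image, other)
        b = rg.mutual_information(other, reference_image)
        assert a == pytest.approx(b)
        assert a >= 0

    def test_constant_image_carries_no_information(self, reference_image):
        const = np.full(reference_image.data.shape, 9, np.uint8)
        assert rg.mutual_information(const, reference_image) == pytest.approx(0.0)

    def test_toy_joint_histogram_hand_sum(self):
        # 2x2 images; with 256 bins every pixel is its own intensity bin.
        a = np.array([[0, 0], [128, 128]], dtype=np.uint8)
        b = np.array([[0, 128], [128, 128]], dtype=np.uint8)
        # joint: p(0,0)=1/4, p(0,128)=1/4, p(128,128)=1/2
        expected = (0.25 * np.log(0.25 / (0.5 * 0.25))
                    + 0.25 * np.log(0.25 / (0.5 * 0.75))
                    + 0.50 * np.log(0.50 / (0.5 * 0.75)))
        assert rg.mutual_information(a, b, 256) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rg.mutual_information(np.zeros((4, 4), np.uint8),
                                  np.zeros((5, 5), np.uint8))


class TestApplyTransform:
    def test_identity_model_returns_input(self, reference_image):
        model = rg.DeformationModel(16.0,
                                    rg.BsplineField((225, 300), 16.0).coeff,
                                    shape=(225, 300))
        out = rg.apply_transform(reference_image, model)
        assert np.array_equal(out.data, reference_image.data)

    def test_impulse_moves_under_translation(self):
        imp = np.zeros((40, 40), np.uint8)
        imp[20, 20] = 255
        t = rg.RigidTransform(0.0, 1.0, (0.0, 5.0))
        out = rg.apply_transform(imp, t)
        assert out.data[20, 25] == 255
        assert out.data.sum() == 255

    def test_rigid_round_trip_small_interior_error(self, reference_image):
        t = rg.RigidTransform(0.05, 1.02, (2.0, -3.0))
        fwd = rg.apply_transform(reference_image, t)
        back = rg.apply_transform(fwd, t.inverse())
        m = 15
        diff = np.abs(back.data[m:-m, m:-m].astype(int)
                      - reference_image.data[m:-m, m:-m].astype(int))
        assert diff.mean() < 6.0

    def test_outside_samples_fill_with_zero(self):
        img = np.full((20, 20), 200, np.uint8)
        t = rg.RigidTransform(0.0, 1.0, (0.0, 10.0))
        out = rg.apply_transform(img, t)
        assert (out.data[:, :10] == 0).all()


class TestRegisterPairwise:
    def test_identity_registration_recovers_identity(self, reference_image,
                                                     foreground):
        res = rg.register_pairwise(reference_image, reference_image)
        d = res.model.dense_field()
        assert np.hypot(d[0], d[1])[foreground].mean() < 0.5
        assert res.mi_final >= res.mi_initial

    def test_huge_regularization_pins_field_to_identity(self, reference_image,
                                                        foreground):
        moving, _ = sd.generate_deformed_copy(reference_image, 8.0, seed=0)
        cfg = rg.RegistrationConfig(lam=1e6)
        res = rg.register_pairwise(moving, reference_image, cfg)
        d = res.model.dense_field()
        assert np.hypot(d[0], d[1])[foreground].mean() < 0.5

    def test_synthetic_warp_recovered_within_two_pixels(self, reference_image,
                                                        foreground):
        moving, truth = sd.generate_deformed_copy(reference_image, 8.0, seed=1)
        res = rg.register_pairwise(moving, reference_image)
        u = res.model.dense_field()
        ustar = truth.inverse_field()
        err = np.hypot(u[0] - ustar[0], u[1] - ustar[1])[foreground].mean()
        assert err <= 2.0
        assert res.mi_final >= res.mi_initial

    def test_bending_energy_finite_and_field_smooth(self, reference_image):
        moving, _ = sd.generate_deformed_copy(reference_image, 8.0, seed=2)
        res = rg.register_pairwise(moving, reference_image)
        energy, _ = rg._bending_energy_grad(res.model.coeff,
                                            res.model.grid_spacing)
        assert np.isfinite(energy)

    def test_narrow_spacing_rejected(self):
        with pytest.raises(ValueError):
            rg.BsplineField((64, 64), 4.0)


class TestDeformationModel:
    def test_json_round_trip(self, tmp_path):
        f = rg.BsplineField((64, 80), 16.0)
        f.coeff = np.random.default_rng(0).normal(0, 2, f.coeff.shape)
        model = rg.DeformationModel(16.0, f.coeff, 0.1, "mi", (64, 80))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = rg.DeformationModel.from_json(path)
        assert np.allclose(back.coeff, model.coeff)
        assert back.grid_spacing == model.grid_spacing
        assert back.shape == model.shape

    def test_zero_coefficients_are_identity(self):
        f = rg.BsplineField((32, 32), 16.0)
        assert np.abs(f.dense_field()).max() == 0.0

    def test_basis_is_partition_of_unity(self):
        f = rg.BsplineField((50, 50), 10.0)
        B = f.basis(np.arange(50, dtype=float), f.coeff.shape[1])
        assert np.allclose(B.sum(axis=1), 1.0)


class TestBuildReference:
    def test_identical_inputs_reproduce_the_common_image(self, reference_image):
        med, _ = rg.build_reference([reference_image] * 3, rounds=2)
        assert np.array_equal(med.data, reference_image.data)

    def test_fewer_than_three_images_rejected(self, reference_image):
        with pytest.raises(ValueError):
            rg.build_reference([reference_image, reference_image])

    def test_reference_closer_to_truth_than_inputs(self, reference_image,
                                                   foreground):
        truth_arr = image_array(reference_image).astype(float)
        warped = [sd.generate_deformed_copy(reference_image, 6.0, 100 + s)[0]
                  for s in range(5)]
        input_err = np.mean([
            np.abs(image_array(w).astype(float) - truth_arr)[foreground].mean()
            for w in warped])
        med, _ = rg.build_reference(warped, rounds=2)
        ref_err = np.abs(med.data.astype(float) - truth_arr)[foreground].mean()
        assert ref_err < input_err
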