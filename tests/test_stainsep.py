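import numpy as np
import pytest

from classm import stainsep
from classm.stainsep import (ChannelPair, DegenerateStainWarning,
                             IllConditionedBasisError, InsufficientTissueError,
                             ODTile, RGBTile, SingularPlaneError,
                             basis_from_vectors, calibrate_norm_scales,
                             fit_slide_basis, fit_stain_basis,
                             fixed_default_basis, load_bases, od_to_rgb,
                             pool_od_pixels, project_to_concentrations,
                             rgb_to_od, save_bases, separate_tile)
from classm.synthesis import (default_textures, make_slide_spec,
                              random_stain_pair, render_tile,
                              sample_od_pixels)


def angle_deg(a, b):
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# rgb_to_od / od_to_rgb
# ---------------------------------------------------------------------------


class TestRGBToOD:
    def test_background_pixel_zero_od(self, white_tile):
        od = rgb_to_od(white_tile)
        assert np.all(od.od == 0.0)

    def test_log10_example(self):
        # I = I0/10 in one channel -> OD exactly 1 there
        px = np.full((1, 1, 3), 255.0)
        px[0, 0, 0] = 25.5
        tile = RGBTile(px, 255.0)
        od = rgb_to_od(tile)
        assert np.allclose(od.od[0, 0], [1.0, 0.0, 0.0])

    def test_entrywise_oracle(self):
        # oracle: scalar log10 evaluation per channel
        px = np.array([[[100, 50, 200]]], dtype=float)
        od = rgb_to_od(RGBTile(px, 255.0)).od[0, 0]
        expected = [np.log10(255 / 100), np.log10(255 / 50), np.log10(255 / 200)]
        assert np.allclose(od, expected)

    def test_monotone_decreasing_in_intensity(self):
        lo = rgb_to_od(RGBTile(np.full((1, 1, 3), 40.0), 255.0)).od
        hi = rgb_to_od(RGBTile(np.full((1, 1, 3), 200.0), 255.0)).od
        assert np.all(lo > hi)

    def test_shape_error(self):
        with pytest.raises(ValueError):
            RGBTile(np.zeros((4, 4, 4)))

    def test_negative_intensity_error(self):
        with pytest.raises(ValueError):
            RGBTile(np.full((2, 2, 3), -1.0))

    def test_epsilon_guards_zero(self):
        od = rgb_to_od(RGBTile(np.zeros((1, 1, 3)), 255.0), epsilon=0.5).od
        assert np.all(np.isfinite(od))
        assert np.allclose(od, np.log10(255 / 0.5))


class TestODToRGB:
    def test_zero_od_is_background(self):
        tile = od_to_rgb(np.zeros((2, 2, 3)), 255.0)
        assert np.all(tile.pixels == 255)

    def test_unit_od_rounds(self):
        # 255 * 10^-1 = 25.5 rounds to 26 (banker's rounding of .5 -> even)
        tile = od_to_rgb(np.ones((1, 1, 3)), 255.0)
        assert np.all(tile.pixels == 26)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            od_to_rgb(np.full((1, 1, 3), -0.1))

    def test_round_trip_1000_random_pixels(self, rng):
        # 8-bit quantization limits round-trip accuracy to ~0.217/I OD,
        # so the 0.01 tolerance applies for OD up to ~1.0 (I >= 25)
        od = rng.uniform(0.0, 1.0, size=(1000, 1, 3))
        tile = od_to_rgb(od, 255.0)
        back = rgb_to_od(tile).od
        assert np.max(np.abs(back - od)) <= 0.01

    def test_od_tile_invariants(self):
        with pytest.raises(ValueError):
            ODTile(np.full((2, 2, 3), np.nan))
        with pytest.raises(ValueError):
            ODTile(np.full((2, 2, 3), -0.5))


# ---------------------------------------------------------------------------
# fit_stain_basis
# ---------------------------------------------------------------------------


class TestFitStainBasis:
    def test_recovery_noise_free(self, rng):
        v_h, v_e = random_stain_pair(rng)
        od = sample_od_pixels(v_h, v_e, 50_000, rng)
        basis = fit_stain_basis(od)
        assert angle_deg(basis.v_h, v_h) < 2.0
        assert angle_deg(basis.v_e, v_e) < 2.0

    def test_recovery_with_noise(self, rng):
        v_h, v_e = random_stain_pair(rng)
        od = sample_od_pixels(v_h, v_e, 50_000, rng, noise_sd=0.01)
        basis = fit_stain_basis(od)
        assert angle_deg(basis.v_h, v_h) < 3.0
        assert angle_deg(basis.v_e, v_e) < 3.0

    def test_rank_one_raises_singular_plane(self, rng):
        direction = np.array([0.6, 0.7, 0.4])
        od = np.outer(rng.uniform(0.2, 1.0, 5000), direction)
        with pytest.raises(SingularPlaneError):
            fit_stain_basis(od)

    def test_too_few_pixels(self, rng):
        v_h, v_e = random_stain_pair(rng)
        od = sample_od_pixels(v_h, v_e, 100, rng)
        with pytest.raises(InsufficientTissueError):
            fit_stain_basis(od)

    def test_quadrant_contract(self, rng):
        for i in range(5):
            r = np.random.default_rng(i)
            v_h, v_e = random_stain_pair(r)
            basis = fit_stain_basis(sample_od_pixels(v_h, v_e, 20_000, r))
            assert basis.theta_h < 0.0 < basis.theta_e

    def test_axes_orthonormal_and_ordered(self, rng):
        v_h, v_e = random_stain_pair(rng)
        basis = fit_stain_basis(sample_od_pixels(v_h, v_e, 20_000, rng))
        gram = basis.axes @ basis.axes.T
        assert np.allclose(gram, np.eye(3), atol=1e-10)
        assert np.allclose(np.linalg.norm(basis.v_h), 1.0)
        assert np.allclose(np.linalg.norm(basis.v_e), 1.0)

    def test_forward_inverse_identity(self, rng):
        v_h, v_e = random_stain_pair(rng)
        basis = fit_stain_basis(sample_od_pixels(v_h, v_e, 20_000, rng))
        assert np.allclose(basis.forward_matrix @ basis.inverse_matrix,
                           np.eye(3), atol=1e-10)

    def test_scale_equivariance_of_angles(self, rng):
        # all pixels above threshold before and after scaling
        v_h, v_e = random_stain_pair(rng)
        alpha = rng.uniform(0.3, 1.0, size=(30_000, 2))
        od = alpha[:, :1] * v_h + alpha[:, 1:] * v_e
        b1 = fit_stain_basis(od)
        b2 = fit_stain_basis(2.0 * od)
        assert np.isclose(b1.theta_h, b2.theta_h, atol=1e-9)
        assert np.isclose(b1.theta_e, b2.theta_e, atol=1e-9)

    def test_determinism(self, rng):
        v_h, v_e = random_stain_pair(rng)
        od = sample_od_pixels(v_h, v_e, 20_000, rng)
        b1 = fit_stain_basis(od)
        b2 = fit_stain_basis(od.copy())
        assert np.array_equal(b1.forward_matrix, b2.forward_matrix)
        assert b1.theta_h == b2.theta_h

    def test_recovery_sweep_20_bases(self):
        # basis-recovery invariant over 20 random ground truths
        for i in range(20):
            r = np.random.default_rng(1000 + i)
            v_h, v_e = random_stain_pair(r)
            basis = fit_stain_basis(sample_od_pixels(v_h, v_e, 50_000, r))
            assert angle_deg(basis.v_h, v_h) < 2.0
            assert angle_deg(basis.v_e, v_e) < 2.0


# ---------------------------------------------------------------------------
# projection / calibration / separation
# ---------------------------------------------------------------------------


@pytest.fixture
def known_basis():
    rng = np.random.default_rng(3)
    v_h, v_e = random_stain_pair(rng)
    return basis_from_vectors(v_h, v_e, slide_id="known")


class TestProjection:
    def test_basis_vector_maps_to_unit(self, known_basis):
        od = known_basis.v_h.reshape(1, 1, 3)
        a_h, a_e, a_res = project_to_concentrations(od, known_basis)
        assert np.allclose([a_h[0, 0], a_e[0, 0], a_res[0, 0]], [1, 0, 0],
                           atol=1e-10)

    def test_zero_maps_to_zero(self, known_basis):
        a_h, a_e, a_res = project_to_concentrations(np.zeros((1, 1, 3)),
                                                    known_basis)
        assert a_h[0, 0] == a_e[0, 0] == a_res[0, 0] == 0.0

    def test_linear_combination(self, known_basis):
        od = (0.3 * known_basis.v_h + 0.7 * known_basis.v_e).reshape(1, 1, 3)
        a_h, a_e, a_res = project_to_concentrations(od, known_basis)
        assert np.allclose([a_h[0, 0], a_e[0, 0]], [0.3, 0.7], atol=1e-10)
        assert abs(a_res[0, 0]) < 1e-10

    def test_negative_concentration_clipped(self, known_basis):
        od = (-0.2 * known_basis.v_h + 0.5 * known_basis.v_e).reshape(1, 1, 3)
        a_h, _, _ = project_to_concentrations(od, known_basis)
        assert a_h[0, 0] == 0.0

    def test_ill_conditioned_rejected(self):
        with pytest.raises(IllConditionedBasisError):
            basis_from_vectors([0.6, 0.7, 0.3], [0.6, 0.7, 0.30000001])


class TestCalibration:
    def test_quantile_and_ratio(self, known_basis, rng):
        samples = rng.uniform(0, 2.0, 100_000)
        basis = calibrate_norm_scales(known_basis, samples, samples,
                                      percentile=99, target=0.5)
        q99 = np.quantile(samples, 0.99)
        assert np.isclose(basis.norm_scale_h, q99, rtol=1e-6)
        # subsequent normalization divides by scale / target
        assert np.isclose(basis.norm_scale_h / basis.norm_target, q99 / 0.5)

    def test_constant_samples_fixed_point(self, known_basis):
        samples = np.full(1000, 0.5)
        basis = calibrate_norm_scales(known_basis, samples, samples)
        assert basis.norm_scale_h == 0.5
        assert np.isclose(0.5 / (basis.norm_scale_h / basis.norm_target), 0.5)

    def test_clip_rule(self, known_basis):
        basis = calibrate_norm_scales(known_basis, np.array([2.0]),
                                      np.array([2.0]), percentile=100,
                                      target=0.5)
        raw = 6.0
        value = min(raw / (basis.norm_scale_h / basis.norm_target), 1.0)
        assert value == 1.0  # 6.0 / 4.0 = 1.5 clipped

    def test_all_zero_warns_scale_one(self, known_basis):
        with pytest.warns(DegenerateStainWarning):
            basis = calibrate_norm_scales(known_basis, np.zeros(10),
                                          np.ones(10))
        assert basis.norm_scale_h == 1.0


class TestSeparateTile:
    def test_background_tile_zero_channels(self, known_basis, white_tile):
        basis = calibrate_norm_scales(known_basis, np.ones(10), np.ones(10))
        pair = separate_tile(white_tile, basis)
        assert np.all(pair.h_image == 0.0)
        assert np.all(pair.e_image == 0.0)

    def test_uncalibrated_basis_rejected(self, known_basis, white_tile):
        with pytest.raises(ValueError):
            separate_tile(white_tile, known_basis)

    def test_output_range(self, tiny_dataset):
        sid = next(iter(tiny_dataset.slides))
        spec = tiny_dataset.slides[sid]
        tile, _, _ = render_tile(spec, default_textures()[1], size=64, seed=5)
        basis = basis_from_vectors(spec.v_h, spec.v_e, slide_id=sid,
                                   norm_scale_h=0.5, norm_scale_e=0.5)
        pair = separate_tile(tile, basis)
        assert pair.h_image.min() >= 0.0 and pair.h_image.max() <= 1.0
        assert pair.e_image.min() >= 0.0 and pair.e_image.max() <= 1.0

    def test_round_trip_with_true_basis(self):
        # forward-rendered tile separated with its true basis recovers the
        # ground-truth concentration fields (norm scales = target => no
        # rescaling); zero noise
        rng = np.random.default_rng(11)
        spec = make_slide_spec("s", rng, brightness_range=(1.0, 1.0))
        tile, alpha_h, alpha_e = render_tile(spec, default_textures()[0],
                                             size=64, noise_sd=0.0, seed=2)
        basis = basis_from_vectors(spec.v_h, spec.v_e, slide_id="s",
                                   norm_scale_h=0.5, norm_scale_e=0.5)
        pair = separate_tile(tile, basis)
        assert np.abs(pair.h_image - np.clip(alpha_h, 0, 1)).mean() <= 0.02
        assert np.abs(pair.e_image - np.clip(alpha_e, 0, 1)).mean() <= 0.02

    def test_same_slide_same_basis_bit_equal(self, tiny_dataset):
        frame = tiny_dataset.manifest.frame
        sid = frame.iloc[0]["slide_id"]
        tiles = [tiny_dataset.tiles.get(p)
                 for p in frame[frame.slide_id == sid]["tile_path"][:4]]
        b1 = fit_slide_basis(tiles, slide_id=sid)
        b2 = fit_slide_basis(tiles, slide_id=sid)
        assert np.array_equal(b1.forward_matrix, b2.forward_matrix)
        assert b1.norm_scale_h == b2.norm_scale_h


class TestFixedDefaultBasis:
    def test_unit_norm_vectors(self):
        basis = fixed_default_basis()
        assert np.isclose(np.linalg.norm(basis.v_h), 1.0)
        assert np.isclose(np.linalg.norm(basis.v_e), 1.0)

    def test_deterministic(self):
        b1, b2 = fixed_default_basis(), fixed_default_basis()
        assert np.array_equal(b1.forward_matrix, b2.forward_matrix)

    def test_differs_from_adaptive_on_drifted_slide(self):
        rng = np.random.default_rng(9)
        spec = make_slide_spec("s", rng, drift_deg=8.0,
                               brightness_range=(1.0, 1.0))
        tile, _, _ = render_tile(spec, default_textures()[1], size=64, seed=1)
        tiles = [render_tile(spec, default_textures()[i % 3], size=64,
                             seed=i)[0] for i in range(10)]
        adaptive = fit_slide_basis(tiles, slide_id="s")
        fixed = fixed_default_basis()
        pa = separate_tile(tile, adaptive)
        pf = separate_tile(tile, fixed)
        assert not np.allclose(pa.h_image, pf.h_image)


class TestPersistence:
    def test_basis_json_round_trip(self, tmp_path, rng):
        v_h, v_e = random_stain_pair(rng)
        basis = fit_stain_basis(sample_od_pixels(v_h, v_e, 20_000, rng),
                                slide_id="sA")
        basis = calibrate_norm_scales(basis, rng.uniform(0, 1, 100),
                                      rng.uniform(0, 1, 100))
        path = tmp_path / "bases.json"
        save_bases({"sA": basis}, path)
        loaded = load_bases(path)["sA"]
        assert np.array_equal(loaded.forward_matrix, basis.forward_matrix)
        assert np.array_equal(loaded.inverse_matrix, basis.inverse_matrix)
        assert loaded.theta_h == basis.theta_h
        assert loaded.norm_scale_h == basis.norm_scale_h
        assert loaded.params == basis.params


class TestPooling:
    def test_pool_respects_cap_and_seed(self, tiny_dataset):
        frame = tiny_dataset.manifest.frame
        tiles = [tiny_dataset.tiles.get(p) for p in frame["tile_path"][:6]]
        p1 = pool_od_pixels(tiles, max_pixels=500, seed=1)
        p2 = pool_od_pixels(tiles, max_pixels=500, seed=1)
        assert p1.shape == (500, 3)
        assert np.array_equal(p1, p2)
        assert np.all(np.linalg.norm(p1, axis=1) >= 0.1)


class TestChannelPair:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ChannelPair(np.zeros((4, 4)), np.zeros((5, 4)))
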