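"""Preprocessing chain: binning, registration, stretching, cropping,
contrast, background subtraction, maxima counting, unit conversion,
kymographs."""

import numpy as np
import pytest
from scipy import ndimage

from mitoflow import Calibration, Movie
from mitoflow import preprocess as pp
from mitoflow.preprocess import RegistrationError
from mitoflow.synthetic import NoiseModel, binned_scene_config, make_scene_movie


def movie_from(data, **cal):
    return Movie(np.asarray(data, dtype=float), Calibration(**cal))


rng = np.random.default_rng(42)


class TestBinSpatial:
    def test_constant_image_unchanged(self):
        m = movie_from(np.full((2, 8, 8), 7.0))
        out = pp.bin_spatial(m, 4)
        assert out.shape == (2, 2, 2)
        np.testing.assert_array_equal(out.data, 7.0)

    def test_block_mean_arithmetic(self):
        m = movie_from(np.arange(16, dtype=float).reshape(1, 4, 4))
        out = pp.bin_spatial(m, 4)
        assert out.data[0, 0, 0] == 7.5

    def test_matches_loop_oracle(self):
        data = rng.random((1, 64, 64))
        out = pp.bin_spatial(movie_from(data), 4)
        oracle = np.empty((16, 16))
        for i in range(16):
            for j in range(16):
                oracle[i, j] = data[0, 4 * i:4 * i + 4, 4 * j:4 * j + 4].mean()
        np.testing.assert_allclose(out.data[0], oracle, rtol=1e-12)

    def test_trims_nondivisible_and_updates_calibration(self):
        out = pp.bin_spatial(movie_from(rng.random((1, 10, 11))), 4)
        assert out.shape == (1, 2, 2)
        assert out.calibration.bin_factor == 4
        assert out.calibration.effective_pixel_um == pytest.approx(0.432)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            pp.bin_spatial(movie_from(np.zeros((1, 4, 4))), 0)


class TestRegisterRigid:
    def test_identical_frames_identity_transforms(self):
        frame = rng.random((48, 48))
        m = movie_from(np.stack([frame] * 4))
        _, transforms = pp.register_rigid(m)
        assert all(t.is_identity for t in transforms)

    def test_recovers_pure_translation(self):
        base = ndimage.gaussian_filter(rng.random((64, 64)), 2)
        shifted = ndimage.shift(base, (-1.0, 2.0), order=3, mode="nearest")
        m = movie_from(np.stack([base, shifted]))
        _, transforms = pp.register_rigid(m, refine_rotation=False)
        # frame 1 moved by (dx, dy) = (2.0, -1.0)
        assert transforms[1].dx == pytest.approx(2.0, abs=0.25)
        assert transforms[1].dy == pytest.approx(-1.0, abs=0.25)

    def test_recovers_small_rotation(self):
        base = ndimage.gaussian_filter(rng.random((96, 96)), 2)
        rotated = ndimage.rotate(base, 2.0, reshape=False, order=3, mode="nearest")
        m = movie_from(np.stack([base, rotated]))
        _, transforms = pp.register_rigid(m, refine_rotation=True)
        assert abs(np.rad2deg(abs(transforms[1].theta)) - 2.0) < 0.2

    def test_residual_shift_after_registration(self):
        cfg = binned_scene_config(image_size=(96, 96), n_frames=4, n_stationary=25,
                                  n_moving=0, seed=8)
        movie, _ = make_scene_movie(cfg)
        drifted = movie.data.copy()
        for t, s in enumerate([0.0, 0.8, 1.6, 2.4]):
            drifted[t] = ndimage.shift(movie.data[t], (s, -s / 2), order=1,
                                       mode="nearest")
        reg, _ = pp.register_rigid(Movie(drifted, movie.calibration),
                                   refine_rotation=False)
        for t in range(1, 4):
            from skimage.registration import phase_cross_correlation
            shift, _, _ = phase_cross_correlation(reg.data[t - 1], reg.data[t],
                                                  upsample_factor=50)
            assert np.hypot(*shift) <= 0.25

    def test_registration_preserves_mean_intensity(self):
        cfg = binned_scene_config(image_size=(96, 96), n_frames=5, n_stationary=30,
                                  n_moving=0, seed=2)
        movie, _ = make_scene_movie(cfg)
        reg, _ = pp.register_rigid(movie, refine_rotation=False)
        for t in range(movie.n_frames):
            rel = abs(reg.data[t].mean() - movie.data[t].mean()) / movie.data[t].mean()
            assert rel < 0.01

    def test_all_zero_frame_raises(self):
        data = np.stack([rng.random((32, 32)), np.zeros((32, 32))])
        with pytest.raises(RegistrationError):
            pp.register_rigid(movie_from(data))


class TestStretchTime:
    def test_constant_movie_doubles_length(self):
        out = pp.stretch_time(movie_from(np.full((6, 4, 4), 3.0)), 2)
        assert out.n_frames == 12
        np.testing.assert_allclose(out.data, 3.0)
        assert out.calibration.effective_interval_s == pytest.approx(1.75)

    def test_linear_ramp_inserted_frames_are_midpoints(self):
        t = np.arange(8, dtype=float)
        data = np.tile(t[:, None, None], (1, 3, 3))
        out = pp.stretch_time(movie_from(data), 2)
        # even outputs hit the original samples, odd ones their midpoints
        np.testing.assert_allclose(out.data[::2, 0, 0][:8], t, atol=1e-6)
        np.testing.assert_allclose(out.data[1::2, 0, 0][:7], t[:-1] + 0.5, atol=1e-6)

    def test_quintic_beats_linear_on_sinusoid(self):
        t = np.arange(24, dtype=float)
        series = np.sin(2 * np.pi * t / 12)
        data = np.tile(series[:, None, None], (1, 2, 2))
        out = pp.stretch_time(movie_from(data), 2)
        half = np.arange(48) / 2
        truth = np.sin(2 * np.pi * np.clip(half, 0, 23) / 12)
        err_spline = np.abs(out.data[:, 0, 0] - truth).max()
        linear = np.interp(np.clip(half, 0, 23), t, series)
        err_linear = np.abs(linear - truth).max()
        assert err_spline < err_linear

    def test_factor_one_is_identity(self):
        data = rng.random((5, 4, 4))
        out = pp.stretch_time(movie_from(data), 1)
        np.testing.assert_allclose(out.data, data, rtol=1e-9)


class TestCropCenter:
    def test_same_size_is_identity(self):
        data = rng.random((2, 10, 10))
        out = pp.crop_center(movie_from(data), 10)
        np.testing.assert_array_equal(out.data, data)

    def test_index_bookkeeping_512_to_450(self):
        data = rng.random((1, 512, 512))
        out = pp.crop_center(movie_from(data), 450)
        assert out.shape == (1, 450, 450)
        assert out.data[0, 0, 0] == data[0, 31, 31]

    def test_odd_remainder_removes_extra_from_bottom_right(self):
        data = rng.random((1, 5, 5))
        out = pp.crop_center(movie_from(data), 4)
        np.testing.assert_array_equal(out.data[0], data[0, 0:4, 0:4])

    def test_too_large_raises(self):
        with pytest.raises(ValueError):
            pp.crop_center(movie_from(np.zeros((1, 4, 4))), 8)


class TestEnhanceContrast:
    def test_two_valued_min_max_stretch(self):
        data = np.zeros((1, 10, 10))
        data[0, :5] = 100.0
        out = pp.enhance_contrast_8bit(movie_from(data), 0.0, method="none")
        assert set(np.unique(out.data)) == {0, 255}

    def test_equalization_monotone(self):
        data = rng.random((1, 32, 32)) * 200
        out = pp.enhance_contrast_8bit(movie_from(data), 0.0, method="sqrt")
        flat_in, flat_out = data.ravel(), out.data.ravel().astype(float)
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)

    @pytest.mark.parametrize("method", ["sqrt", "classic"])
    def test_equalization_flattens_histogram(self, method):
        data = (rng.lognormal(4, 0.5, size=(1, 64, 64))).clip(0, 500)
        m = movie_from(data)
        out = pp.enhance_contrast_8bit(m, 0.02, method=method)
        def cv(img):
            h, _ = np.histogram(img, bins=32)
            return h.std() / h.mean()
        assert cv(out.data) < cv(data)

    def test_constant_movie_returns_midgray_flag(self):
        out = pp.enhance_contrast_8bit(movie_from(np.full((2, 8, 8), 9.0)))
        np.testing.assert_array_equal(out.data, 128)
        assert out.history[-1].get("degenerate") is True


class TestSubtractMeanProjection:
    def test_static_movie_goes_to_zero(self):
        frame = rng.random((16, 16))
        out = pp.subtract_mean_projection(movie_from(np.stack([frame] * 5)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_constant_offset_invariance(self):
        data = rng.random((4, 8, 8))
        a = pp.subtract_mean_projection(movie_from(data))
        b = pp.subtract_mean_projection(movie_from(data + 50.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_mover_retains_positive_transient(self):
        cal = Calibration(0.432, 3.5)
        v = cal.pf_to_umps(2.0)
        cfg = binned_scene_config(
            image_size=(96, 96), n_frames=10, n_stationary=6, n_moving=1,
            mover_speeds_umps=(v,), run_pause_schedule=(((0, 10, (v, 0.0)),),),
            noise=NoiseModel(0.0, 0.0), jitter_sd_px=0.0, seed=3)
        movie, gt = make_scene_movie(cfg)
        out = pp.subtract_mean_projection(movie)
        x, y = gt.trajectories[0, 9]
        assert out.data[9, int(round(y)), int(round(x))] > 100


class TestCountMaxima:
    def test_blank_frame(self):
        assert pp.count_maxima(np.zeros((32, 32)), 2, 10.0) == 0

    def test_five_separated_spots(self):
        frame = np.zeros((96, 96))
        for cx, cy in [(15, 15), (15, 75), (75, 15), (75, 75), (48, 48)]:
            y, x = np.ogrid[:96, :96]
            frame += 300 * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 2.0**2))
        assert pp.count_maxima(frame, 2, 100.0) == 5

    def test_tolerance_above_amplitude(self):
        frame = np.zeros((32, 32))
        frame[16, 16] = 50.0
        assert pp.count_maxima(frame, 1, 100.0) == 0


class TestVelocityConversion:
    CAL = Calibration(0.108, 3.5, bin_factor=4, time_stretch=2)

    def test_one_pixel_per_frame(self):
        assert pp.velocity_umps(1.0, self.CAL) == pytest.approx(0.2469, abs=1e-4)

    def test_histogram_upper_bound_in_umps(self):
        # exp(4) = 54.6 px/frame at the working calibration is 13.5 um/s
        assert pp.velocity_umps(np.exp(4.0), self.CAL) == pytest.approx(13.5, abs=0.05)

    def test_zero_and_round_trip(self):
        assert pp.velocity_umps(0.0, self.CAL) == 0.0
        assert pp.umps_to_pf(pp.velocity_umps(1.7, self.CAL), self.CAL) == pytest.approx(1.7)


class TestKymograph:
    def test_static_movie_columns_identical(self):
        frame = rng.random((32, 32))
        m = movie_from(np.stack([frame] * 6))
        k = pp.kymograph(m, np.array([[2.0, 16.0], [29.0, 16.0]]), width=1)
        assert k.shape[1] == 6
        for t in range(1, 6):
            np.testing.assert_allclose(k[:, t], k[:, 0])

    def test_ridge_slope_matches_velocity(self):
        cal = Calibration(0.432, 3.5)
        v_pf = 1.5
        v = cal.pf_to_umps(v_pf)
        cfg = binned_scene_config(
            image_size=(96, 96), n_frames=14, n_stationary=0, n_moving=1,
            mover_speeds_umps=(v,), run_pause_schedule=(((0, 14, (v, 0.0)),),),
            noise=NoiseModel(0.0, 0.0), jitter_sd_px=0.0, seed=5)
        movie, gt = make_scene_movie(cfg)
        y = gt.trajectories[0, 0, 1]
        path = np.array([[5.0, y], [90.0, y]])
        k = pp.kymograph(movie, path, width=3)
        ridge = k.argmax(axis=0)
        slope = np.polyfit(np.arange(len(ridge)), ridge, 1)[0]
        assert slope == pytest.approx(v_pf, rel=0.10)

    def test_worked_run_example(self):
        # a 13.8 um run over 35 s read off a kymograph is 0.39 um/s
        assert 13.8 / 35 == pytest.approx(0.39, abs=0.005)
        cal = Calibration(0.432, 3.5)
        slope_pf = cal.umps_to_pf(13.8 / 35)
        assert pp.velocity_umps(slope_pf, cal) == pytest.approx(0.394, abs=1e-3)


def test_rayleigh_limit():
    assert pp.rayleigh_limit_nm(532.0, 0.95) == pytest.approx(341.6, abs=0.1)


def test_history_grows_one_entry_per_operation():
    m = movie_from(rng.random((8, 16, 16)))
    assert m.history == []
    m1 = pp.bin_spatial(m, 2)
    m2 = pp.stretch_time(m1, 2)
    m3 = pp.crop_center(m2, 6)
    assert [h["op"] for h in m3.history] == ["bin_spatial", "stretch_time", "crop_center"]
    assert m3.history[0]["factor"] == 2
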