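"""Forward acquisition simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lenspol import jones, scenes, simulate
from lenspol.propagation import ComplexField, angular_spectrum_propagate, led_tilt
from lenspol.simulate import MosaicLayout, NoiseModel


def isotropic_scene(n=64, amplitude=None):
    zero = np.zeros((n, n))
    return jones.RetOriMap(delta=zero, theta=zero, amplitude=amplitude)


class TestMosaicLayout:
    def test_default_contains_all_angles(self):
        layout = MosaicLayout()
        assert {layout.angles_deg[r][c] for r in range(2) for c in range(2)} == {0, 45, 90, 135}

    def test_duplicate_angle_rejected(self):
        with pytest.raises(ValueError):
            MosaicLayout(((0.0, 45.0), (0.0, 135.0)))


class TestMosaicSample:
    def test_identical_channels_pass_through(self, rng):
        grid = rng.uniform(size=(16, 16))
        out = simulate.mosaic_sample({psi: grid for psi in jones.PSI_ANGLES_DEG})
        assert np.array_equal(out, grid)

    def test_tiling_follows_layout(self):
        layout = MosaicLayout()
        channels = {psi: np.full((8, 8), psi) for psi in jones.PSI_ANGLES_DEG}
        out = simulate.mosaic_sample(channels, layout)
        for psi in jones.PSI_ANGLES_DEG:
            r, c = layout.parity_of(psi)
            assert np.all(out[r::2, c::2] == psi)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_split_restores_each_parity(self, seed):
        from lenspol.demosaic import split_mosaic

        rng = np.random.default_rng(seed)
        channels = {psi: rng.uniform(size=(8, 8)) for psi in jones.PSI_ANGLES_DEG}
        layout = MosaicLayout()
        raw = simulate.mosaic_sample(channels, layout)
        parts = split_mosaic(raw, layout)
        for psi, (sparse, valid) in parts.items():
            assert np.array_equal(sparse[valid], channels[psi][valid])


class TestObjectExitChannel:
    def test_isotropic_channels_equal(self, small_geometry):
        scene = isotropic_scene()
        tilt = np.ones((64, 64), dtype=complex)
        i0 = simulate.object_exit_channel(scene, 0.0, tilt, small_geometry).intensity()
        i90 = simulate.object_exit_channel(scene, 90.0, tilt, small_geometry).intensity()
        assert np.allclose(i0, i90, atol=1e-14)

    def test_crossed_channel_extinction(self, small_geometry):
        n = 64
        scene = jones.RetOriMap(delta=np.full((n, n), np.pi / 2),
                                theta=np.full((n, n), np.pi / 4))
        tilt = np.ones((n, n), dtype=complex)
        dark = simulate.object_exit_channel(scene, 0.0, tilt, small_geometry).intensity()
        bright = simulate.object_exit_channel(scene, 90.0, tilt, small_geometry).intensity()
        assert dark.max() / bright.max() < 1e-6

    def test_tilt_shifts_exit_spectrum(self, small_geometry):
        scene = isotropic_scene()
        flat = simulate.object_exit_channel(scene, 0.0, np.ones((64, 64), complex), small_geometry)
        tilt = led_tilt(small_geometry, (1, 2), (64, 64))
        tilted = simulate.object_exit_channel(scene, 0.0, tilt, small_geometry)
        peak_flat = np.unravel_index(np.argmax(np.abs(np.fft.fft2(flat.values))), (64, 64))
        peak_tilted = np.unravel_index(np.argmax(np.abs(np.fft.fft2(tilted.values))), (64, 64))
        assert peak_flat == (0, 0)
        assert peak_tilted != (0, 0)

    def test_analyzer_placement_equivalence(self, small_geometry, small_mask):
        """Analyzing at the object plane then propagating the scalar equals
        propagating the Jones vector and analyzing at the sensor."""
        n = 64
        rng = np.random.default_rng(2)
        scene = jones.RetOriMap(delta=rng.uniform(0, 1.2, (n, n)),
                                theta=rng.uniform(0, np.pi, (n, n)))
        tilt = led_tilt(small_geometry, (0, 1), (n, n))
        psi = np.deg2rad(45.0)
        g = small_geometry

        scalar_path = simulate.object_exit_channel(scene, 45.0, tilt, g)
        scalar_sensor = angular_spectrum_propagate(scalar_path, g.z_obj_mask_mm, pad_factor=1)

        vec = jones.channel_field(scene.delta, scene.theta, psi)
        c, s = np.cos(psi), np.sin(psi)
        vx = angular_spectrum_propagate(
            ComplexField(vec[..., 0] * tilt, g.pixel_um, g.wavelength_um),
            g.z_obj_mask_mm, pad_factor=1).values
        vy = angular_spectrum_propagate(
            ComplexField(vec[..., 1] * tilt, g.pixel_um, g.wavelength_um),
            g.z_obj_mask_mm, pad_factor=1).values
        vector_sensor = c * vx + s * vy
        assert np.max(np.abs(scalar_sensor.values - vector_sensor)) < 1e-10


class TestCaptureFrame:
    def test_open_mask_isotropic_scene_gives_flat_frame(self, small_geometry):
        frame = simulate.capture_frame(isotropic_scene(), None, small_geometry, (1, 1))
        cv = frame.values.std() / frame.values.mean()
        assert cv < 1e-6

    def test_frame_mean_tracks_channel_mean(self, small_geometry, small_mask):
        n = 64
        rng = np.random.default_rng(0)
        scene = jones.RetOriMap(delta=rng.uniform(0, 1.0, (n, n)),
                                theta=rng.uniform(0, np.pi, (n, n)))
        channels = simulate.capture_channels(scene, small_mask, small_geometry, (1, 1))
        frame = simulate.capture_frame(scene, small_mask, small_geometry, (1, 1))
        channel_mean = np.mean([channels[psi].mean() for psi in jones.PSI_ANGLES_DEG])
        assert abs(frame.values.mean() - channel_mean) / channel_mean < 0.01

    def test_mask_scene_mismatch_raises(self, small_geometry):
        mask = scenes.random_binary_mask((32, 32), feature_px=8, seed=0)
        with pytest.raises(ValueError):
            simulate.capture_frame(isotropic_scene(64), mask, small_geometry, (0, 0))


class TestCaptureStack:
    def test_frame_count_matches_led_grid(self, small_geometry, small_mask):
        stack = simulate.capture_stack(isotropic_scene(), small_mask, small_geometry)
        assert len(stack) == 9

    def test_frames_differ_for_structured_scene(self, small_geometry, small_mask):
        needle = scenes.needle_crystal((64, 64), 0.3, 0.5, 30, 6)
        stack = simulate.capture_stack(needle, small_mask, small_geometry)
        mse = np.mean((stack.frames[0].values - stack.frames[-1].values) ** 2)
        assert mse > 0

    def test_noise_seed_reproducible(self, small_geometry, small_mask):
        noise = NoiseModel(photon_scale=1e4, read_noise_sd=1.0, seed=11)
        a = simulate.capture_stack(isotropic_scene(), small_mask, small_geometry, noise=noise)
        b = simulate.capture_stack(isotropic_scene(), small_mask, small_geometry, noise=noise)
        assert np.array_equal(a.as_array(), b.as_array())


class TestNoise:
    def test_large_photon_scale_converges_to_truth(self):
        frame = np.full((100, 100), 0.7)
        noisy = simulate.apply_noise(frame, NoiseModel(photon_scale=1e6, read_noise_sd=0.0, seed=0))
        assert np.abs(noisy.mean() - 0.7) / 0.7 < 0.01

    def test_poisson_variance_matches_mean(self):
        scale = 50.0
        frame = np.full((400, 250), 1.0)
        noisy = simulate.apply_noise(frame, NoiseModel(photon_scale=scale, read_noise_sd=0.0, seed=1))
        counts = noisy * scale
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_negative_frame_rejected(self):
        with pytest.raises(ValueError):
            simulate.apply_noise(np.array([[-1.0]]), NoiseModel())
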