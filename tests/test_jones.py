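"""Jones forward model and birefringence inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lenspol import jones


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def brute_force_jones(delta, theta):
    """Independent oracle: explicit R @ diag(e^{i d/2}, e^{-i d/2}) @ R^-1."""
    p = np.diag([np.exp(1j * delta / 2), np.exp(-1j * delta / 2)])
    r = rotation(theta)
    return r @ p @ np.linalg.inv(r)


class TestSampleJones:
    def test_zero_retardance_is_identity(self):
        j = jones.sample_jones_matrix(np.zeros((3, 3)), np.random.default_rng(0).uniform(0, np.pi, (3, 3)))
        assert np.allclose(j, np.eye(2), atol=1e-14)

    def test_quarter_wave_axis_aligned_is_diagonal(self):
        j = jones.sample_jones_matrix(np.array([[np.pi / 2]]), np.array([[0.0]]))
        expected = np.diag([np.exp(1j * np.pi / 4), np.exp(-1j * np.pi / 4)])
        assert np.allclose(j[0, 0], expected, atol=1e-14)

    def test_matches_explicit_matrix_product(self, rng):
        deltas = rng.uniform(0, np.pi, 25)
        thetas = rng.uniform(0, np.pi, 25)
        j = jones.sample_jones_matrix(deltas, thetas)
        for k in range(25):
            assert np.allclose(j[k], brute_force_jones(deltas[k], thetas[k]), atol=1e-12)

    def test_unitary_determinant(self, rng):
        d = rng.uniform(0, np.pi, (16, 16))
        t = rng.uniform(0, np.pi, (16, 16))
        j = jones.sample_jones_matrix(d, t)
        det = j[..., 0, 0] * j[..., 1, 1] - j[..., 0, 1] * j[..., 1, 0]
        assert np.allclose(np.abs(det), 1.0, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            jones.sample_jones_matrix(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            jones.sample_jones_matrix(np.array([np.nan]), np.array([0.0]))


class TestAnalyzer:
    @pytest.mark.parametrize("psi_deg,expected", [
        (0.0, [[1, 0], [0, 0]]),
        (90.0, [[0, 0], [0, 1]]),
        (45.0, [[0.5, 0.5], [0.5, 0.5]]),
    ])
    def test_known_matrices(self, psi_deg, expected):
        assert np.allclose(jones.analyzer_jones(np.deg2rad(psi_deg)), expected, atol=1e-15)

    def test_idempotent_projector_with_unit_trace(self, rng):
        for psi in rng.uniform(0, np.pi, 8):
            j = jones.analyzer_jones(psi)
            assert np.allclose(j @ j, j, atol=1e-14)
            assert np.isclose(np.trace(j), 1.0)


class TestChannelField:
    def test_isotropic_psi0_passes_x_component(self):
        out = jones.channel_field(np.zeros((1, 1)), np.zeros((1, 1)), 0.0, intensity=2.0)
        assert np.allclose(out[0, 0], [1.0, 0.0], atol=1e-14)

    def test_intensity_matches_closed_form(self, rng):
        d = rng.uniform(0, np.pi / 2, (8, 8))
        t = rng.uniform(0, np.pi, (8, 8))
        ch = jones.channel_intensities(d, t, 1.3)
        for psi_deg in jones.PSI_ANGLES_DEG:
            field = jones.channel_field(d, t, np.deg2rad(psi_deg), intensity=1.3)
            intensity = np.sum(np.abs(field) ** 2, axis=-1)
            assert np.allclose(intensity, ch[psi_deg], atol=1e-12)

    def test_analyzer_pi_periodic(self, rng):
        d = rng.uniform(0, np.pi / 2, (4, 4))
        t = rng.uniform(0, np.pi, (4, 4))
        a = jones.channel_field(d, t, 0.3)
        b = jones.channel_field(d, t, 0.3 + np.pi)
        assert np.allclose(np.abs(a) ** 2, np.abs(b) ** 2, atol=1e-13)

    def test_negative_intensity_raises(self):
        with pytest.raises(ValueError):
            jones.channel_field(np.zeros((1, 1)), np.zeros((1, 1)), 0.0, intensity=-1.0)


class TestChannelIntensities:
    def test_isotropic_splits_evenly(self):
        ch = jones.channel_intensities(np.zeros((2, 2)), np.zeros((2, 2)), 1.0)
        for psi in jones.PSI_ANGLES_DEG:
            assert np.allclose(ch[psi], 0.5)

    def test_quarter_wave_at_45deg(self):
        ch = jones.channel_intensities(np.array([[np.pi / 2]]), np.array([[np.pi / 4]]), 1.0)
        assert np.allclose([ch.i0, ch.i45, ch.i90, ch.i135],
                           [[[0.0]], [[0.5]], [[1.0]], [[0.5]]], atol=1e-14)

    def test_frozen_values_delta_pi4_theta_15deg(self):
        ch = jones.channel_intensities(np.array([[np.pi / 4]]), np.array([[np.deg2rad(15.0)]]), 1.0)
        assert np.allclose([ch.i0[0, 0], ch.i45[0, 0], ch.i90[0, 0], ch.i135[0, 0]],
                           [0.3232, 0.8062, 0.6768, 0.1938], atol=5e-5)

    def test_channel_sums_conserve_intensity(self, rng):
        d = rng.uniform(0, np.pi, (16, 16))
        t = rng.uniform(0, np.pi, (16, 16))
        ch = jones.channel_intensities(d, t, 2.7)
        assert np.allclose(ch.i0 + ch.i90, 2.7, atol=1e-12)
        assert np.allclose(ch.i45 + ch.i135, 2.7, atol=1e-12)


class TestQMapsAndInversion:
    def test_isotropic_gives_zero_q(self):
        ch = jones.ChannelIntensities(*(np.full((2, 2), 0.5),) * 4)
        q = jones.compute_q_maps(ch)
        assert np.allclose(q.q1, 0) and np.allclose(q.q2, 0)

    def test_frozen_q_values(self):
        ch = jones.ChannelIntensities(i0=np.array([[0.3232]]), i45=np.array([[0.8062]]),
                                      i90=np.array([[0.6768]]), i135=np.array([[0.1938]]))
        q = jones.compute_q_maps(ch)
        assert np.isclose(q.q1[0, 0], 0.3536, atol=2e-4)
        assert np.isclose(q.q2[0, 0], 0.6124, atol=2e-4)

    def test_extreme_case_q1_one(self):
        ch = jones.ChannelIntensities(i0=np.array([[0.0]]), i45=np.array([[0.5]]),
                                      i90=np.array([[1.0]]), i135=np.array([[0.5]]))
        q = jones.compute_q_maps(ch)
        assert np.isclose(q.q1[0, 0], 1.0) and np.isclose(q.q2[0, 0], 0.0)
        delta, _ = jones.retardation_map(q)
        assert np.isclose(delta[0, 0], np.pi / 2)

    def test_zero_denominator_flagged(self):
        ch = jones.ChannelIntensities(i0=np.array([[0.0]]), i45=np.array([[0.5]]),
                                      i90=np.array([[0.0]]), i135=np.array([[0.5]]))
        q = jones.compute_q_maps(ch)
        assert q.invalid[0, 0]

    def test_clipping_flags_out_of_range_q(self):
        q = jones.QMaps(q1=np.array([[0.8]]), q2=np.array([[0.8]]))
        delta, flagged = jones.retardation_map(q)
        assert np.isclose(delta[0, 0], np.pi / 2)
        assert flagged[0, 0]

    def test_inverted_orientation_values(self):
        q = jones.QMaps(q1=np.array([[0.0, 0.5, 0.3536]]), q2=np.array([[0.5, 0.0, 0.6124]]))
        theta, _ = jones.orientation_map(q)
        assert np.allclose(np.rad2deg(theta[0]), [0.0, 45.0, 15.0], atol=0.1)

    def test_isotropic_orientation_flagged(self):
        q = jones.QMaps(q1=np.zeros((1, 1)), q2=np.zeros((1, 1)))
        _, flagged = jones.orientation_map(q)
        assert flagged[0, 0]

    @settings(deadline=None, max_examples=60)
    @given(delta=st.floats(0.01, np.pi / 2 - 0.01), theta=st.floats(0, np.pi, exclude_max=True))
    def test_roundtrip_property(self, delta, theta):
        """Forward intensities -> Q maps -> (delta, theta) is exact."""
        ch = jones.channel_intensities(np.array([[delta]]), np.array([[theta]]), 1.0)
        q = jones.compute_q_maps(ch)
        d, _ = jones.retardation_map(q)
        t, _ = jones.orientation_map(q)
        assert abs(d[0, 0] - delta) < 1e-9
        err = min(abs(t[0, 0] - theta), np.pi - abs(t[0, 0] - theta))
        assert err < 1e-9

    def test_opposite_handedness_flips_q1(self):
        d, t = np.array([[0.8]]), np.array([[0.4]])
        q_plus = jones.compute_q_maps(jones.channel_intensities(d, t, 1.0, handedness=+1))
        q_minus = jones.compute_q_maps(jones.channel_intensities(d, t, 1.0, handedness=-1))
        assert np.isclose(q_plus.q1[0, 0], -q_minus.q1[0, 0])
        assert np.isclose(q_plus.q2[0, 0], -q_minus.q2[0, 0])


class TestPhysicalRetardation:
    def test_msu_crystal_value(self):
        c = jones.CrystalPhysical(birefringence=0.1, thickness_um=0.236, wavelength_um=0.5145)
        assert np.isclose(jones.retardation_from_physical(c), 0.288, atol=5e-4)

    def test_zero_birefringence(self):
        c = jones.CrystalPhysical(birefringence=0.0, thickness_um=1.0, wavelength_um=0.5)
        assert jones.retardation_from_physical(c) == 0.0

    def test_full_wave_plate(self):
        c = jones.CrystalPhysical(birefringence=0.1, thickness_um=5.145, wavelength_um=0.5145)
        assert np.isclose(jones.retardation_from_physical(c), 2 * np.pi, atol=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            jones.CrystalPhysical(birefringence=0.1, thickness_um=-1.0, wavelength_um=0.5)
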