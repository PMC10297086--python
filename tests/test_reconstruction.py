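import numpy as np
import pytest
from scipy.constants import epsilon_0, mu_0, speed_of_light
from scipy.special import j0, y0

import hpwave as hw
from hpwave.reconstruction import (
    DegenerateImageError,
    GreenOperator,
    ImageGrid,
    MediumParameters,
)
from hpwave.acquisition import GeometryError

from conftest import reconstruct_phantom


class TestComplexWavenumber:
    def test_lossless_free_space(self):
        k = hw.complex_wavenumber(1e9, MediumParameters(1.0, 0.0))
        assert k.imag == 0.0
        assert k.real == pytest.approx(2 * np.pi * 1e9 / speed_of_light, rel=1e-12)
        assert k.real == pytest.approx(20.958, rel=1e-3)

    def test_defining_identity(self):
        med = MediumParameters(1.0, 0.3)
        for f in (1e9, 3.7e9, 9e9):
            k = hw.complex_wavenumber(f, med)
            w = 2 * np.pi * f
            expected_sq = w**2 * mu_0 * epsilon_0 - 1j * w * mu_0 * 0.3
            assert k**2 == pytest.approx(expected_sq, rel=1e-12)

    def test_loss_tangent_decreases_with_frequency(self):
        med = MediumParameters(1.0, 0.3)
        k1, k9 = hw.complex_wavenumber(1e9, med), hw.complex_wavenumber(9e9, med)
        assert k1.imag < 0 and k9.imag < 0  # decaying under e^{+jwt}
        assert abs(k1.imag) / k1.real > abs(k9.imag) / k9.real

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            hw.complex_wavenumber(0.0, MediumParameters())


class TestGreen2d:
    def test_matches_bessel_pair(self):
        """Independent special-function oracle: H0^(2) = J0 - i Y0."""
        k = 100.0
        for d in (0.01, 0.05, 0.2):
            expected = -0.25j * (j0(k * d) - 1j * y0(k * d))
            assert hw.green2d(k, d) == pytest.approx(expected, rel=1e-12)

    def test_amplitude_follows_inverse_sqrt_distance(self):
        k = 500.0
        d = 0.12  # kd = 60
        ratio = abs(hw.green2d(k, d)) / abs(hw.green2d(k, 4 * d))
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_asymptotic_form(self):
        k = 300.0
        for d in (0.2, 0.5):
            asym = np.sqrt(2 / (np.pi * k * d)) * np.exp(-1j * (k * d - np.pi / 4)) * -0.25j
            assert abs(hw.green2d(k, d) - asym) / abs(asym) < 0.01

    def test_lossy_decay_monotone(self):
        k = hw.complex_wavenumber(5e9, MediumParameters(1.0, 0.3))
        d = np.linspace(0.01, 0.2, 50)
        mags = np.abs(hw.green2d(k, d))
        assert np.all(np.diff(mags) < 0)

    def test_self_point_rejected(self):
        with pytest.raises(ValueError):
            hw.green2d(100.0, 0.0)


class TestRotationSubtract:
    def test_nine_degree_shift_on_clinical_grid(self):
        geo = hw.make_geometry(n_freq=2)
        rng = np.random.default_rng(0)
        s = rng.standard_normal(geo.shape) + 1j * rng.standard_normal(geo.shape)
        out = hw.rotation_subtract(hw.SignalSet(s, geo), delta=9.0)
        np.testing.assert_allclose(out.s21, s - np.roll(s, -2, axis=1))

    def test_receiver_constant_component_nulled(self, geo_small):
        s = np.ones(geo_small.shape, dtype=complex) * (0.3 - 0.1j)
        out = hw.rotation_subtract(hw.SignalSet(s, geo_small), delta=9.0)
        assert np.all(out.s21 == 0)

    def test_cyclic_sum_telescopes_to_zero(self, geo_small):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(geo_small.shape) + 1j * rng.standard_normal(geo_small.shape)
        out = hw.rotation_subtract(hw.SignalSet(s, geo_small), delta=9.0)
        np.testing.assert_allclose(out.s21.sum(axis=1), 0, atol=1e-12)

    def test_off_grid_delta_rejected(self, geo_small):
        s = np.zeros(geo_small.shape, dtype=complex)
        with pytest.raises(GeometryError):
            hw.rotation_subtract(hw.SignalSet(s, geo_small), delta=4.0)


class TestHuygensReconstruct:
    def test_all_zero_signals_flagged_degenerate(self, geo_small):
        sig = hw.SignalSet(np.zeros(geo_small.shape, dtype=complex), geo_small)
        img = hw.huygens_reconstruct(
            sig, medium=MediumParameters(), grid=ImageGrid(0.06, 16), match_delta=9.0
        )
        assert img.degenerate and np.all(img.intensity == 0)

    def test_point_scatterer_localization(
        self, geo_default_coarse_freq, sigma_medium, grid64, matched_operator64
    ):
        """Noiseless single off-centre scatterer: argmax within 2 pixels."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r, th = rng.uniform(0.008, 0.045), rng.uniform(0, 2 * np.pi)
            x, y = r * np.cos(th), r * np.sin(th)
            ph = hw.BreastPhantom(
                breast_radius=0.06,
                lesions=(hw.Scatterer(x, y, 1.0, 0.005),),
                symmetric_artifact_amplitude=0.01,
            )
            img = reconstruct_phantom(ph, geo_default_coarse_freq, matched_operator64, sigma_medium)
            am = np.unravel_index(np.argmax(img.intensity), img.intensity.shape)
            cx, cy = grid64.pixel_centres[am]
            assert np.hypot(cx - x, cy - y) <= 2 * grid64.pixel_spacing

    def test_end_to_end_median_localization(
        self, geo_default_coarse_freq, sigma_medium, grid64, matched_operator64
    ):
        """Median argmax-to-lesion distance over 20 seeded WF phantoms <= 2 px."""
        errs = []
        for seed in range(20):
            ph = hw.sample_phantom("WF", "C", seed=seed)
            img = reconstruct_phantom(ph, geo_default_coarse_freq, matched_operator64, sigma_medium)
            am = np.unravel_index(np.argmax(img.intensity), img.intensity.shape)
            cx, cy = grid64.pixel_centres[am]
            les = ph.lesions[0]
            errs.append(np.hypot(cx - les.x, cy - les.y))
        assert np.median(errs) <= 2 * grid64.pixel_spacing

    def test_artifact_suppressed_by_rotation_subtraction(self, geo_small, sigma_medium):
        """Pure rotation-invariant artifact: subtracted image is numerically null."""
        ph = hw.BreastPhantom(breast_radius=0.06, symmetric_artifact_amplitude=0.05)
        sig = hw.simulate_s21(ph, geo_small)
        grid = ImageGrid(0.06, 32)
        raw = hw.huygens_reconstruct(sig, medium=sigma_medium, grid=grid)
        sub = hw.huygens_reconstruct(
            hw.rotation_subtract(sig, delta=9.0),
            medium=sigma_medium, grid=grid, match_delta=9.0,
        )
        assert raw.intensity.max() > 0
        assert sub.intensity.max() <= 1e-6 * raw.intensity.max()

    def test_transmitter_incoherent_additivity(self, geo_small, sigma_medium):
        ph = hw.sample_phantom("WF", "B", seed=4)
        sig = hw.rotation_subtract(hw.simulate_s21(ph, geo_small), delta=9.0)
        op = GreenOperator(geo_small, sigma_medium, ImageGrid(0.06, 24), match_delta=9.0)
        full = hw.huygens_reconstruct(sig, operator=op).intensity
        sa, sb = sig.s21.copy(), sig.s21.copy()
        sa[5:] = 0.0
        sb[:5] = 0.0
        part_a = hw.huygens_reconstruct(sig.copy_with(sa), operator=op).intensity
        part_b = hw.huygens_reconstruct(sig.copy_with(sb), operator=op).intensity
        np.testing.assert_allclose(part_a + part_b, full, rtol=1e-10, atol=1e-30)
        # removing transmitters never increases intensity anywhere
        assert np.all(part_a <= full + 1e-30)

    def test_shape_mismatch_rejected(self, geo_small):
        with pytest.raises(ValueError):
            hw.SignalSet(np.zeros((2, 3, 4), dtype=complex), geo_small)


class TestNormalization:
    def make_image(self, seed=0):
        grid = ImageGrid(0.05, 32)
        rng = np.random.default_rng(seed)
        inten = rng.uniform(0.1, 5.0, size=(32, 32))
        inten[~grid.breast_mask] = 0.0
        return hw.MicrowaveImage(inten, grid)

    def test_masked_mean_is_one(self):
        img = hw.normalize_mean1(self.make_image())
        assert img.normalized
        assert img.masked_values.mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_and_idempotence(self):
        img = self.make_image(1)
        scaled = hw.MicrowaveImage(7.3 * img.intensity, img.grid)
        a = hw.normalize_mean1(img)
        b = hw.normalize_mean1(scaled)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)
        c = hw.normalize_mean1(a)
        np.testing.assert_allclose(c.intensity, a.intensity, rtol=1e-12)

    def test_constant_image_becomes_unity(self):
        grid = ImageGrid(0.05, 16)
        inten = np.full((16, 16), 3.7)
        inten[~grid.breast_mask] = 0.0
        img = hw.normalize_mean1(hw.MicrowaveImage(inten, grid))
        assert np.allclose(img.intensity[grid.breast_mask], 1.0)

    def test_degenerate_image_rejected(self):
        grid = ImageGrid(0.05, 16)
        img = hw.MicrowaveImage(np.zeros((16, 16)), grid)
        with pytest.raises(DegenerateImageError):
            hw.normalize_mean1(img)


class TestMip:
    def test_identity_dominance_commutativity(self):
        grid = ImageGrid(0.05, 16)
        rng = np.random.default_rng(2)
        a = hw.MicrowaveImage(rng.uniform(0, 1, (16, 16)), grid)
        b = hw.MicrowaveImage(rng.uniform(0, 1, (16, 16)), grid)
        np.testing.assert_array_equal(hw.mip([a]).intensity, a.intensity)
        m = hw.mip([a, b])
        assert np.all(m.intensity >= a.intensity) and np.all(m.intensity >= b.intensity)
        np.testing.assert_array_equal(m.intensity, hw.mip([b, a]).intensity)

    def test_mixed_grids_rejected(self):
        a = hw.MicrowaveImage(np.zeros((16, 16)), ImageGrid(0.05, 16))
        b = hw.MicrowaveImage(np.zeros((32, 32)), ImageGrid(0.05, 32))
        with pytest.raises(ValueError):
            hw.mip([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            hw.mip([])
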