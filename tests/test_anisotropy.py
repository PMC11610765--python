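"""Anisotropy math and the rotated-frame decomposition."""

import numpy as np
import pytest

from qband.anisotropy import (
    AnisotropyTrace,
    DecompositionFrame,
    anisotropy_from_pair,
    decompose,
    fit_bigaussian,
    fundamental_anisotropy,
    magic_from_pair,
    optimize_beta,
)
from qband.spectral import Spectrum


def make_trace(axis, r):
    return AnisotropyTrace(axis=axis, r=np.full(axis.size, r))


class TestFundamentalAnisotropy:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0.0, 0.4), (90.0, -0.2), (54.7356, 0.0), (73.0, -0.1487)],
    )
    def test_reference_values(self, delta, expected):
        assert fundamental_anisotropy(delta) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fundamental_anisotropy(200.0)


class TestPairCombinations:
    axis = np.linspace(14000.0, 15000.0, 11)

    def test_anisotropy_values(self):
        for ipar, iperp, expected in [(1.8, 0.6, 0.4), (1.0, 1.0, 0.0), (1.0, 2.0, -0.2)]:
            par = Spectrum(self.axis, np.full(11, ipar))
            perp = Spectrum(self.axis, np.full(11, iperp))
            tr = anisotropy_from_pair(par, perp)
            assert np.allclose(tr.r[~tr.mask], expected)

    def test_magic_combination(self):
        par = Spectrum(self.axis, np.full(11, 3.0))
        perp = Spectrum(self.axis, np.zeros(11))
        assert np.allclose(magic_from_pair(par, perp).values, 1.0)

    def test_low_intensity_masked(self):
        vals = np.full(11, 1.0)
        vals[3] = 1e-8
        par = Spectrum(self.axis, vals)
        perp = Spectrum(self.axis, vals)
        assert anisotropy_from_pair(par, perp).mask[3]

    def test_axis_mismatch_raises(self):
        par = Spectrum(self.axis, np.ones(11))
        perp = Spectrum(self.axis + 5.0, np.ones(11))
        with pytest.raises(ValueError, match="axes"):
            anisotropy_from_pair(par, perp)


class TestDecompose:
    axis = np.linspace(14000.0, 15000.0, 101)

    def test_uniform_parallel_anisotropy_kills_orthogonal(self):
        frame = DecompositionFrame(20.0)
        s = Spectrum(self.axis, 1.0 + np.sin(self.axis / 300.0))
        comps = decompose(s, make_trace(self.axis, frame.r_parallel), 20.0)
        assert np.allclose(comps.S_orthogonal.values, 0.0, atol=1e-12)

    def test_halfway_split_at_beta_zero(self):
        s = Spectrum(self.axis, np.ones(101))
        comps = decompose(s, make_trace(self.axis, 0.1), 0.0)
        assert np.allclose(comps.S_parallel.values, 0.5)
        assert np.allclose(comps.S_orthogonal.values, 0.5)

    def test_additivity_is_exact(self):
        rng = np.random.default_rng(11)
        s = Spectrum(self.axis, rng.normal(size=101))
        r = AnisotropyTrace(self.axis, rng.uniform(-0.2, 0.4, 101))
        comps = decompose(s, r, 23.0)
        # bit-for-bit reconstruction at unmasked points
        assert np.array_equal(comps.S_parallel.values + comps.S_orthogonal.values, s.values)

    def test_anisotropy_round_trip(self):
        rng = np.random.default_rng(5)
        s = Spectrum(self.axis, 1.0 + rng.uniform(0.5, 1.0, 101))
        r_in = rng.uniform(-0.19, 0.39, 101)
        comps = decompose(s, AnisotropyTrace(self.axis, r_in), 17.0)
        fr = comps.frame
        r_back = (
            comps.S_parallel.values * fr.r_parallel
            + comps.S_orthogonal.values * fr.r_orthogonal
        ) / s.values
        assert np.allclose(r_back, r_in, atol=1e-10)

    def test_degenerate_frame_rejected(self):
        s = Spectrum(self.axis, np.ones(101))
        with pytest.raises(ValueError):
            decompose(s, make_trace(self.axis, 0.1), 45.0)

    def test_mask_propagates(self):
        mask = np.zeros(101, dtype=bool)
        mask[10] = True
        s = Spectrum(self.axis, np.ones(101))
        comps = decompose(s, AnisotropyTrace(self.axis, np.full(101, 0.1), mask), 10.0)
        assert comps.mask[10] and comps.S_parallel.values[10] == 0.0


class TestOptimizeBeta:
    axis = np.linspace(14000.0, 16000.0, 201)

    @pytest.mark.parametrize("delta", [5.0, 17.0, 32.0, 40.0])
    def test_single_component_recovers_its_angle(self, delta):
        s = Spectrum(self.axis, 1.0 + np.exp(-0.5 * ((self.axis - 15000) / 200.0) ** 2))
        r = make_trace(self.axis, fundamental_anisotropy(delta))
        beta = optimize_beta(s, r, (14500.0, 15500.0))
        assert beta == pytest.approx(delta, abs=0.1)

    @pytest.mark.parametrize("theta", [60.0, 73.0, 80.0, 90.0])
    def test_two_band_mixture_recovers_frame_rotation(self, theta):
        """Bands at 90-theta and 90 deg from the reference: beta* = 90-theta."""
        a = np.exp(-0.5 * ((self.axis - 14600.0) / 150.0) ** 2)
        b = 0.4 * np.exp(-0.5 * ((self.axis - 15800.0) / 150.0) ** 2)
        r0a = fundamental_anisotropy(90.0 - theta)
        r0b = fundamental_anisotropy(90.0)
        iso = a + b
        r = AnisotropyTrace(self.axis, (a * r0a + b * r0b) / iso)
        beta = optimize_beta(Spectrum(self.axis, iso), r, (14300.0, 14900.0))
        assert beta == pytest.approx(90.0 - theta, abs=0.1)

    def test_window_outside_axis_rejected(self):
        s = Spectrum(self.axis, np.ones(201))
        with pytest.raises(ValueError):
            optimize_beta(s, make_trace(self.axis, 0.1), (20000.0, 21000.0))


class TestBiGaussian:
    def test_noiseless_self_fit_is_exact(self):
        axis = np.linspace(15000.0, 18000.0, 300)
        y = -0.5 * np.exp(-0.5 * ((axis - 16000.0) / 250.0) ** 2)
        y += -0.35 * np.exp(-0.5 * ((axis - 17100.0) / 300.0) ** 2)
        fit = fit_bigaussian(Spectrum(axis, y, "delta_A"), (15900.0, 17200.0))
        assert fit.centers == pytest.approx([16000.0, 17100.0], abs=1e-4)
        assert fit.spacing == pytest.approx(1100.0, abs=1e-4)
        assert not fit.degenerate

    def test_two_percent_noise_recovers_spacing(self):
        rng = np.random.default_rng(7)
        axis = np.linspace(15000.0, 18000.0, 300)
        y = -0.5 * np.exp(-0.5 * ((axis - 16000.0) / 250.0) ** 2)
        y += -0.35 * np.exp(-0.5 * ((axis - 17100.0) / 300.0) ** 2)
        y += rng.normal(0.0, 0.02 * np.max(np.abs(y)), axis.size)
        fit = fit_bigaussian(Spectrum(axis, y, "delta_A"), (16000.0, 17100.0))
        assert fit.spacing == pytest.approx(1100.0, abs=25.0)

    def test_single_gaussian_flags_degenerate(self):
        axis = np.linspace(15000.0, 18000.0, 300)
        y = np.exp(-0.5 * ((axis - 16500.0) / 300.0) ** 2)
        fit = fit_bigaussian(Spectrum(axis, y), (16000.0, 17000.0))
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        axis = np.linspace(15000.0, 18000.0, 5)
        with pytest.raises(ValueError):
            fit_bigaussian(Spectrum(axis, np.ones(5)), (16000.0, 17000.0))
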