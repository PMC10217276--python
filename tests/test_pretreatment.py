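import numpy as np
import pytest

from visbrix.pretreatment import (
    METHODS,
    PretreatmentConfig,
    apply,
    derivative,
    sd_sg,
    sg_smooth,
    snv,
    vector_normalize,
)
from visbrix.spectra import SpectrumSet


def _set(matrix, wavelengths=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if wavelengths is None:
        wavelengths = 400 + 5 * np.arange(matrix.shape[1])
    return SpectrumSet(wavelengths, matrix, [f"s{i}" for i in range(matrix.shape[0])])


class TestSNV:
    def test_three_point_example(self):
        out = snv(_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_row_moments(self, noisy_set):
        out = snv(noisy_set)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_named(self):
        with pytest.raises(ValueError, match="s1"):
            snv(_set([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    def test_offset_and_scale_invariance(self, noisy_set):
        base = snv(noisy_set).absorbance
        shifted = snv(noisy_set.with_absorbance(3.0 * noisy_set.absorbance + 7.0))
        np.testing.assert_allclose(shifted.absorbance, base, atol=1e-9)


class TestVectorNormalize:
    def test_two_point_example(self):
        out = vector_normalize(_set([[3.0, 4.0]]))
        np.testing.assert_allclose(out.absorbance[0], [0.6, 0.8], atol=1e-12)

    def test_unit_norm_and_scale_invariance(self, noisy_set):
        out = vector_normalize(noisy_set)
        np.testing.assert_allclose(
            np.linalg.norm(out.absorbance, axis=1), 1.0, atol=1e-12
        )
        scaled = vector_normalize(noisy_set.with_absorbance(10 * noisy_set.absorbance))
        np.testing.assert_allclose(scaled.absorbance, out.absorbance, atol=1e-12)

    def test_zero_row_named(self):
        with pytest.raises(ValueError, match="s0"):
            vector_normalize(_set([[0.0, 0.0, 0.0]]))


class TestSGSmooth:
    def test_polynomial_reproduction(self):
        lam = 400 + 5 * np.arange(30)
        row = (lam / 100.0) ** 2
        out = sg_smooth(_set([row]), window=5, polyorder=2)
        np.testing.assert_allclose(out.absorbance[0][2:-2], row[2:-2], atol=1e-9)

    def test_central_weights_window5_order2(self):
        """Impulse response of the filter equals the least-squares weights
        (-3, 12, 17, 12, -3)/35, derived here from the 5-point quadratic fit."""
        # independent oracle: explicit LS fit at the window center
        x = np.arange(-2, 3, dtype=float)
        design = np.vander(x, 3, increasing=True)
        # weight vector for the fitted value at x=0 = first row of the hat map
        oracle = (np.linalg.pinv(design))[0]
        np.testing.assert_allclose(oracle, np.array([-3, 12, 17, 12, -3]) / 35, atol=1e-12)
        impulse = np.zeros(11)
        impulse[5] = 1.0
        out = sg_smooth(_set([impulse]), window=5, polyorder=2).absorbance[0]
        np.testing.assert_allclose(out[3:8], oracle[::-1], atol=1e-12)

    def test_noise_variance_reduced(self, rng):
        rows = rng.normal(size=(20, 81))
        out = sg_smooth(_set(rows), window=7, polyorder=3)
        assert np.all(out.absorbance.var(axis=1) < rows.var(axis=1))

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (5, 6)])
    def test_bad_params(self, window, polyorder):
        with pytest.raises(ValueError):
            sg_smooth(_set([np.arange(10.0)]), window=window, polyorder=polyorder)


class TestDerivative:
    def test_linear_row_fd_constant(self):
        lam = 400 + 5 * np.arange(20)
        out = derivative(_set([0.01 * lam]), order=1)
        np.testing.assert_allclose(out.absorbance[0], 0.01, atol=1e-12)

    def test_quadratic_row_sd_constant(self):
        lam = 400 + 5 * np.arange(20)
        a = 3e-4
        out = derivative(_set([a * lam**2]), order=2)
        np.testing.assert_allclose(out.absorbance[0], 2 * a, atol=1e-9)

    def test_fd_annihilates_constants(self):
        out = derivative(_set([np.full(15, 2.5)]), order=1)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-15)

    def test_sd_annihilates_affine(self):
        lam = 400 + 5 * np.arange(15)
        out = derivative(_set([0.3 + 0.002 * lam]), order=2)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            derivative(_set([[1.0, 2.0, 3.0]], wavelengths=[400, 405, 415]), order=1)


class TestSDSG:
    def test_offset_independence(self):
        lam = 400 + 5 * np.arange(30)
        cubic = 1e-6 * (lam - 600) ** 3
        a = sd_sg(_set([cubic]))
        b = sd_sg(_set([cubic + 0.8]))
        np.testing.assert_allclose(a.absorbance, b.absorbance, atol=1e-9)

    def test_matches_plain_sd_on_smooth_rows(self):
        lam = 400 + 5 * np.arange(40)
        smooth = np.sin(lam / 120.0)
        via_sdsg = sd_sg(_set([smooth]), window=7, polyorder=3).absorbance[0]
        via_sd = derivative(_set([smooth]), order=2).absorbance[0]
        np.testing.assert_allclose(via_sdsg[4:-4], via_sd[4:-4], rtol=5e-3, atol=1e-7)

    def test_suppresses_noise_below_plain_sd(self, rng):
        lam = 400 + 5 * np.arange(81)
        a = 3e-4
        clean_sd = 2 * a  # analytic second derivative of the quadratic
        rows = a * lam**2 + rng.normal(0, 0.01, (10, 81))
        spect = _set(rows)
        dev_sdsg = sd_sg(spect).absorbance[:, 5:-5] - clean_sd
        dev_sd = derivative(spect, order=2).absorbance[:, 5:-5] - clean_sd
        assert np.var(dev_sdsg) < np.var(dev_sd)


class TestApply:
    def test_none_is_identity(self, noisy_set):
        out = apply(noisy_set, PretreatmentConfig(method="none"))
        np.testing.assert_array_equal(out.absorbance, noisy_set.absorbance)

    @pytest.mark.parametrize("method", [m for m in METHODS if m != "none"])
    def test_dispatch_matches_direct_call(self, method, noisy_set):
        cfg = PretreatmentConfig(method=method)
        out = apply(noisy_set, cfg).absorbance
        direct = {
            "snv": lambda: snv(noisy_set),
            "vn": lambda: vector_normalize(noisy_set),
            "sg": lambda: sg_smooth(noisy_set, cfg.sg_window, cfg.sg_polyorder),
            "fd": lambda: derivative(noisy_set, 1),
            "sd": lambda: derivative(noisy_set, 2),
            "sd-sg": lambda: sd_sg(noisy_set, cfg.sg_window, cfg.sg_polyorder),
        }[method]()
        np.testing.assert_array_equal(out, direct.absorbance)

    def test_unknown_method_lists_valid(self):
        with pytest.raises(ValueError, match="snv"):
            PretreatmentConfig(method="msc")

    @pytest.mark.parametrize("method", METHODS)
    def test_row_wise_permutation_commutes(self, method, noisy_set):
        cfg = PretreatmentConfig(method=method)
        perm = np.random.default_rng(0).permutation(noisy_set.n_samples)
        a = apply(noisy_set, cfg).absorbance[perm]
        b = apply(noisy_set.subset(perm), cfg).absorbance
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_length_preserved_for_all_methods(self, noisy_set):
        for method in METHODS:
            out = apply(noisy_set, PretreatmentConfig(method=method))
            assert out.absorbance.shape == noisy_set.absorbance.shape
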