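import numpy as np
import pytest

from spectrofibro.emsc import (EMSCBasis, ModelError, apply_correction,
                               build_paraffin_basis, build_poly_basis,
                               dewax, estimate_reference, fit_emsc,
                               flag_outliers, reduce_interference)
from spectrofibro.io import SpectralImage, WavenumberAxis
from spectrofibro.synth import default_endmembers, synth_spectrum

from conftest import small_image


@pytest.fixture(scope="module")
def axis():
    return WavenumberAxis(np.arange(900.0, 1801.0, 2.0))


@pytest.fixture(scope="module")
def reference(axis):
    return synth_spectrum(default_endmembers()["glycogen_nodule"], axis)


@pytest.fixture(scope="module")
def paraffin_spec(axis):
    return synth_spectrum(default_endmembers()["paraffin"], axis)


def _basis(axis, reference, paraffin_spec, degree=2):
    interference = (paraffin_spec / np.linalg.norm(paraffin_spec))[:, None]
    poly = build_poly_basis(axis, degree)
    return EMSCBasis(reference, interference, poly, axis)


class TestPolyBasis:
    def test_columns_are_monomials_on_rescaled_axis(self, axis):
        t = build_poly_basis(axis, 3)
        x = 2 * (axis.values - axis.values[0]) / (
            axis.values[-1] - axis.values[0]) - 1
        assert np.allclose(t[:, 0], 1.0)
        assert np.allclose(t[:, 1], x)
        assert np.allclose(t[:, 3], x**3)


class TestParaffinBasis:
    def test_zero_variance_cube_gives_single_mean_column(self, axis,
                                                         paraffin_spec):
        cube = np.tile(paraffin_spec, (3, 3, 1))
        img = SpectralImage(cube, axis)
        basis = build_paraffin_basis(img, 1)
        assert basis.shape == (len(axis), 1)
        assert np.allclose(basis[:, 0], paraffin_spec)

    def test_planted_modes_recovered(self, axis, paraffin_spec):
        # two known variation modes; oracle = eigendecomposition of the
        # exact covariance of the planted coefficients
        rng = np.random.default_rng(0)
        v1 = np.sin(np.linspace(0, 3 * np.pi, len(axis)))
        v2 = np.cos(np.linspace(0, 5 * np.pi, len(axis)))
        v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
        coef = rng.normal(size=(64, 2)) * [2.0, 1.0]
        spectra = paraffin_spec + coef @ np.vstack([v1, v2])
        img = small_image(spectra, axis, (8, 8))
        basis = build_paraffin_basis(img, 3)
        loadings = basis[:, 1:]
        # principal angles between recovered and planted 2-D subspaces
        q1, _ = np.linalg.qr(loadings)
        q2, _ = np.linalg.qr(np.vstack([v1, v2]).T)
        angles = np.arccos(np.clip(np.linalg.svd(q1.T @ q2,
                                                 compute_uv=False), -1, 1))
        assert angles.max() < 1e-6

    def test_sign_convention_deterministic(self, axis, paraffin_spec):
        rng = np.random.default_rng(1)
        spectra = paraffin_spec + 0.1 * rng.normal(size=(30, len(axis)))
        img = small_image(spectra, axis, (5, 6))
        b1 = build_paraffin_basis(img, 4)
        b2 = build_paraffin_basis(img, 4)
        assert np.array_equal(b1, b2)
        for j in range(1, 4):
            col = b1[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_rank_error(self, axis, paraffin_spec):
        cube = np.tile(paraffin_spec, (2, 2, 1))
        with pytest.raises(ModelError):
            build_paraffin_basis(SpectralImage(cube, axis), 10)


class TestEstimateReference:
    def test_homogeneous_cube_returns_input_direction(self, axis, reference,
                                                      paraffin_spec):
        spectra = np.tile(reference, (25, 1))
        img = small_image(spectra, axis, (5, 5))
        interference = (paraffin_spec / np.linalg.norm(paraffin_spec))[:, None]
        m = estimate_reference(img, interference, build_poly_basis(axis, 2))
        cos = m @ reference / np.linalg.norm(m) / np.linalg.norm(reference)
        assert cos > 0.9999
        assert m.mean() == pytest.approx(1.0, abs=1e-9)

    def test_purges_varying_paraffin_better_than_raw_mean(
            self, axis, reference, paraffin_spec):
        rng = np.random.default_rng(2)
        amps = rng.uniform(0.2, 0.8, size=50)
        spectra = reference + amps[:, None] * paraffin_spec
        img = small_image(spectra, axis, (5, 10))
        interference = (paraffin_spec / np.linalg.norm(paraffin_spec))[:, None]
        m = estimate_reference(img, interference, build_poly_basis(axis, 2))

        def cos(a, b):
            return a @ b / np.linalg.norm(a) / np.linalg.norm(b)

        raw_mean = spectra.mean(axis=0)
        assert cos(m, reference) > cos(raw_mean, reference)
        assert cos(m, reference) > 0.9999

    def test_empty_image_rejected(self, axis, reference, paraffin_spec):
        img = small_image(np.tile(reference, (4, 1)), axis, (2, 2))
        img.mask[:] = False
        with pytest.raises(ValueError):
            estimate_reference(img, paraffin_spec[:, None],
                               build_poly_basis(axis, 2))


class TestFitEMSC:
    def test_identity_case(self, axis, reference, paraffin_spec):
        basis = _basis(axis, reference, paraffin_spec)
        img = small_image(np.tile(reference, (4, 1)), axis, (2, 2))
        fit = fit_emsc(img, basis)
        assert np.allclose(fit.a[fit.valid], 1.0, atol=1e-10)
        assert np.abs(fit.b[fit.valid]).max() < 1e-10
        assert np.abs(fit.c[fit.valid]).max() < 1e-10
        assert fit.rmse.max() < 1e-10

    def test_planted_coefficients_recovered_exactly(self, axis, reference,
                                                    paraffin_spec):
        p1 = paraffin_spec / np.linalg.norm(paraffin_spec)
        s = 2.0 * reference + 0.5 * p1 + 0.1
        basis = _basis(axis, reference, paraffin_spec)
        fit = fit_emsc(small_image(s[None, :], axis, (1, 1)), basis)
        assert fit.a[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert fit.b[0, 0, 0] == pytest.approx(0.5, abs=1e-8)
        assert fit.c[0, 0, 0] == pytest.approx(0.1, abs=1e-8)
        assert fit.rmse[0, 0] < 1e-10

    def test_rmse_estimates_noise_sigma(self, axis, reference, paraffin_spec):
        rng = np.random.default_rng(3)
        sigma = 0.05
        spectra = reference + rng.normal(0, sigma, size=(100, len(axis)))
        basis = _basis(axis, reference, paraffin_spec)
        fit = fit_emsc(small_image(spectra, axis, (10, 10)), basis)
        assert fit.rmse[fit.valid].mean() == pytest.approx(sigma, rel=0.1)

    def test_rank_deficient_design_raises(self, axis, reference):
        # interference column == first polynomial column
        poly = build_poly_basis(axis, 2)
        basis = EMSCBasis(reference, poly[:, :1].copy(), poly, axis)
        img = small_image(np.tile(reference, (4, 1)), axis, (2, 2))
        with pytest.raises(ModelError, match="collinear"):
            fit_emsc(img, basis)


class TestApplyCorrection:
    def test_identity_and_algebraic_inversion(self, axis, reference,
                                              paraffin_spec):
        p1 = paraffin_spec / np.linalg.norm(paraffin_spec)
        spectra = np.vstack([reference, 2.0 * reference + 0.5 * p1 + 0.1])
        basis = _basis(axis, reference, paraffin_spec)
        img = small_image(spectra, axis, (1, 2))
        fit = fit_emsc(img, basis)
        out = apply_correction(img, fit, basis)
        assert np.allclose(out.cube[0, 0], reference, atol=1e-10)
        assert np.allclose(out.cube[0, 1], reference, atol=1e-8)

    def test_idempotence(self, axis, reference, paraffin_spec):
        rng = np.random.default_rng(4)
        p1 = paraffin_spec / np.linalg.norm(paraffin_spec)
        a = rng.uniform(0.5, 2.0, 16)
        b = rng.uniform(-0.3, 0.3, 16)
        spectra = a[:, None] * reference + b[:, None] * p1
        basis = _basis(axis, reference, paraffin_spec)
        img = small_image(spectra, axis, (4, 4))
        corrected = apply_correction(img, fit_emsc(img, basis), basis)
        refit = fit_emsc(corrected, basis)
        assert np.allclose(refit.a[refit.valid], 1.0, atol=1e-6)
        assert np.abs(refit.b[refit.valid]).max() < 1e-6

    def test_scale_equivariance(self, axis, reference, paraffin_spec):
        lam = 3.7
        rng = np.random.default_rng(5)
        spectra = (rng.uniform(0.5, 2.0, 9)[:, None] * reference
                   + 0.01 * rng.normal(size=(9, len(axis))))
        basis = _basis(axis, reference, paraffin_spec)
        img1 = small_image(spectra, axis, (3, 3))
        img2 = small_image(lam * spectra, axis, (3, 3))
        fit1, fit2 = fit_emsc(img1, basis), fit_emsc(img2, basis)
        assert np.allclose(fit2.a, lam * fit1.a)
        assert np.array_equal(fit1.outlier, fit2.outlier)
        out1 = apply_correction(img1, fit1, basis)
        out2 = apply_correction(img2, fit2, basis)
        assert np.allclose(out1.cube, out2.cube, atol=1e-9)


class TestFlagOutliers:
    def test_homogeneous_noise_free_cube_has_none(self, axis, reference,
                                                  paraffin_spec):
        basis = _basis(axis, reference, paraffin_spec)
        img = small_image(np.tile(reference, (16, 1)), axis, (4, 4))
        fit = fit_emsc(img, basis, kappa=5.0)
        assert fit.outlier.sum() == 0

    def test_planted_flat_pixel_is_flagged(self, axis, reference,
                                           paraffin_spec):
        spectra = np.tile(reference, (16, 1))
        spectra[5] = 1e-6  # bare substrate
        basis = _basis(axis, reference, paraffin_spec)
        fit = fit_emsc(small_image(spectra, axis, (4, 4)), basis, kappa=5.0)
        flagged = np.nonzero(fit.outlier.ravel())[0]
        assert list(flagged) == [5]

    def test_flags_monotone_in_kappa(self, axis, reference, paraffin_spec):
        rng = np.random.default_rng(6)
        spectra = reference + rng.normal(0, 0.02, size=(64, len(axis)))
        spectra[3] += rng.normal(0, 0.3, size=len(axis))
        basis = _basis(axis, reference, paraffin_spec)
        fit = fit_emsc(small_image(spectra, axis, (8, 8)), basis, flag=False)
        f3 = flag_outliers(fit, kappa=3.0).outlier
        f5 = flag_outliers(fit, kappa=5.0).outlier
        fnone = flag_outliers(fit, kappa=None).outlier
        assert (f5 <= f3).all()  # kappa=5 flags a subset of kappa=3
        assert (fnone <= f5).all()


class TestReduceInterference:
    def test_polynomial_modes_are_dropped(self, axis, paraffin_spec):
        poly = build_poly_basis(axis, 3)
        interference = np.column_stack([
            paraffin_spec, poly[:, 1] / np.linalg.norm(poly[:, 1])])
        red = reduce_interference(interference, poly)
        assert red.shape[1] == 1  # the pure-baseline column vanished
        # remaining column orthogonal to the baseline span
        assert np.abs(poly.T @ red[:, 0]).max() < 1e-8 * np.abs(poly).max()


class TestDewaxPipeline:
    def test_paraffin_suppression_on_phantom(self, phantom30):
        from spectrofibro.synth import PhantomConfig, make_phantom

        config, truth, cube, paraffin, _ = phantom30
        clean_cfg = PhantomConfig(**{**config.__dict__,
                                     "paraffin_amp": (0.0, 0.0)})
        _, cube0, paraffin0, _ = make_phantom(clean_cfg)
        corr1, _, _ = dewax(cube, paraffin)
        corr0, _, _ = dewax(cube0, paraffin0)
        v = corr1.axis.values
        idx = [np.argmin(np.abs(v - c)) for c in (1378, 1462)]
        both = corr1.mask & corr0.mask
        raw = cube.cube[both][:, idx].mean() - cube0.cube[both][:, idx].mean()
        res = corr1.cube[both][:, idx].mean() - corr0.cube[both][:, idx].mean()
        suppression = 100.0 * (1.0 - abs(res) / abs(raw))
        assert suppression >= 95.0
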