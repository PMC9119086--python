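"""Accuracy theory: covariance, translation-error moment, Fourier statistics, R."""

import numpy as np
import pytest

from morphoreg import (
    Contour,
    SectionPairSpec,
    ShapeParams,
    contour_fourier,
    contour_roundness,
    kappa_approx,
    kappa_exact,
    radial_covariance,
    roundness_index,
    spatial_angle_cos,
    theoretical_translation_variance,
)
from morphoreg.accuracy_theory import PERFECT_CIRCLE_FLOOR, pointwise_radius_variance
from morphoreg.sphere_model import (
    _k_squared,
    harmonic_basis_matrix,
    lambda_variance,
    sample_coefficients,
    section_latitudes,
)
from scipy.special import eval_legendre, lpmv


def _simulate_equator_radii(params, n_draws, n_theta, seed, phi=np.pi / 2):
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta
    basis = harmonic_basis_matrix(params, thetas, np.full(n_theta, phi))
    coeffs = sample_coefficients(params, n_draws, seed)
    return thetas, 1 + np.einsum("pnm,knm->kp", basis, coeffs)


class TestSpatialAngle:
    def test_reference_directions(self):
        assert spatial_angle_cos(0.3, 1.1, 0.3, 1.1) == pytest.approx(1.0)
        assert spatial_angle_cos(0.3, 1.1, 0.3 + np.pi, np.pi - 1.1) == pytest.approx(-1.0)
        assert spatial_angle_cos(0.0, np.pi / 2, np.pi / 2, np.pi / 2) == pytest.approx(0.0)


class TestRadialCovariance:
    def test_psi_zero_is_pointwise_variance(self, default_params):
        ns = default_params.degrees
        lam = lambda_variance(ns, default_params)
        expected = np.sum(lam * (2 * ns + 1) / (4 * np.pi))
        assert radial_covariance(1.0, default_params) == pytest.approx(expected)

    def test_matches_term_by_term_series(self):
        # independent oracle: explicit loop over degrees with eval_legendre
        params = ShapeParams(alpha=1.0, beta=0.1, p=4.0, n_max=40)
        for cos_psi in (0.0, -0.7, 0.35):
            expected = sum(
                lambda_variance(n, params) * (2 * n + 1) / (4 * np.pi)
                * eval_legendre(n, cos_psi)
                for n in range(2, 41)
            )
            assert radial_covariance(cos_psi, params) == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo(self, default_params):
        rng = np.random.default_rng(0)
        pairs = rng.uniform([0, 0.3, 0, 0.3], [2 * np.pi, np.pi - 0.3, 2 * np.pi, np.pi - 0.3],
                            size=(5, 4))
        coeffs = sample_coefficients(default_params, 5000, seed=1)
        for t1, f1, t2, f2 in pairs:
            basis = harmonic_basis_matrix(default_params, [t1, t2], [f1, f2])
            r = 1 + np.einsum("pnm,knm->kp", basis, coeffs)
            emp = np.cov(r[:, 0], r[:, 1])[0, 1]
            theo = radial_covariance(spatial_angle_cos(t1, f1, t2, f2), default_params)
            v1, v2 = r[:, 0].var(ddof=1), r[:, 1].var(ddof=1)
            se = np.sqrt((v1 * v2 + theo**2) / 4999)
            assert abs(emp - theo) < 3 * se

    def test_gram_matrices_positive_semidefinite(self, default_params):
        rng = np.random.default_rng(7)
        for _ in range(4):
            thetas = rng.uniform(0, 2 * np.pi, 8)
            phis = rng.uniform(0.2, np.pi - 0.2, 8)
            cos_psi = spatial_angle_cos(
                thetas[:, None], phis[:, None], thetas[None, :], phis[None, :]
            )
            gram = radial_covariance(cos_psi, default_params)
            assert np.allclose(gram, gram.T)
            assert np.linalg.eigvalsh(gram).min() > -1e-10


class TestTranslationVariance:
    def test_deterministic_sphere_has_zero_error(self):
        params = ShapeParams(alpha=1e14, beta=1.0)
        var = theoretical_translation_variance(params, SectionPairSpec())
        assert var == pytest.approx(0.0, abs=1e-8)

    def test_zero_thickness_has_zero_error(self, default_params):
        spec = SectionPairSpec(thickness=0.0)
        assert theoretical_translation_variance(default_params, spec) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_monte_carlo_second_moment(self):
        # the module's headline property, checked here at one setting
        # (more settings in the acceptance suite)
        from morphoreg.landmark_registration import simulate_translation_errors

        params = ShapeParams(alpha=100.0, beta=0.1)
        spec = SectionPairSpec(n_landmarks=64)
        theo = theoretical_translation_variance(params, spec)
        sq = simulate_translation_errors(params, spec, 2000, seed=2)[:, 0] ** 2
        se = sq.std(ddof=1) / np.sqrt(2000)
        assert abs(sq.mean() - theo) < 3 * se


class TestContourFourier:
    def _contour(self, radii, latitude=np.pi / 2):
        n = len(radii)
        return Contour(
            angles=2 * np.pi * np.arange(n) / n, radii=np.asarray(radii, float),
            origin=(0.0, 0.0), latitude=latitude,
        )

    def test_perfect_circle_spectrum_vanishes(self):
        spectrum = contour_fourier(self._contour(np.full(128, 37.0)), 20)
        assert np.all(spectrum.bn < 1e-12)

    def test_single_mode_amplitude(self):
        thetas = 2 * np.pi * np.arange(128) / 128
        for lat, s in ((np.pi / 2, 1.0), (1.0, np.sin(1.0))):
            spectrum = contour_fourier(
                self._contour(1 + 0.1 * np.sin(3 * thetas), latitude=lat), 10,
                normalize=False,
            )
            assert spectrum.bns[2] == pytest.approx(0.1 * s, rel=1e-9)
            assert spectrum.bn[2] == pytest.approx(0.01 * s**2, rel=1e-9)
            other = np.delete(spectrum.bn, 2)
            assert np.all(other < 1e-10)

    def test_bn_identity(self):
        rng = np.random.default_rng(3)
        spectrum = contour_fourier(self._contour(20 + rng.uniform(-1, 1, 96)), 15)
        assert np.array_equal(spectrum.bn, spectrum.bnc**2 + spectrum.bns**2)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            contour_fourier(self._contour(np.full(16, 1.0)), 10)


class TestKappa:
    def test_vanishes_with_vanishing_lambda(self):
        params = ShapeParams(alpha=1e15, beta=1.0)
        assert kappa_exact(3, params) < 1e-14
        assert kappa_approx(3, params) < 1e-14

    def test_leading_term_underestimates_and_converges(self):
        # the l = n term is a lower bound; for fast-decaying lambda (beta
        # dominant) the even-degree error is small, odd degrees keep an
        # irreducible tail from the l = n + 2 term
        params = ShapeParams(alpha=4.0, beta=0.5)
        for n in range(2, 11):
            exact = kappa_exact(n, params)
            approx = kappa_approx(n, params)
            assert approx <= exact
            assert approx / exact > 0.6
        assert kappa_approx(2, params) / kappa_exact(2, params) > 0.95

    def test_variance_of_fourier_coefficient(self, default_params):
        _, r = _simulate_equator_radii(default_params, 5000, 128, seed=4)
        spec_f = np.fft.rfft(r, axis=1)
        for n in (2, 3, 5):
            bns = (-2.0 / 128) * spec_f[:, n].imag
            kappa = kappa_exact(n, default_params)
            se = kappa * np.sqrt(2.0 / 4999)
            assert abs(bns.var(ddof=1) - kappa) < 3 * se

    def test_low_degree_rejected(self, default_params):
        with pytest.raises(ValueError):
            kappa_exact(1, default_params)
        with pytest.raises(ValueError):
            kappa_approx(0, default_params)


class TestRoundnessIndex:
    def _spectrum_of(self, radii):
        n = len(radii)
        contour = Contour(
            angles=2 * np.pi * np.arange(n) / n, radii=radii,
            origin=(0.0, 0.0), latitude=np.pi / 2,
        )
        return contour_fourier(contour, 20)

    def test_perfect_circle_is_capped(self):
        result = roundness_index(self._spectrum_of(np.full(128, 10.0)))
        assert result.capped
        assert result.R == pytest.approx(-np.log(PERFECT_CIRCLE_FLOOR))

    def test_doubling_coefficients_shifts_R_by_log4(self):
        rng = np.random.default_rng(5)
        thetas = 2 * np.pi * np.arange(128) / 128
        radii = 1 + 0.05 * np.sin(2 * thetas) + 0.02 * np.cos(5 * thetas)
        base = roundness_index(self._spectrum_of(radii))
        spectrum = self._spectrum_of(radii)
        doubled = type(spectrum)(
            degrees=spectrum.degrees, bnc=2 * spectrum.bnc, bns=2 * spectrum.bns
        )
        assert roundness_index(doubled).R == pytest.approx(base.R - np.log(4), rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        thetas = 2 * np.pi * np.arange(96) / 96
        radii = 15 * (1 + 0.07 * np.sin(4 * thetas))
        r1 = roundness_index(self._spectrum_of(radii)).R
        r2 = roundness_index(self._spectrum_of(7.3 * radii)).R
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_mean_R_increases_with_beta(self):
        # larger beta damps high-degree deformation -> rounder -> larger R
        means = []
        for beta in (1e-4, 1e-3, 1e-2, 1e-1):
            params = ShapeParams(alpha=1000.0, beta=beta)
            _, r = _simulate_equator_radii(params, 600, 64, seed=7)
            rs = []
            thetas = 2 * np.pi * np.arange(64) / 64
            for k in range(600):
                contour = Contour(
                    angles=thetas, radii=np.maximum(150 * r[k], 1e-6),
                    origin=(0.0, 0.0), latitude=np.pi / 2,
                )
                rs.append(contour_roundness(contour).R)
            means.append(np.mean(rs))
        assert np.all(np.diff(means) > 0)
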