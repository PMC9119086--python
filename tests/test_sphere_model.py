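"""Spherical deformation model: variance law, sampling, sectioning, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphoreg import (
    Contour,
    SectionPairSpec,
    ShapeParams,
    default_dataset_design,
    evaluate_radius,
    lambda_variance,
    make_section_pair,
    project_contour,
    render_contour_image,
    sample_shape,
    section_latitudes,
)
from morphoreg.accuracy_theory import pointwise_radius_variance
from morphoreg.sphere_model import harmonic_basis_matrix, sample_coefficients


class TestLambdaVariance:
    def test_degree_two_equals_one_over_alpha(self):
        for alpha, beta, p in [(1.0, 1.0, 4.0), (3.5, 0.2, 2.5), (100.0, 7.0, 6.0)]:
            params = ShapeParams(alpha=alpha, beta=beta, p=p)
            assert lambda_variance(2, params) == pytest.approx(1.0 / alpha)

    def test_plugin_value(self):
        assert lambda_variance(3, ShapeParams(alpha=1.0, beta=1.0, p=4.0)) == pytest.approx(
            1.0 / 66.0
        )

    def test_strictly_decreasing_over_range(self):
        params = ShapeParams(alpha=1.0, beta=0.1, p=4.0)
        lam = lambda_variance(np.arange(2, 41), params)
        assert np.all(lam > 0)
        assert np.all(np.diff(lam) < 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.5, 1e4), beta=st.floats(1e-4, 10.0),
        scale=st.floats(1.1, 5.0), n=st.integers(2, 40),
    )
    def test_increasing_precision_never_increases_lambda(self, alpha, beta, scale, n):
        base = ShapeParams(alpha=alpha, beta=beta)
        assert lambda_variance(n, ShapeParams(alpha=alpha * scale, beta=beta)) <= (
            lambda_variance(n, base)
        )
        assert lambda_variance(n, ShapeParams(alpha=alpha, beta=beta * scale)) <= (
            lambda_variance(n, base)
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            lambda_variance(1, ShapeParams(alpha=1.0, beta=1.0))
        with pytest.raises(ValueError):
            ShapeParams(alpha=-1.0, beta=1.0)
        with pytest.raises(ValueError):
            ShapeParams(alpha=1.0, beta=1.0, p=2.0)


class TestSampling:
    def test_same_seed_reproduces_coefficients(self, default_params):
        a = sample_shape(default_params, 42)
        b = sample_shape(default_params, 42)
        c = sample_shape(default_params, 43)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert not np.array_equal(a.coeffs, c.coeffs)

    def test_huge_alpha_gives_near_sphere(self):
        params = ShapeParams(alpha=1e12, beta=1.0)
        shape = sample_shape(params, 0)
        assert np.abs(shape.coeffs).max() < 1e-4
        r = evaluate_radius(shape, 1.0, 1.0)
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_coefficient_variance_matches_law(self, default_params):
        coeffs = sample_coefficients(default_params, 5000, seed=5)
        n_max = default_params.n_max
        for n in (2, 5, 10):
            lam = lambda_variance(n, default_params)
            block = coeffs[:, n - 2, n_max - n : n_max + n + 1]
            sample_var = block.var(axis=0, ddof=1)
            # SE of a normal sample variance: lam * sqrt(2 / (reps - 1))
            se = lam * np.sqrt(2.0 / 4999)
            assert np.all(np.abs(sample_var - lam) < 3 * se + 1e-12)


def _zero_shape(params):
    from morphoreg import HarmonicShape

    n_max = params.n_max
    return HarmonicShape(
        params=params, coeffs=np.zeros((n_max - 1, 2 * n_max + 1)), seed=0
    )


class TestEvaluateRadius:
    def test_zero_coefficients_give_unit_radius(self, default_params):
        shape = _zero_shape(default_params)
        thetas = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        phis = np.linspace(0.1, np.pi - 0.1, 17)
        assert np.allclose(evaluate_radius(shape, thetas, phis), 1.0)

    def test_sphere_average_is_one(self, default_params):
        # area-weighted 64x64 quadrature (Gauss-Legendre in cos phi, uniform
        # in theta): every harmonic with n >= 2 integrates to zero
        shape = sample_shape(default_params, 3)
        n_grid = 64
        thetas = 2 * np.pi * np.arange(n_grid) / n_grid
        mu, weights = np.polynomial.legendre.leggauss(n_grid)
        phis = np.arccos(mu)
        tt, pp = np.meshgrid(thetas, phis)
        r = evaluate_radius(shape, tt.ravel(), pp.ravel()).reshape(n_grid, n_grid)
        mean = float(weights @ r.mean(axis=1)) / 2.0
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_pointwise_variance_matches_addition_theorem(self, default_params):
        basis = harmonic_basis_matrix(default_params, [1.0], [2.0])
        coeffs = sample_coefficients(default_params, 5000, seed=6)
        r = 1 + np.einsum("pnm,knm->kp", basis, coeffs)[:, 0]
        expected = pointwise_radius_variance(default_params)
        se = expected * np.sqrt(2.0 / 4999)
        assert abs(r.var(ddof=1) - expected) < 3 * se
        assert r.mean() == pytest.approx(1.0, abs=3 * np.sqrt(expected / 5000))

    def test_angle_domain_enforced(self, default_params):
        shape = sample_shape(default_params, 0)
        with pytest.raises(ValueError):
            evaluate_radius(shape, -0.1, 1.0)
        with pytest.raises(ValueError):
            evaluate_radius(shape, 1.0, 3.5)


class TestSectioning:
    def test_zero_thickness_cuts_the_equator(self):
        assert section_latitudes(0.0, 150.0) == pytest.approx((np.pi / 2, np.pi / 2))

    def test_default_geometry(self):
        phi_s, phi_t = section_latitudes(40.0, 150.0)
        assert phi_s == pytest.approx(np.arccos(2 / 15))
        assert phi_t == pytest.approx(np.arccos(-2 / 15))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d=st.floats(0.0, 299.0))
    def test_latitude_symmetry_is_exact(self, d):
        phi_s, phi_t = section_latitudes(d, 150.0)
        assert abs(np.sin(phi_s) - np.sin(phi_t)) < 1e-12

    def test_thickness_beyond_diameter_rejected(self):
        with pytest.raises(ValueError):
            section_latitudes(300.0, 150.0)

    def test_projected_circle_radius(self):
        shape = _zero_shape(ShapeParams(alpha=1e6, beta=1.0, mean_radius=150.0))
        contour = project_contour(shape, np.pi / 2, 64)
        assert np.allclose(contour.radii, 150.0)
        assert contour.angles[1] - contour.angles[0] == pytest.approx(2 * np.pi / 64)

    def test_projection_mean_radius(self, default_params):
        phi = 1.2
        n = 64
        basis = harmonic_basis_matrix(default_params, 2 * np.pi * np.arange(n) / n,
                                      np.full(n, phi))
        coeffs = sample_coefficients(default_params, 2000, seed=8)
        r = 1 + np.einsum("pnm,knm->kp", basis, coeffs)
        rho = default_params.mean_radius * np.sin(phi) * r
        expected = default_params.mean_radius * np.sin(phi)
        se = rho.mean(axis=1).std(ddof=1) / np.sqrt(2000)
        assert abs(rho.mean() - expected) < 3 * se

    def test_pole_cut_is_degenerate(self, default_params):
        shape = sample_shape(default_params, 1)
        with pytest.raises(ValueError):
            project_contour(shape, 0.0, 32)


class TestSectionPair:
    def test_degenerate_spec_reproduces_identical_contours(self, default_params):
        spec = SectionPairSpec(thickness=0.0, translation=(0.0, 0.0), n_landmarks=32)
        s, t = make_section_pair(default_params, spec, seed=3)
        assert np.allclose(s.radii, t.radii)
        assert s.origin == t.origin

    def test_template_origin_carries_translation(self, default_params):
        spec = SectionPairSpec()  # thickness 40, translation (4.5, 4.5)
        s, t = make_section_pair(default_params, spec, seed=4)
        assert t.origin == (s.origin[0] + 4.5, s.origin[1] + 4.5)
        assert len(s) == len(t) == spec.n_landmarks
        assert np.array_equal(s.angles, t.angles)

    def test_same_seed_bit_identical(self, default_params):
        spec = SectionPairSpec()
        s1, t1 = make_section_pair(default_params, spec, seed=9)
        s2, t2 = make_section_pair(default_params, spec, seed=9)
        assert np.array_equal(s1.radii, s2.radii)
        assert np.array_equal(t1.radii, t2.radii)


class TestRendering:
    def _circle(self, radius, center, n=180):
        thetas = 2 * np.pi * np.arange(n) / n
        return Contour(
            angles=thetas, radii=np.full(n, float(radius)),
            origin=center, latitude=np.pi / 2,
        )

    def test_disc_area(self):
        image = render_contour_image(self._circle(10.0, (32.0, 32.0)), (64, 64))
        interior = (image < 0.8).sum()
        assert abs(interior - np.pi * 100) / (np.pi * 100) < 0.05

    def test_translation_equivariance(self):
        a = render_contour_image(self._circle(10.0, (24.0, 30.0)), (64, 64))
        b = render_contour_image(self._circle(10.0, (27.0, 30.0)), (64, 64))
        assert np.array_equal(np.roll(a, 3, axis=1), b)

    def test_contour_exceeding_canvas_rejected(self):
        with pytest.raises(ValueError):
            render_contour_image(self._circle(100.0, (32.0, 32.0)), (64, 64))


def test_default_dataset_design_has_121_subsets():
    design = default_dataset_design()
    assert len(design.subsets) == 121
    assert len(set(design.subsets)) == 121
    assert design.p == 4.0
    assert design.mean_radius == 150.0
    assert design.thickness == 40.0
    assert design.translation == (4.5, 4.5)
    assert design.pairs_per_subset == 1000
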