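"""Registration-accuracy theory for the spherical deformation model.

Links the shape statistics of a local structure to the error of the
translation-only landmark registration of its two adjacent-section contours:

* radial covariance of the normalized radius field on K,
* the closed-form second moment of the translation-estimate error,
* Fourier-coefficient statistics of a contour (variance kappa_n, chi^2(2)
  law of the squared magnitudes b_n),
* the roundness index R = -log(sum b_n) used to select sphere-like regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lpmv

from .sphere_model import (
    Contour,
    SectionPairSpec,
    ShapeParams,
    _k_squared,
    lambda_variance,
    section_latitudes,
)

#: Floor on sum(b_n) below which a contour counts as a perfect circle.
PERFECT_CIRCLE_FLOOR = 1e-12

#: Default number of Fourier degrees summed by the roundness index.
DEFAULT_N_HARM = 20

#: Default roundness threshold separating sphere-like from irregular regions
#: (natural-log scale of the index).
DEFAULT_R_THRES = 6.0


@dataclass(frozen=True)
class FourierSpectrum:
    """Fourier coefficients of a contour's normalized radius function."""

    degrees: np.ndarray
    bnc: np.ndarray
    bns: np.ndarray

    @property
    def bn(self) -> np.ndarray:
        return self.bnc**2 + self.bns**2

    @property
    def total_power(self) -> float:
        return float(np.sum(self.bn))


@dataclass(frozen=True)
class RoundnessIndex:
    R: float
    n_harm: int
    capped: bool


def spatial_angle_cos(theta1, phi1, theta2, phi2):
    """cos(psi) between unit directions omega(theta1, phi1), omega(theta2, phi2)."""
    c = (
        np.sin(phi1) * np.sin(phi2) * np.cos(np.asarray(theta1) - np.asarray(theta2))
        + np.cos(phi1) * np.cos(phi2)
    )
    return np.clip(c, -1.0, 1.0)


def radial_covariance(cos_psi, params: ShapeParams):
    """Cov(r(omega1), r(omega2)) = sum_n lambda_n (2n+1)/(4 pi) P_n(cos psi)."""
    cos_psi = np.clip(np.asarray(cos_psi, dtype=float), -1.0, 1.0)
    ns = params.degrees
    lam = lambda_variance(ns, params)
    coeffs = np.zeros(params.n_max + 1)
    coeffs[2:] = lam * (2 * ns + 1) / (4 * np.pi)
    out = np.polynomial.legendre.legval(cos_psi, coeffs)
    return float(out) if out.shape == () else out


def pointwise_radius_variance(params: ShapeParams) -> float:
    """Var r(theta, phi) at any fixed direction (covariance at psi = 0)."""
    return float(radial_covariance(1.0, params))


def theoretical_translation_variance(params: ShapeParams, spec: SectionPairSpec) -> float:
    """Closed-form second moment E[(dt_hat - dt)^2] of the X-translation error.

    With landmarks at theta_i = 2 pi i / N on the two symmetric latitude
    contours, the estimator error is (r̄ sin phi / N) sum_i cos(theta_i)
    (r_iT - r_iS); expanding its square gives

        r̄^2 sin^2(phi) / N^2 * sum_ij 2 cos(theta_i) cos(theta_j)
            * (Cov_iTjT - Cov_iSjT),

    where the covariances follow from the radial covariance evaluated at the
    spatial angles between same-section and cross-section directions.
    The analysis for the Y-translation is identical by symmetry.
    """
    n = spec.n_landmarks
    thetas = 2 * np.pi * np.arange(n) / n
    phi_s, phi_t = section_latitudes(spec.thickness, params.mean_radius)
    sin_phi = np.sin(phi_s)
    cos_s, cos_t = np.cos(phi_s), np.cos(phi_t)

    dtheta = thetas[:, None] - thetas[None, :]
    cos_tt = np.clip(sin_phi**2 * np.cos(dtheta) + cos_t * cos_t, -1, 1)
    cos_st = np.clip(sin_phi**2 * np.cos(dtheta) + cos_s * cos_t, -1, 1)
    cov_diff = radial_covariance(cos_tt, params) - radial_covariance(cos_st, params)

    weights = np.cos(thetas)
    quad = 2.0 * weights @ cov_diff @ weights
    var = (params.mean_radius * sin_phi / n) ** 2 * quad
    return max(float(var), 0.0)


# --------------------------------------------------------------------------
# Fourier statistics of a contour
# --------------------------------------------------------------------------

def contour_fourier(
    contour: Contour, n_harm: int = DEFAULT_N_HARM, normalize: bool = True
) -> FourierSpectrum:
    """Fourier coefficients b_n^c, b_n^s of the contour radius function.

    b_n^s = sin(phi0)/pi * integral of r(theta) sin(n theta) dtheta, with the
    integral evaluated by the trapezoid rule over the equally spaced samples
    (exact for band-limited r).  With ``normalize`` the radii are first
    divided by their mean, which makes the spectrum — and hence the roundness
    index — invariant to region size.
    """
    n_samples = len(contour)
    if n_samples < 2 * n_harm + 1:
        raise ValueError(
            f"{n_samples} samples alias degrees up to {n_harm}; "
            f"need at least {2 * n_harm + 1}"
        )
    rho = np.asarray(contour.radii, dtype=float)
    if normalize:
        rho = rho / rho.mean()
    sin_phi0 = np.sin(contour.latitude)
    # periodic trapezoid == rectangle rule: sum rho * e^{-i n theta} = rfft
    spectrum = np.fft.rfft(rho)
    degrees = np.arange(1, n_harm + 1)
    bnc = (2.0 * sin_phi0 / n_samples) * spectrum[degrees].real
    bns = (-2.0 * sin_phi0 / n_samples) * spectrum[degrees].imag
    return FourierSpectrum(degrees=degrees, bnc=bnc, bns=bns)


def kappa_exact(n: int, params: ShapeParams, phi0: float = np.pi / 2) -> float:
    """Variance kappa_n of b_n^s (and b_n^c): the full harmonic series.

    With the orthonormal real harmonics used throughout this package,
    b_n^s = sin(phi0) sum_{l>=n} a_ln k_l^n P_l^n(cos phi0), so

        kappa_n = sin^2(phi0) sum_{l=n}^{n_max} (k_l^n P_l^n(cos phi0))^2 lambda_l.
    """
    if n < 2:
        raise ValueError("kappa_n is defined for degrees n >= 2")
    ls = np.arange(n, params.n_max + 1)
    if len(ls) == 0:
        return 0.0
    cos0 = np.cos(phi0)
    terms = _k_squared(ls, n) * lpmv(n, ls, cos0) ** 2 * lambda_variance(ls, params)
    return float(np.sin(phi0) ** 2 * np.sum(terms))


def kappa_approx(n: int, params: ShapeParams, phi0: float = np.pi / 2) -> float:
    """Leading-term (l = n) approximation of kappa_n, valid when lambda decays fast."""
    if n < 2:
        raise ValueError("kappa_n is defined for degrees n >= 2")
    cos0 = np.cos(phi0)
    c_n = np.sin(phi0) ** 2 * _k_squared(n, n) * lpmv(n, n, cos0) ** 2
    return float(c_n * lambda_variance(n, params))


def roundness_index(spectrum: FourierSpectrum) -> RoundnessIndex:
    """R = -log(sum_n b_n), capped for (near-)perfect circles.

    Natural logarithm; degrees start at n = 1 so residual origin offsets
    penalize the score (n = 1 is near zero when the centroid is the origin).
    Large R means a near-circular contour, which the accuracy theory links
    to smaller translation-estimate variance.
    """
    total = spectrum.total_power
    if total < PERFECT_CIRCLE_FLOOR:
        return RoundnessIndex(
            R=float(-np.log(PERFECT_CIRCLE_FLOOR)), n_harm=len(spectrum.degrees), capped=True
        )
    return RoundnessIndex(R=float(-np.log(total)), n_harm=len(spectrum.degrees), capped=False)


def contour_roundness(contour: Contour, n_harm: int = DEFAULT_N_HARM) -> RoundnessIndex:
    """Convenience: roundness index straight from a contour."""
    return roundness_index(contour_fourier(contour, n_harm))
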