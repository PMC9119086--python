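"""Spherical deformation model for sphere-like local neuronal structures.

A local structure K is a random star-shaped surface whose normalized radius
is 1 plus a truncated real spherical-harmonic series with independent
Gaussian coefficients, ``a_nm ~ N(0, lambda_n)`` where
``1/lambda_n = alpha + beta * (n**p - 2**p)``.  Cutting K with two parallel
planes a thickness ``d`` apart yields a pair of adjacent-section contours;
a known in-plane translation applied to one of them emulates the deformation
introduced by slicing and imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, lpmv


# --------------------------------------------------------------------------
# parameters and domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Parameters of the spherical deformation model.

    Attributes
    ----------
    alpha : float
        Global-shape precision (> 0); large alpha damps every harmonic.
    beta : float
        Local-shape precision (> 0); large beta damps high degrees faster.
    p : float
        Smoothness exponent (> 2) controlling how fast lambda_n decays.
    n_max : int
        Truncation degree of the harmonic series (>= 2).
    mean_radius : float
        Mean radius r̄ of the structure, in pixels (> 0).
    """

    alpha: float
    beta: float
    p: float = 4.0
    n_max: int = 40
    mean_radius: float = 150.0

    def __post_init__(self) -> None:
        if not self.p > 2:
            raise ValueError(f"smoothness exponent p must be > 2, got {self.p}")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")
        if not self.mean_radius > 0:
            raise ValueError("mean_radius must be positive")

    @property
    def degrees(self) -> np.ndarray:
        return np.arange(2, self.n_max + 1)


@dataclass(frozen=True)
class SectionPairSpec:
    """Geometry of an adjacent-section pair cut from one local structure."""

    thickness: float = 40.0
    translation: tuple[float, float] = (4.5, 4.5)
    n_landmarks: int = 64

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be non-negative")
        if self.n_landmarks < 4:
            raise ValueError("need at least 4 landmarks")


@dataclass(frozen=True)
class HarmonicShape:
    """One sampled local structure: coefficients a_nm for 2 <= n <= n_max.

    ``coeffs`` has shape (n_max - 1, 2 * n_max + 1); row k holds degree
    n = k + 2, column j holds order m = j - n_max (entries with |m| > n are 0).
    """

    params: ShapeParams
    coeffs: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        expected = (self.params.n_max - 1, 2 * self.params.n_max + 1)
        if self.coeffs.shape != expected:
            raise ValueError(
                f"coefficient array has shape {self.coeffs.shape}, expected {expected}"
            )


@dataclass(frozen=True)
class Contour:
    """Radius samples of a section contour at equally spaced polar angles.

    Coordinates: x = column (rightward), y = row (downward), 0-based, with
    pixel centers at integer coordinates; angles counterclockwise from +x.
    ``latitude`` is the polar latitude phi of the cutting plane on K
    (pi/2 for real image regions, where it only fixes the sin(phi) factor
    of the Fourier normalization).
    """

    angles: np.ndarray
    radii: np.ndarray
    origin: tuple[float, float]
    latitude: float

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.radii):
            raise ValueError("angles and radii must have equal length")
        step = 2 * np.pi / len(self.angles)
        if not np.allclose(np.diff(self.angles), step):
            raise ValueError("angles must be equally spaced over [0, 2*pi)")
        if np.any(self.radii <= 0):
            raise ValueError("all contour radii must be positive")

    def __len__(self) -> int:
        return len(self.angles)

    def points(self) -> np.ndarray:
        """Landmark coordinates (N, 2) as (x, y) = origin + rho * (cos, sin)."""
        x = self.origin[0] + self.radii * np.cos(self.angles)
        y = self.origin[1] + self.radii * np.sin(self.angles)
        return np.column_stack([x, y])


# --------------------------------------------------------------------------
# variance law and harmonic basis
# --------------------------------------------------------------------------

def lambda_variance(n, params: ShapeParams):
    """Variance lambda_n = 1 / (alpha + beta * (n**p - 2**p)) for degree n >= 2."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 2):
        raise ValueError("lambda_n is defined for degrees n >= 2")
    lam = 1.0 / (params.alpha + params.beta * (n_arr ** params.p - 2.0 ** params.p))
    return lam if lam.shape else float(lam)


def _k_squared(n: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Squared normalizer (k_n^m)^2 of the real orthonormal harmonics.

    (k_n^0)^2 = (2n+1)/(4 pi); for m > 0 the cos/sin pair shares
    (k_n^m)^2 = (2n+1)/(2 pi) * (n-m)!/(n+m)!.
    """
    n = np.asarray(n, dtype=float)
    m = np.asarray(np.abs(m), dtype=float)
    log_ratio = gammaln(n - m + 1) - gammaln(n + m + 1)
    k2 = (2 * n + 1) / (2 * np.pi) * np.exp(log_ratio)
    return np.where(m == 0, (2 * n + 1) / (4 * np.pi), k2)


def harmonic_basis_matrix(params: ShapeParams, thetas, phis) -> np.ndarray:
    """Real orthonormal spherical harmonics phi_nm at given directions.

    Returns an array of shape (n_points, n_max - 1, 2 * n_max + 1) laid out
    like :class:`HarmonicShape` coefficients, so that
    ``r = 1 + einsum('pnm,nm->p', basis, coeffs)``.

    Basis convention (matching the coefficient variance law): for m < 0 the
    angular factor is cos(|m| theta), for m > 0 it is sin(m theta); the
    radial part is k_n^|m| P_n^|m|(cos phi).  The normalizers satisfy
    sum_m phi_nm^2 = (2n+1)/(4 pi) (addition theorem at psi = 0).
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    phis = np.broadcast_to(np.atleast_1d(np.asarray(phis, dtype=float)), thetas.shape)
    n_max = params.n_max
    cos_phi = np.cos(phis)

    basis = np.zeros((len(thetas), n_max - 1, 2 * n_max + 1))
    for n in range(2, n_max + 1):
        row = n - 2
        for m in range(0, n + 1):
            radial = np.sqrt(_k_squared(n, m)) * lpmv(m, n, cos_phi)
            if m == 0:
                basis[:, row, n_max] = radial
            else:
                basis[:, row, n_max - m] = radial * np.cos(m * thetas)
                basis[:, row, n_max + m] = radial * np.sin(m * thetas)
    return basis


def coefficient_std(params: ShapeParams) -> np.ndarray:
    """Per-entry standard deviation sqrt(lambda_n) laid out like coeffs."""
    n_max = params.n_max
    std = np.zeros((n_max - 1, 2 * n_max + 1))
    for n in range(2, n_max + 1):
        lam = lambda_variance(n, params)
        std[n - 2, n_max - n : n_max + n + 1] = np.sqrt(lam)
    return std


def sample_shape(params: ShapeParams, seed: int) -> HarmonicShape:
    """Draw one local structure: independent a_nm ~ N(0, lambda_n)."""
    coeffs = sample_coefficients(params, 1, seed)[0]
    return HarmonicShape(params=params, coeffs=coeffs, seed=seed)


def sample_coefficients(params: ShapeParams, n_draws: int, seed: int) -> np.ndarray:
    """Batch coefficient sampling: (n_draws, n_max - 1, 2 n_max + 1)."""
    rng = np.random.default_rng(seed)
    std = coefficient_std(params)
    draws = rng.standard_normal((n_draws,) + std.shape)
    return draws * std


def evaluate_radius(shape: HarmonicShape, theta, phi):
    """Normalized radius r(theta, phi) = 1 + sum a_nm phi_nm(theta, phi)."""
    theta_arr = np.asarray(theta, dtype=float)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(theta_arr < 0) or np.any(theta_arr >= 2 * np.pi):
        raise ValueError("theta must lie in [0, 2*pi)")
    if np.any(phi_arr < 0) or np.any(phi_arr > np.pi):
        raise ValueError("phi must lie in [0, pi]")
    scalar = theta_arr.ndim == 0 and phi_arr.ndim == 0
    basis = harmonic_basis_matrix(shape.params, theta_arr.ravel(), phi_arr.ravel())
    r = 1.0 + np.einsum("pnm,nm->p", basis, shape.coeffs)
    return float(r[0]) if scalar else r.reshape(np.broadcast(theta_arr, phi_arr).shape)


# --------------------------------------------------------------------------
# sectioning
# --------------------------------------------------------------------------

def section_latitudes(d: float, mean_radius: float) -> tuple[float, float]:
    """Latitudes of two parallel cutting planes a distance d apart.

    The planes are placed symmetrically about the equator of K, so
    cos(phi_S) = d / (2 r̄) and cos(phi_T) = -d / (2 r̄); this makes
    sin(phi_S) = sin(phi_T) hold exactly, as the accuracy analysis assumes.
    """
    if d < 0:
        raise ValueError("thickness must be non-negative")
    if d >= 2 * mean_radius:
        raise ValueError(
            f"thickness {d} >= diameter {2 * mean_radius}: planes miss the structure"
        )
    c = d / (2.0 * mean_radius)
    return float(np.arccos(c)), float(np.arccos(-c))


_MIN_RADIUS = 1e-6  # floor keeping rasterizable contours strictly star-shaped


@lru_cache(maxsize=64)
def _contour_basis(params: ShapeParams, phi: float, n_points: int) -> np.ndarray:
    """Memoized harmonic basis at the equally spaced contour angles."""
    thetas = 2 * np.pi * np.arange(n_points) / n_points
    return harmonic_basis_matrix(params, thetas, np.full(n_points, phi))


def project_contour(
    shape: HarmonicShape,
    phi: float,
    n_points: int,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Contour:
    """Contour of K on the latitude-phi cutting plane.

    rho_i = r̄ * sin(phi) * r(theta_i, phi) at theta_i = 2 pi i / N.  Radii
    are floored at a tiny positive value; with realistic (alpha, beta) the
    floor is never active.
    """
    if n_points < 4:
        raise ValueError("need at least 4 contour points")
    if np.sin(phi) <= 1e-12:
        raise ValueError("degenerate contour: cutting plane tangent to the pole")
    thetas = 2 * np.pi * np.arange(n_points) / n_points
    basis = _contour_basis(shape.params, float(phi), n_points)
    r = 1.0 + np.einsum("pnm,nm->p", basis, shape.coeffs)
    rho = shape.params.mean_radius * np.sin(phi) * r
    rho = np.maximum(rho, _MIN_RADIUS)
    return Contour(angles=thetas, radii=rho, origin=origin, latitude=float(phi))


def make_section_pair(
    params: ShapeParams,
    spec: SectionPairSpec,
    seed: int,
    base_origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[Contour, Contour]:
    """Cut one sampled structure into an adjacent-section contour pair.

    Both contours come from the same HarmonicShape, at the two symmetric
    latitudes; the template contour T carries the known in-plane translation
    (its origin is S's origin plus ``spec.translation``).  Landmark i in both
    contours sits at the same longitude theta_i.
    """
    shape = sample_shape(params, seed)
    phi_s, phi_t = section_latitudes(spec.thickness, params.mean_radius)
    contour_s = project_contour(shape, phi_s, spec.n_landmarks, origin=base_origin)
    origin_t = (base_origin[0] + spec.translation[0], base_origin[1] + spec.translation[1])
    contour_t = project_contour(shape, phi_t, spec.n_landmarks, origin=origin_t)
    return contour_s, contour_t


# --------------------------------------------------------------------------
# rendering and the dataset design
# --------------------------------------------------------------------------

def render_contour_image(
    contour: Contour,
    canvas: tuple[int, int],
    interior: float = 0.45,
    boundary: float = 0.15,
    background: float = 0.85,
) -> np.ndarray:
    """Rasterize a contour as a filled polygon on a grayscale canvas.

    Dark interior, darker 2-px inner boundary, light background; binary fill
    with fixed gray levels (no anti-aliasing) so rendering is deterministic.
    """
    from skimage.draw import polygon
    from skimage.morphology import binary_erosion, disk

    height, width = canvas
    pts = contour.points()
    if (
        pts[:, 0].min() < 0 or pts[:, 0].max() > width - 1
        or pts[:, 1].min() < 0 or pts[:, 1].max() > height - 1
    ):
        raise ValueError("contour exceeds canvas bounds")
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=canvas)
    mask = np.zeros(canvas, dtype=bool)
    mask[rr, cc] = True
    inner = binary_erosion(mask, disk(2))
    image = np.full(canvas, background, dtype=np.float32)
    image[mask] = boundary
    image[inner] = interior
    return image


@dataclass(frozen=True)
class DatasetDesign:
    """The synthetic-dataset grid: one subset per (alpha, beta) pair."""

    alphas: np.ndarray
    betas: np.ndarray
    pairs_per_subset: int = 1000
    p: float = 4.0
    mean_radius: float = 150.0
    thickness: float = 40.0
    translation: tuple[float, float] = (4.5, 4.5)

    @property
    def subsets(self) -> list[tuple[float, float]]:
        return [(float(a), float(b)) for a in self.alphas for b in self.betas]

    def subset_params(self, alpha: float, beta: float) -> ShapeParams:
        return ShapeParams(alpha=alpha, beta=beta, p=self.p, mean_radius=self.mean_radius)

    def pair_spec(self, n_landmarks: int = 64) -> SectionPairSpec:
        return SectionPairSpec(
            thickness=self.thickness,
            translation=self.translation,
            n_landmarks=n_landmarks,
        )


def default_dataset_design(pairs_per_subset: int = 1000) -> DatasetDesign:
    """Default 11 x 11 (alpha, beta) grid: 121 subsets.

    The grid values are an implementation choice: log-spaced over ranges that
    span visually near-circular to strongly deformed contours at p = 4 while
    keeping the radius field essentially positive (physical validity).
    """
    return DatasetDesign(
        alphas=np.logspace(2, 4, 11),
        betas=np.logspace(-2, 0, 11),
        pairs_per_subset=pairs_per_subset,
    )
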