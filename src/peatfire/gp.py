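"""Matérn-3/2 Gaussian-process propagation of combustion-model uncertainty.

Combustion residuals are treated as a spatially correlated field over the
year's burned pixels: a unit-variance Matérn-3/2 kernel (length scale 25 km
by default, with correlations beyond the length scale cut to zero) plus a
heteroscedastic diagonal noise term D = diag((σ_CC,i · A_i)²) built from
each model's residual spread and the pixel area.  The posterior covariance
at the burned pixels,

    K_post = K - K (K + D)^-1 K,

is summed (1ᵀ K_post 1) into the annual total's variance.  For large pixel
counts the Gram matrix is replaced by its Nyström low-rank reconstruction
from m randomly sampled inducing pixels per processing batch
(K̃ = K_nm K_mm⁻¹ K_mn, cost O(m²n)) combined with the Woodbury identity so
the full n×n matrix is never materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

SQRT3 = np.sqrt(3.0)

#: Default length scale (m): the coarsest predictor resolution, beyond which
#: spatial correlation is ignored.
DEFAULT_LENGTH_SCALE = 25_000.0
DEFAULT_INDUCING = 1000

#: Jitter added to kernel diagonals before inversion.  The hard distance
#: cutoff technically breaks exact positive semi-definiteness, so a small
#: ridge keeps factorizations stable.
JITTER = 1e-8


def matern32(distance, length_scale: float = DEFAULT_LENGTH_SCALE,
             cutoff: float | None = None):
    """Matérn-3/2 kernel value (1 + √3 d/ℓ) exp(-√3 d/ℓ) for d ≥ 0.

    With ``cutoff`` set, values at distances beyond it are zeroed (the
    25-km correlation cutoff by default lives in :func:`kernel_matrix`).
    """
    if length_scale <= 0:
        raise ValueError("length scale must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    s = SQRT3 * d / length_scale
    k = (1.0 + s) * np.exp(-s)
    if cutoff is not None:
        k = np.where(d > cutoff, 0.0, k)
    return k if k.ndim else float(k)


def kernel_matrix(coords: np.ndarray, length_scale: float = DEFAULT_LENGTH_SCALE,
                  cutoff: float | None = None,
                  coords2: np.ndarray | None = None) -> np.ndarray:
    """Gram (or cross-Gram) matrix of the Matérn-3/2 kernel over pixel centers.

    ``cutoff`` defaults to the length scale when left unset with
    ``cutoff='default'`` semantics handled by callers; pass ``None`` for no
    cutoff.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    other = coords if coords2 is None else np.atleast_2d(np.asarray(coords2, float))
    d = cdist(coords, other)
    return matern32(d, length_scale, cutoff=cutoff)


@dataclass
class PixelVariance:
    """Heteroscedastic noise of scaled per-pixel emissions.

    ``sigma_cc`` is the residual standard deviation of the combustion model
    (g C m⁻², constant per model per run unless inflated per pixel) and
    ``area`` the pixel area (m²); the noise variance per pixel is
    (σ_CC,i · A_i)².
    """

    sigma_cc: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_cc = np.broadcast_arrays(
            np.asarray(self.sigma_cc, float), np.asarray(self.area, float))[0].copy()
        self.area = np.asarray(self.area, dtype=float)
        if np.any(self.sigma_cc < 0) or np.any(self.area < 0):
            raise ValueError("sigma_cc and area must be non-negative")

    @property
    def noise_diag(self) -> np.ndarray:
        return (self.sigma_cc * self.area) ** 2


def covariance_matrices(coords: np.ndarray, noise: PixelVariance,
                        length_scale: float = DEFAULT_LENGTH_SCALE,
                        cutoff: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(K, K_prior, K_posterior) at the burned pixels.

    K_prior = K + D with D the heteroscedastic noise diagonal;
    K_posterior = K - K K_prior⁻¹ K.  A singular prior (possible only with
    zero noise and duplicated points) is regularized with a logged jitter.
    """
    k = kernel_matrix(coords, length_scale, cutoff)
    d = noise.noise_diag
    if d.shape[0] != k.shape[0]:
        raise ValueError("noise length must match number of pixels")
    prior = k + np.diag(d)
    try:
        sol = solve(prior, k, assume_a="pos")
    except np.linalg.LinAlgError:
        logger.warning("singular prior covariance; applying jitter %.1e", JITTER)
        prior = prior + JITTER * np.eye(k.shape[0])
        sol = solve(prior, k, assume_a="pos")
    posterior = k - k @ sol
    posterior = (posterior + posterior.T) / 2.0
    return k, prior, posterior


@dataclass
class NystromFactors:
    """Low-rank reconstruction K̃ = K_nm K_mm⁻¹ K_mn in factored form.

    ``b`` is K_nm L⁻ᵀ for the Cholesky factor L of K_mm (+ jitter), so
    K̃ = B Bᵀ without materializing n×n; ``inducing`` holds the sampled
    pixel indices.
    """

    b: np.ndarray
    inducing: np.ndarray

    @property
    def n(self) -> int:
        return self.b.shape[0]

    @property
    def m(self) -> int:
        return len(self.inducing)

    def materialize(self) -> np.ndarray:
        """Dense K̃ (small n only)."""
        return self.b @ self.b.T


def nystrom_approx(coords: np.ndarray, m: int,
                   length_scale: float = DEFAULT_LENGTH_SCALE,
                   cutoff: float | None = None,
                   rng: np.random.Generator | int | None = None
                   ) -> NystromFactors:
    """Nyström factors from m uniformly sampled inducing pixels.

    At m = n (all points inducing) the reconstruction is exact.  An
    ill-conditioned K_mm falls back to an eigenvalue pseudo-inverse with a
    logged tolerance.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if not 1 <= m <= n:
        raise ValueError("inducing count m must satisfy 1 <= m <= n")
    rng = np.random.default_rng(rng)
    inducing = np.sort(rng.choice(n, size=m, replace=False))
    z = coords[inducing]
    k_mm = kernel_matrix(z, length_scale, cutoff)
    k_nm = kernel_matrix(coords, length_scale, cutoff, coords2=z)
    try:
        chol = np.linalg.cholesky(k_mm + JITTER * np.eye(m))
        b = np.linalg.solve(chol, k_nm.T).T  # K_nm L^-T
    except np.linalg.LinAlgError:
        tol = 1e-10
        logger.warning("ill-conditioned K_mm; eigenvalue pseudo-inverse, tol %.0e", tol)
        w, v = np.linalg.eigh(k_mm)
        keep = w > tol * w.max()
        b = k_nm @ (v[:, keep] / np.sqrt(w[keep]))
    return NystromFactors(b=b, inducing=inducing)


@dataclass
class AnnualUncertainty:
    """Annual emission total with its GP-propagated standard deviation."""

    total_g_c: float
    total_corrected_g_c: float
    variance: float
    year: int | None = None

    @property
    def sd_g_c(self) -> float:
        return float(np.sqrt(max(self.variance, 0.0)))

    @property
    def total_pg_c(self) -> float:
        return self.total_g_c / 1e15

    @property
    def sd_pg_c(self) -> float:
        return self.sd_g_c / 1e15


def annual_uncertainty(pixel_cc: np.ndarray, coords: np.ndarray,
                       noise: PixelVariance,
                       length_scale: float = DEFAULT_LENGTH_SCALE,
                       cutoff: float | None = None,
                       m: int | None = DEFAULT_INDUCING,
                       mu_res: float = 0.0,
                       rng: np.random.Generator | int | None = None,
                       year: int | None = None) -> AnnualUncertainty:
    """Variance of the annual emission total through the posterior covariance.

    The per-pixel emission error carries amplitude s_i = σ_CC,i · A_i (g C)
    and the Matérn correlation structure, so

        Var(total) = sᵀ K_post s,   K_post = K̃ - K̃ (K̃ + D)⁻¹ K̃,

    computed through the Nyström factors and the Woodbury identity when
    m < n (never forming n×n matrices).  With ℓ→0 this reduces to the sum
    of scaled pixelwise posterior variances; with zero residual noise the
    posterior — and the variance — vanish.  The residual mean ``mu_res``
    (g C m⁻², from model evaluation) is applied as a bias correction to the
    total before reporting.  Zero burned pixels give zero variance.
    """
    pixel_cc = np.asarray(pixel_cc, dtype=float)
    n = pixel_cc.size
    total = float(np.nansum(pixel_cc * noise.area))
    corrected = total - mu_res * float(noise.area.sum())
    if n == 0:
        return AnnualUncertainty(0.0, 0.0, 0.0, year)
    s = noise.sigma_cc * noise.area
    if m is None or m >= n:
        _, _, post = covariance_matrices(coords, noise, length_scale, cutoff)
        var = float(s @ post @ s)
        return AnnualUncertainty(total, corrected, var, year)
    d = noise.noise_diag
    if np.any(d <= 0):
        # Woodbury needs invertible D; fall back to a tiny floor
        d = np.maximum(d, JITTER)
    fac = nystrom_approx(coords, m, length_scale, cutoff, rng)
    b = fac.b  # (n, m): K~ = B B^T
    u = b.T @ s                         # B^T s
    v = b @ u                           # K~ s
    dinv_v = v / d
    core = np.eye(fac.m) + (b.T * (1.0 / d)) @ b
    cf = cho_factor(core)
    w = dinv_v - (b @ cho_solve(cf, b.T @ dinv_v)) / d  # (K~ + D)^-1 K~ s
    var = float(u @ u - v @ w)
    return AnnualUncertainty(total, corrected, var, year)
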