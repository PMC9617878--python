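"""Matern covariance, penalised-complexity (PC) priors and Gaussian random
field simulation.

The spatial convention throughout the package: ``rho`` is the *range* in
metres at which the Matern correlation has fallen to roughly 0.13, i.e.
kappa = sqrt(8 nu) / rho. This is the standard geostatistical (SPDE)
parameterisation, so priors stated for "the range" act on an interpretable
distance.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "matern_cov",
    "pc_prior_range_logpdf",
    "pc_prior_sd_logpdf",
    "pc_range_rate",
    "pc_sd_rate",
    "grf_sample_grid",
    "grf_sample_grid_fast",
    "grf_sample_points",
]


def matern_cov(distances, rho, sigma, nu=1.0):
    """Matern covariance C(d) = sigma^2 2^(1-nu)/Gamma(nu) (kappa d)^nu K_nu(kappa d).

    ``rho`` is the correlation range (kappa = sqrt(8 nu)/rho); C(0) = sigma^2
    exactly. Vectorised over ``distances``.
    """
    if rho <= 0 or sigma <= 0:
        raise ValueError("rho and sigma must be positive")
    if nu <= 0:
        raise ValueError("nu must be positive")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    kappa = np.sqrt(8.0 * nu) / rho
    x = kappa * d
    with np.errstate(invalid="ignore"):
        corr = (2.0 ** (1.0 - nu) / special.gamma(nu)) * x**nu * special.kv(nu, x)
    corr = np.where(x == 0.0, 1.0, corr)
    # K_nu underflows for huge x; the limit is 0 correlation
    corr = np.nan_to_num(corr, nan=0.0)
    return sigma**2 * corr


def pc_range_rate(rho0, alpha=0.05):
    """Rate lambda of the PC range prior such that P(rho < rho0) = alpha.

    The PC prior for the range of a 2-d Matern field is
    pi(rho) = lambda rho^-2 exp(-lambda / rho), an inverse-exponential:
    P(rho < rho0) = exp(-lambda / rho0).
    """
    if not 0 < alpha < 1 or rho0 <= 0:
        raise ValueError("need rho0 > 0 and alpha in (0, 1)")
    return -np.log(alpha) * rho0


def pc_sd_rate(sigma0, alpha=0.05):
    """Rate lambda of the exponential PC prior on the marginal SD with
    P(sigma > sigma0) = alpha."""
    if not 0 < alpha < 1 or sigma0 <= 0:
        raise ValueError("need sigma0 > 0 and alpha in (0, 1)")
    return -np.log(alpha) / sigma0


def pc_prior_range_logpdf(rho, rho0, alpha=0.05):
    """Log-density of the PC prior on the Matern range (see pc_range_rate)."""
    lam = pc_range_rate(rho0, alpha)
    rho = np.asarray(rho, dtype=float)
    out = np.full(rho.shape if rho.ndim else (), -np.inf, dtype=float)
    ok = rho > 0
    out = np.where(ok, np.log(lam) - 2.0 * np.log(np.where(ok, rho, 1.0)) - lam / np.where(ok, rho, 1.0), out)
    return out


def pc_prior_sd_logpdf(sigma, sigma0, alpha=0.05):
    """Log-density of the exponential PC prior on a marginal SD."""
    lam = pc_sd_rate(sigma0, alpha)
    sigma = np.asarray(sigma, dtype=float)
    return np.where(sigma >= 0, np.log(lam) - lam * sigma, -np.inf)


def _circulant_embedding_spectrum(nx, ny, dx, dy, rho, sigma, nu):
    """Eigenvalues of the periodic embedding of the Matern covariance on a
    (2 nx) x (2 ny) torus. Tiny negative eigenvalues from imperfect
    embedding are clipped to zero (approximation error is negligible when
    the embedding is at least a couple of ranges wide)."""
    mx, my = 2 * nx, 2 * ny
    ix = np.minimum(np.arange(mx), mx - np.arange(mx)) * dx
    iy = np.minimum(np.arange(my), my - np.arange(my)) * dy
    d = np.hypot(ix[:, None], iy[None, :])
    cov = matern_cov(d, rho=rho, sigma=sigma, nu=nu)
    lam = np.fft.fft2(cov).real
    return np.maximum(lam, 0.0)


def grf_sample_grid(shape, cell_size, rho, sigma, rng, nu=1.0, n_fields=1):
    """Sample stationary zero-mean Matern Gaussian fields on a regular grid.

    Uses circulant embedding (exact up to clipped negative eigenvalues), so
    a fixed generator state gives a bit-reproducible field. Returns an array
    of shape ``(n_fields, ny, nx)`` (squeezed when n_fields == 1).
    """
    ny, nx = shape
    if sigma == 0.0:
        out = np.zeros((n_fields, ny, nx))
        return out[0] if n_fields == 1 else out
    lam = _circulant_embedding_spectrum(nx, ny, cell_size, cell_size, rho, sigma, nu)
    mx, my = 2 * nx, 2 * ny
    scale = np.sqrt(lam / (mx * my))
    fields = np.empty((n_fields, ny, nx))
    for i in range(n_fields):
        noise = rng.standard_normal((my, mx)) + 1j * rng.standard_normal((my, mx))
        f = np.fft.fft2(noise * scale.T).real
        fields[i] = f[:ny, :nx]
    return fields[0] if n_fields == 1 else fields


def grf_sample_grid_fast(shape, cell_size, rho, sigma, rng, nu=1.0, n_fields=1,
                         oversample=6.0):
    """Matern field on a fine grid via a coarse circulant-embedding draw plus
    bilinear interpolation.

    The coarse spacing is rho / oversample, which resolves the correlation
    structure while cutting the FFT size by orders of magnitude for
    long-range fields; at ranges comparable to the cell size it falls back
    to the exact per-cell sampler.
    """
    from scipy import ndimage

    ny, nx = shape
    factor = max(1, int(rho / (oversample * cell_size)))
    if factor == 1:
        return grf_sample_grid(shape, cell_size, rho, sigma, rng, nu, n_fields)
    if sigma == 0.0:
        out = np.zeros((n_fields, ny, nx))
        return out[0] if n_fields == 1 else out
    cny, cnx = ny // factor + 2, nx // factor + 2
    coarse = grf_sample_grid((cny, cnx), cell_size * factor, rho, sigma, rng, nu, n_fields)
    coarse = coarse[None] if n_fields == 1 else coarse
    # fine-cell centres expressed in coarse-grid index coordinates
    iy = ((np.arange(ny) + 0.5) / factor - 0.5)
    ix = ((np.arange(nx) + 0.5) / factor - 0.5)
    yy, xx = np.meshgrid(iy, ix, indexing="ij")
    fields = np.stack(
        [ndimage.map_coordinates(c, [yy, xx], order=1, mode="nearest") for c in coarse]
    )
    return fields[0] if n_fields == 1 else fields


def grf_sample_points(coords, rho, sigma, rng, nu=1.0, n_fields=1, jitter=1e-8):
    """Sample Matern fields at arbitrary coordinates by dense Cholesky.

    Suitable for up to a few thousand points; used for pixel-level fields in
    the outcome-model simulations.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if sigma == 0.0:
        out = np.zeros((n_fields, n))
        return out[0] if n_fields == 1 else out
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = matern_cov(d, rho=rho, sigma=sigma, nu=nu)
    cov[np.diag_indices(n)] += jitter * sigma**2
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, n_fields))
    fields = (chol @ z).T
    return fields[0] if n_fields == 1 else fields
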