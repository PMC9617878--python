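"""Zero-inflated negative binomial (ZINB) probability primitives.

The observation model for pixel-year canopy loss (rounded to whole m^2) is a
mixture of a point mass at zero, with weight ``pi``, and a negative binomial
component parameterised by its mean ``mu`` and dispersion ``k``:

    P(y) = pi * 1[y = 0] + (1 - pi) * NB(y; mu, k)

with ``Var(y | NB) = mu + mu^2 / k``; ``k -> inf`` recovers the Poisson.
Everything here is written against log-scale quantities so that extreme
``pi`` and large counts stay finite.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["nb_logpmf", "zinb_logpmf", "zinb_rvs", "zinb_mean"]


def nb_logpmf(y, mu, k):
    """Negative binomial log-pmf in mean/dispersion form.

    NB(y; mu, k) = C(y + k - 1, y) (k/(k+mu))^k (mu/(k+mu))^y.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(mu <= 0) or np.any(k <= 0):
        raise ValueError("mu and k must be positive")
    log_k_over = np.log(k) - np.log(k + mu)
    log_mu_over = np.log(mu) - np.log(k + mu)
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * log_k_over
        + y * log_mu_over
    )


def zinb_logpmf(y, mu, k, pi):
    """Log-pmf of the zero-inflated negative binomial.

    For y = 0 the mixture is evaluated with logaddexp so that pi close to
    0 or 1 and tiny NB zero-mass are handled without underflow; ``pi = 1``
    returns log 1 = 0 at y = 0 and -inf elsewhere.
    """
    y = np.asarray(y, dtype=float)
    mu, k = np.broadcast_arrays(np.asarray(mu, float), np.asarray(k, float))
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must be in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1m_pi = np.log1p(-pi)
    nb = nb_logpmf(np.maximum(y, 0.0), mu, k)
    out = np.where(np.isneginf(log1m_pi), -np.inf, log1m_pi + nb)
    zero = y == 0
    if np.any(zero):
        mixed = np.logaddexp(
            np.broadcast_to(log_pi, out.shape),
            np.broadcast_to(log1m_pi + nb, out.shape),
        )
        out = np.where(zero, mixed, out)
    return out


def zinb_mean(mu, k, pi):
    """Expected count: zero-inflation thins the NB mean to (1 - pi) mu."""
    return (1.0 - np.asarray(pi, float)) * np.asarray(mu, float)


def zinb_rvs(mu, k, pi, rng):
    """Draw ZINB variates elementwise (shapes broadcast).

    NB is simulated as the standard gamma-Poisson mixture so that the
    mean/dispersion parameterisation is exact.
    """
    mu, k, pi = np.broadcast_arrays(
        np.asarray(mu, float), np.asarray(k, float), np.asarray(pi, float)
    )
    lam = rng.gamma(shape=k, scale=mu / k)
    y = rng.poisson(lam)
    suppress = rng.random(size=y.shape) < pi
    return np.where(suppress, 0, y)
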