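"""Wrapped (pseudo-hyperbolic Gaussian) normal distribution on the hyperboloid.

The distribution G(mu, sigma^2 I) is the push-forward of an isotropic
Gaussian in the tangent space at the vertex mu_0 through parallel transport
to mu followed by the exponential map.  Sampling is the three-step process:

    (a) draw x ~ N(0, sigma^2 I) in T_{mu_0} H^d  (last coordinate 0),
    (b) parallel-transport x along the geodesic mu_0 -> mu,
    (c) project to the manifold with Exp_mu.

Because both maps are invertible with tractable Jacobian, the density has
the closed form

    ln p(z) = ln N(xbar | 0, sigma^2 I) - (d - 1) ln( sinh(r) / r ),

with r = arccosh(-<mu,z>_L) the geodesic distance from mu and xbar the
tangent pre-image of z.  Only isotropic covariance is implemented; the
matrix-factorization loss uses a single variance per embedding side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lorentz_core import (
    check_point,
    exp_map,
    hyperbolic_distance,
    origin,
    parallel_transport,
)

__all__ = ["WrappedNormal"]


def _log_sinhc(r: np.ndarray) -> np.ndarray:
    """ln(sinh(r)/r), with the series limit r^2/6 for small r and an
    overflow-free form r - ln(2r) + ln(1 - e^{-2r}) for large r."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    small = r < 1e-6
    large = r > 20.0
    mid = ~(small | large)
    out[small] = r[small] ** 2 / 6.0
    rm = r[mid]
    out[mid] = np.log(np.sinh(rm) / rm)
    rl = r[large]
    out[large] = rl - np.log(2.0 * rl) + np.log1p(-np.exp(-2.0 * rl))
    return out


@dataclass(frozen=True)
class WrappedNormal:
    """Pseudo-hyperbolic Gaussian G(mu, sigma2 * I) on H^d.

    Parameters
    ----------
    mu
        Location, a point on the hyperboloid (length d+1).
    sigma2
        Isotropic tangent-space variance; must be positive.
    """

    mu: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        object.__setattr__(self, "mu", check_point(self.mu))

    @property
    def dim(self) -> int:
        """Intrinsic dimension d of the hyperbolic space."""
        return self.mu.shape[-1] - 1

    def sample(self, count: int, rng) -> np.ndarray:
        """Draw ``count`` points, as a (count, d+1) array on the hyperboloid.

        ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
        Deterministic given the seed.
        """
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count}")
        rng = np.random.default_rng(rng)
        d = self.dim
        tangent0 = np.zeros((count, d + 1))
        tangent0[:, :d] = rng.normal(0.0, np.sqrt(self.sigma2), size=(count, d))
        at_mu = parallel_transport(self.mu, tangent0, validate=False)
        return exp_map(np.broadcast_to(self.mu, at_mu.shape), at_mu, validate=False)

    def log_density(self, z) -> np.ndarray:
        """Log-density ln p(z) at hyperboloid point(s) ``z``.

        ln N(xbar|0, sigma^2 I) - (d-1) ln(sinh r / r) with
        r = d_H(mu, z); the r -> 0 limit of the correction term is 0, so the
        density is finite and maximal at mu.
        """
        z = check_point(z)
        d = self.dim
        r = hyperbolic_distance(self.mu, z, validate=False)
        log_gauss = -0.5 * d * np.log(2.0 * np.pi * self.sigma2) - r**2 / (
            2.0 * self.sigma2
        )
        return log_gauss - (d - 1) * _log_sinhc(r)


def sample_at_origin(d: int, sigma2: float, count: int, rng) -> np.ndarray:
    """Convenience draw from G(mu_0, sigma2 I) on H^d."""
    return WrappedNormal(origin(d), sigma2).sample(count, rng)
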