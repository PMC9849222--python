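"""Primitives of the hyperboloid (Lorentz) model of hyperbolic space.

Points live on the upper sheet of the two-sheeted hyperboloid

    H^d = { x in R^{d,1} : <x,x>_L = -1,  x_{d+1} > 0 },

where R^{d,1} is R^{d+1} equipped with the Lorentzian bilinear form

    <x,y>_L = x_1 y_1 + ... + x_d y_d - x_{d+1} y_{d+1}.

The form is negative between hyperboloid points and positive definite on
tangent spaces T_p H^d = { v : <p,v>_L = 0 }, which is what makes gradients
and Gaussian noise well defined there.  The geodesic distance is
``arccosh(-<x,y>_L)``; the squared Lorentzian distance ``-2 - 2<x,y>_L`` is
its monotone surrogate used by the interaction model.

All functions accept arrays whose *last* axis is the ambient coordinate and
broadcast over leading axes.  Curvature is fixed at -1 and coordinates are
dimensionless.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GeometryError",
    "CONSTRAINT_ATOL",
    "origin",
    "lorentz_inner",
    "lorentz_norm",
    "hyperbolic_distance",
    "sq_lorentz_distance",
    "exp_map",
    "log_map",
    "parallel_transport",
    "project_to_tangent",
    "lift_to_hyperboloid",
    "reproject",
    "check_point",
    "check_tangent",
]

#: Absolute tolerance for hyperboloid-constraint and tangency assertions.
#: Chosen for double precision at latent dimensions up to a few hundred; for
#: points far from the origin the check is scaled by x_{d+1}^2 because the
#: cancellation error in <x,x>_L grows with the square of the coordinates.
CONSTRAINT_ATOL = 1e-9


class GeometryError(ValueError):
    """Input violates a hyperboloid-model precondition (shape or domain)."""


def origin(d: int) -> np.ndarray:
    """Vertex mu_0 = (0, ..., 0, 1) of the hyperboloid H^d."""
    if d < 1:
        raise GeometryError(f"latent dimension must be >= 1, got {d}")
    mu0 = np.zeros(d + 1)
    mu0[-1] = 1.0
    return mu0


def _as_ambient(x, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim < 1 or x.shape[-1] < 2:
        raise GeometryError(f"{name} must have ambient dimension >= 2, got shape {x.shape}")
    return x


def lorentz_inner(x, y) -> np.ndarray:
    """Lorentzian bilinear form <x,y>_L = sum_{k<=d} x_k y_k - x_{d+1} y_{d+1}.

    Symmetric; broadcasts over leading axes.  Raises :class:`GeometryError`
    on mismatched or sub-2 ambient dimensions.
    """
    x = _as_ambient(x, "x")
    y = _as_ambient(y, "y")
    if x.shape[-1] != y.shape[-1]:
        raise GeometryError(
            f"ambient dimensions differ: {x.shape[-1]} vs {y.shape[-1]}"
        )
    return np.sum(x[..., :-1] * y[..., :-1], axis=-1) - x[..., -1] * y[..., -1]


def lorentz_norm(v) -> np.ndarray:
    """Lorentzian norm sqrt(<v,v>_L) of a tangent vector.

    The form is positive definite on tangent spaces; tiny negative values
    from floating-point cancellation are clamped to zero.
    """
    return np.sqrt(np.maximum(lorentz_inner(v, v), 0.0))


def check_point(x, atol: float = CONSTRAINT_ATOL) -> np.ndarray:
    """Validate that ``x`` lies on the upper hyperboloid sheet.

    The constraint residual |<x,x>_L + 1| is compared against
    ``atol * (1 + x_{d+1}^2)``: the quadratic scale factor accounts for the
    catastrophic cancellation between the space-like and time-like parts for
    points far from the origin.
    """
    x = _as_ambient(x, "point")
    resid = np.abs(lorentz_inner(x, x) + 1.0)
    scale = 1.0 + x[..., -1] ** 2
    if np.any(resid > atol * scale):
        raise GeometryError(
            f"point off the hyperboloid: max |<x,x>_L + 1| = {np.max(resid):.3e}"
        )
    if np.any(x[..., -1] < 1.0 - atol):
        raise GeometryError("point on the lower sheet: x_{d+1} < 1")
    return x


def check_tangent(base, v, atol: float = CONSTRAINT_ATOL) -> np.ndarray:
    """Validate Lorentz-orthogonality <base, v>_L = 0 of a tangent vector."""
    base = _as_ambient(base, "base")
    v = _as_ambient(v, "tangent")
    resid = np.abs(lorentz_inner(base, v))
    scale = 1.0 + np.abs(base[..., -1]) * (1.0 + lorentz_norm(v))
    if np.any(resid > atol * scale):
        raise GeometryError(
            f"vector not tangent at base: max |<base,v>_L| = {np.max(resid):.3e}"
        )
    return v


def hyperbolic_distance(x, y, validate: bool = True) -> np.ndarray:
    """Geodesic distance d_H(x,y) = arccosh(-<x,y>_L) between hyperboloid points.

    The arccosh argument is clamped to >= 1 before evaluation so coincident
    points (where floating error can push -<x,y>_L infinitesimally below 1)
    return exactly 0 instead of NaN.
    """
    if validate:
        check_point(x)
        check_point(y)
    arg = np.maximum(-lorentz_inner(x, y), 1.0)
    return np.arccosh(arg)


def sq_lorentz_distance(x, y, validate: bool = True) -> np.ndarray:
    """Squared Lorentzian distance d_L^2(x,y) = -2 - 2<x,y>_L.

    Equals 2(cosh d_H(x,y) - 1); nonnegative, zero iff x = y.
    """
    if validate:
        check_point(x)
        check_point(y)
    return np.maximum(-2.0 - 2.0 * lorentz_inner(x, y), 0.0)


def reproject(x) -> np.ndarray:
    """Recompute the time-like coordinate x_{d+1} = sqrt(1 + sum x_k^2).

    Cheap exact repair of constraint drift after a numerical update; the
    first d coordinates are preserved.
    """
    x = _as_ambient(x)
    out = np.array(x, dtype=float, copy=True)
    out[..., -1] = np.sqrt(1.0 + np.sum(out[..., :-1] ** 2, axis=-1))
    return out


def lift_to_hyperboloid(z) -> np.ndarray:
    """Lift a space-like vector z in R^d to (z, sqrt(1 + |z|^2)) on H^d."""
    z = np.asarray(z, dtype=float)
    if z.ndim < 1 or z.shape[-1] < 1:
        raise GeometryError(f"need at least one spatial coordinate, got shape {z.shape}")
    last = np.sqrt(1.0 + np.sum(z**2, axis=-1, keepdims=True))
    return np.concatenate([z, last], axis=-1)


def _sinhc(t: np.ndarray) -> np.ndarray:
    """sinh(t)/t with the series limit 1 + t^2/6 for small t."""
    t = np.asarray(t, dtype=float)
    small = np.abs(t) < 1e-6
    safe = np.where(small, 1.0, t)
    return np.where(small, 1.0 + t * t / 6.0, np.sinh(safe) / safe)


def exp_map(mu, y, validate: bool = True) -> np.ndarray:
    """Exponential map Exp_mu(y) = cosh(|y|_L) mu + sinh(|y|_L) y/|y|_L.

    Shoots the tangent vector ``y`` at ``mu`` along its geodesic; the image
    lies at geodesic distance |y|_L from ``mu``.  For |y|_L below 1e-6 the
    sinh(t)/t ratio is evaluated by series, so the zero vector maps to ``mu``
    exactly.  The result is re-projected onto the hyperboloid.
    """
    mu = _as_ambient(mu, "mu")
    y = _as_ambient(y, "y")
    if validate:
        check_point(mu)
        check_tangent(mu, y, atol=1e-6)
    t = lorentz_norm(y)[..., None]
    out = np.cosh(t) * mu + _sinhc(t) * y
    return reproject(out)


def _acosh_over_sq(alpha: np.ndarray) -> np.ndarray:
    """arccosh(a)/sqrt(a^2-1) with the series limit 1 - (a-1)/3 for a -> 1."""
    alpha = np.asarray(alpha, dtype=float)
    t = alpha - 1.0
    small = t < 1e-6
    safe = np.where(small, 2.0, alpha)
    return np.where(
        small, 1.0 - t / 3.0, np.arccosh(safe) / np.sqrt(safe * safe - 1.0)
    )


def log_map(mu, x, validate: bool = True) -> np.ndarray:
    """Logarithm map Exp_mu^{-1}(x): the tangent vector at mu pointing to x.

    Computed as ``f(a) * (x - a*mu)`` with ``a = -<mu,x>_L`` and
    ``f(a) = arccosh(a)/sqrt(a^2 - 1)``; its Lorentzian norm equals
    d_H(mu, x).  At ``x = mu`` the zero tangent vector is returned (limit),
    not an error.  At mu = mu_0 this reduces to the closed form
    ``arccosh(x_{d+1})/sqrt(x_{d+1}^2 - 1) * (x_1, ..., x_d, 0)``.
    """
    mu = _as_ambient(mu, "mu")
    x = _as_ambient(x, "x")
    if validate:
        check_point(mu)
        check_point(x)
    alpha = np.maximum(-lorentz_inner(mu, x), 1.0)[..., None]
    return _acosh_over_sq(alpha) * (x - alpha * mu)


def parallel_transport(mu, x, validate: bool = True) -> np.ndarray:
    """Parallel transport of a tangent vector at mu_0 to the tangent space at mu.

    Moves ``x`` in T_{mu_0} H^d along the geodesic from the vertex mu_0 to
    ``mu``:

        g(x) = x + <mu + <mu_0,mu>_L mu_0, x>_L / (1 - <mu_0,mu>_L) * (mu_0 + mu)

    A linear isometry between the two tangent spaces.  On the upper sheet the
    denominator 1 - <mu_0,mu>_L = 1 + mu_{d+1} is >= 2, so no degeneracy can
    occur; this is asserted.
    """
    mu = _as_ambient(mu, "mu")
    x = _as_ambient(x, "x")
    mu0 = origin(mu.shape[-1] - 1)
    if validate:
        check_point(mu)
        check_tangent(mu0, x, atol=1e-6)
    ip_mu0_mu = lorentz_inner(mu0, mu)  # equals -mu_{d+1}
    denom = 1.0 - ip_mu0_mu
    if np.any(denom < 2.0 - 1e-9):
        raise GeometryError("degenerate transport: 1 - <mu_0,mu>_L < 2 off the upper sheet")
    coef = lorentz_inner(mu + ip_mu0_mu[..., None] * mu0, x) / denom
    return x + coef[..., None] * (mu0 + mu)


def project_to_tangent(u, g) -> np.ndarray:
    """Orthogonal projection g + <u,g>_L u of an ambient vector onto T_u H^d."""
    u = _as_ambient(u, "u")
    g = _as_ambient(g, "g")
    return g + lorentz_inner(u, g)[..., None] * u
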