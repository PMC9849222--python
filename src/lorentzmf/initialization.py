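"""Similarity-seeded initialization of hyperbolic embeddings.

Plain wrapped-normal initialization near the vertex is the safe default for
the Riemannian descent, but on sparse interaction matrices the descent then
has to discover the whole geometry from a handful of positive cells and
tends to settle in mediocre basins.  When a drug-drug similarity matrix is
available it already encodes pairwise latent distances, so a far better
starting point can be computed in closed form:

1. **Drugs** — convert similarities to squared-distance estimates through
   the same Gaussian-kernel form used throughout the package,
   ``d^2 = -tau * ln s``, with the bandwidth ``tau`` calibrated against the
   model prior (the median squared pairwise distance of a wrapped-normal
   sample with the prior's variance), and embed them by Lorentzian
   multidimensional scaling: the eigenvectors of the target Lorentz-Gram
   matrix ``-cosh(d)`` give the space-like coordinates, and the hyperboloid
   lift restores the time-like one.
2. **Targets** — place each target with at least one (training) interaction
   at the Lorentz centroid of its interacting drugs; place interaction-less
   targets by the weighted-profile rule over the target-similarity matrix.

The subsequent gradient refinement then mostly has to calibrate scales
rather than untangle points, which is a much better conditioned problem.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .coldstart import ColdStartError, lorentz_centroid, weighted_profile
from .lorentz_core import hyperbolic_distance, lift_to_hyperboloid, origin
from .wrapped_normal import WrappedNormal

__all__ = [
    "similarity_mds_init",
    "interaction_profile_init",
    "similarity_seeded_embedding",
]


def _prior_median_sq_distance(d: int, sigma2: float, rng, n_ref: int = 400) -> float:
    """Median squared geodesic distance between wrapped-normal prior draws."""
    pts = WrappedNormal(origin(d), sigma2).sample(n_ref, rng)
    dm = hyperbolic_distance(pts[:, None, :], pts[None, :, :], validate=False)
    off = dm[~np.eye(n_ref, dtype=bool)]
    return float(np.median(off) ** 2)


def similarity_mds_init(
    S: np.ndarray,
    d: int,
    sigma2: float,
    rng,
    floor: float = 1e-12,
) -> np.ndarray:
    """Embed rows on H^d by Lorentzian MDS of similarity-derived distances.

    Parameters
    ----------
    S
        (m, m) similarity matrix with entries in (0, 1].
    d
        Latent dimension of the embedding.
    sigma2
        Prior variance used to calibrate the distance scale ``tau``
        (typically 1/(2*alpha) of the model's prior precision).
    rng
        Generator or seed for the prior reference sample.

    Returns an (m, d+1) array of hyperboloid points.  Rank deficiencies are
    benign: missing space-like directions stay zero and the lift restores
    the constraint exactly.
    """
    rng = np.random.default_rng(rng)
    m = S.shape[0]
    tau = _prior_median_sq_distance(d, sigma2, rng)
    with np.errstate(divide="ignore"):
        D2 = -np.log(np.maximum(S, floor)) * tau
    np.fill_diagonal(D2, 0.0)
    # target Lorentz Gram matrix: <u_i, u_j>_L = -cosh d_ij
    gram = -np.cosh(np.sqrt(D2))
    w, Q = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]  # positive eigenvalues carry space-like axes
    X = np.zeros((m, d))
    k = 0
    for j in order:
        if w[j] <= 0 or k >= d:
            break
        X[:, k] = np.sqrt(w[j]) * Q[:, j]
        k += 1
    return lift_to_hyperboloid(X)


def interaction_profile_init(
    U0: np.ndarray,
    R: np.ndarray,
    T: Optional[np.ndarray] = None,
    J: int = 5,
) -> np.ndarray:
    """Place targets from drug positions: centroid of interacting drugs.

    Targets whose column of ``R`` is empty are imputed by the weighted
    profile over the target-similarity matrix ``T`` (when given); failing
    that they start at the vertex.
    """
    n = R.shape[1]
    d1 = U0.shape[1]
    V0 = np.tile(origin(d1 - 1), (n, 1))
    nonempty = R.sum(axis=0) > 0
    for j in np.flatnonzero(nonempty):
        V0[j] = lorentz_centroid(U0[R[:, j] == 1])
    if T is not None:
        for j in np.flatnonzero(~nonempty):
            try:
                V0[j] = weighted_profile(j, T, V0, J=J, active=nonempty)
            except ColdStartError:
                pass
    return V0


def similarity_seeded_embedding(
    R: np.ndarray,
    S: np.ndarray,
    T: Optional[np.ndarray],
    d: int,
    sigma2: float,
    rng,
    J: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Full similarity-seeded (U0, V0) starting point for the optimizer."""
    rng = np.random.default_rng(rng)
    U0 = similarity_mds_init(S, d, sigma2, rng)
    V0 = interaction_profile_init(U0, R, T, J=J)
    return U0, V0
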