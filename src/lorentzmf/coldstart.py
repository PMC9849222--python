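"""Cold-start imputation of latent vectors via the hyperbolic center of mass.

A drug (or target) with an empty interaction profile carries no likelihood
signal, so its latent vector is rebuilt as a weighted combination of the
embeddings of its most similar neighbors — the "weighted profile" strategy
of neighborhood-regularized MF, moved to the hyperboloid.  The combination
uses the Lorentzian-distance Frechet mean: the minimizer over H^d of

    sum_k w_k d_L^2(x, p_k)

admits the closed form  m / sqrt(-<m,m>_L)  with  m = sum_k w_k p_k
(the weighted ambient mean pushed back onto the hyperboloid).  The closed
form is scale-invariant in the weights, which also resolves whether the
1/SM profile normalization happens before or after the hyperboloid
projection: both give the same point.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .lorentz_core import GeometryError, lorentz_inner

__all__ = ["ColdStartError", "lorentz_centroid", "weighted_profile"]


class ColdStartError(ValueError):
    """No usable neighbor for a cold-start imputation."""


def lorentz_centroid(points, weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Weighted Lorentzian-distance center of mass of hyperboloid points.

    Parameters
    ----------
    points
        (k, d+1) array (or sequence) of hyperboloid points.
    weights
        k nonnegative weights, at least one positive; uniform if omitted.

    Returns the minimizer of ``sum_k w_k d_L^2(x, p_k)`` over H^d:
    ``m / sqrt(-<m,m>_L)`` with ``m`` the weighted ambient mean.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (P.shape[0],):
        raise ValueError("one weight per point is required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ColdStartError("all centroid weights are zero")
    m = w @ P
    nrm2 = -lorentz_inner(m, m)
    if nrm2 <= 0:
        raise GeometryError("degenerate centroid: weighted mean is not time-like")
    return m / np.sqrt(nrm2)


def weighted_profile(
    i: int,
    S: np.ndarray,
    U: np.ndarray,
    J: int = 5,
    active: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Impute row i of an embedding from its J most similar active rows.

    Parameters
    ----------
    i
        Index of the row with an empty interaction profile.
    S
        (m, m) similarity matrix; weights are taken from row i.
    U
        (m, d+1) embedding whose rows are hyperboloid points.
    J
        Number of nearest neighbors; if fewer are available, all are used.
    active
        Boolean mask of rows eligible as neighbors (typically: rows with at
        least one known interaction).  Row i itself is always excluded.

    Returns the Lorentz centroid of the selected neighbors weighted by their
    similarities.  Raises :class:`ColdStartError` when no neighbor has
    positive similarity; callers may fall back to the vertex mu_0.
    """
    m = S.shape[0]
    if U.shape[0] != m:
        raise ValueError("similarity and embedding row counts differ")
    if J < 1:
        raise ValueError("J must be >= 1")
    eligible = np.ones(m, dtype=bool) if active is None else np.asarray(active, bool).copy()
    eligible[i] = False
    cand = np.flatnonzero(eligible & (S[i] > 0))
    if cand.size == 0:
        raise ColdStartError(f"row {i} has no neighbor with positive similarity")
    order = cand[np.argsort(S[i, cand])[::-1]]
    chosen = order[: min(J, order.size)]
    return lorentz_centroid(U[chosen], S[i, chosen])
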