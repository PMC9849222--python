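"""Hyperbolic logistic matrix-factorization model.

Drugs and targets are embedded as points u^i, v^j on the hyperboloid H^d and
an interaction is scored by a logistic link on the squared Lorentzian
distance,

    p_ij = sigmoid( -d_L^2(u^i, v^j) ),     d_L^2(x,y) = -2 - 2 <x,y>_L.

The training objective is the negative log-posterior of a confidence-
weighted Bernoulli likelihood under wrapped-normal priors G(mu_0, sigma^2 I)
on the rows of both embeddings, optionally augmented with a neighborhood
regularizer that pulls the latent vectors of similar drugs (targets)
together in squared Lorentzian distance.  Additive constants of the
posterior are dropped, so loss values are comparable only within a run.

This module evaluates the loss and its analytic *ambient* Lorentzian
gradients; the Riemannian update itself lives in
:mod:`lorentzmf.optimizer`.  The loss is a smooth function of the ambient
coordinates (no hyperboloid projection inside), which is what both the
optimizer and the finite-difference gradient checks require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .lorentz_core import check_point, sq_lorentz_distance
from .wrapped_normal import _log_sinhc

__all__ = [
    "InteractionData",
    "ModelParams",
    "SimilarityPair",
    "Embedding",
    "NumericError",
    "confidence_weights",
    "interaction_probability",
    "pairwise_sq_dists",
    "predict_scores",
    "loss",
    "ambient_gradient_U",
    "ambient_gradient_V",
]


class NumericError(FloatingPointError):
    """Loss or gradient became non-finite."""


@dataclass
class InteractionData:
    """Binary drug-target interaction matrix with row/column identifiers.

    ``R[i, j] = 1`` when drug i is known to interact with target j, else 0
    (no interaction or unknown).
    """

    R: np.ndarray
    drug_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    target_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or min(self.R.shape) < 1:
            raise ValueError(f"R must be a non-empty 2-D matrix, got shape {self.R.shape}")
        if not np.isin(self.R, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be strictly binary 0/1")
        m, n = self.R.shape
        if self.drug_ids is None:
            self.drug_ids = [f"d{i}" for i in range(m)]
        if self.target_ids is None:
            self.target_ids = [f"t{j}" for j in range(n)]
        self.drug_ids = list(self.drug_ids)
        self.target_ids = list(self.target_ids)
        if len(self.drug_ids) != m or len(self.target_ids) != n:
            raise ValueError("identifier lists do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape


@dataclass(frozen=True)
class ModelParams:
    """Hyperparameters of the hyperbolic logistic MF model.

    Parameters
    ----------
    d
        Latent (intrinsic) dimension; embeddings are (d+1)-vectors.
    c
        Confidence weight on observed interactions (w_ij = c for r_ij = 1,
        1 otherwise); must be >= 1.
    alpha_U, alpha_V
        Prior precisions 1/(2 sigma_U^2), 1/(2 sigma_V^2) of the wrapped-
        normal priors; nonnegative.
    beta_U, beta_V
        Neighborhood-regularization weights; nonnegative.
    """

    d: int
    c: float = 5.0
    alpha_U: float = 0.1
    alpha_V: float = 0.1
    beta_U: float = 0.0
    beta_V: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.c < 1:
            raise ValueError(f"c must be >= 1, got {self.c}")
        for name in ("alpha_U", "alpha_V", "beta_U", "beta_V"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimilarityPair:
    """Drug-drug (m x m) and target-target (n x n) similarity matrices.

    Entries in [0,1], symmetric within 1e-9.  The diagonal is irrelevant for
    regularization (d_L^2(u,u) = 0) and is kept as given.
    """

    S: Optional[np.ndarray] = None
    T: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("S", "T"):
            mat = getattr(self, name)
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"{name} must be square, got shape {mat.shape}")
            if not np.allclose(mat, mat.T, atol=1e-9):
                raise ValueError(f"{name} is not symmetric within 1e-9")
            setattr(self, name, mat)

    def sparsify(self, k: int) -> "SimilarityPair":
        """Keep, per row, only the k largest off-diagonal entries.

        An entry survives if it is among the top-k of its row *or* of its
        column, which preserves symmetry.  Mirrors common neighborhood-
        regularized MF practice; dense use is the default.
        """

        def knn(mat: Optional[np.ndarray]) -> Optional[np.ndarray]:
            if mat is None:
                return None
            n = mat.shape[0]
            off = mat - np.diag(np.diag(mat))
            keep = np.zeros_like(off, dtype=bool)
            for i in range(n):
                idx = np.argsort(off[i])[::-1][: min(k, n - 1)]
                keep[i, idx] = True
            keep |= keep.T
            out = np.where(keep, off, 0.0)
            return out + np.diag(np.diag(mat))

        return SimilarityPair(knn(self.S), knn(self.T))


@dataclass
class Embedding:
    """Latent matrices U (m x (d+1)) and V (n x (d+1)); rows are hyperboloid points."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must be 2-D with equal ambient dimension")

    @property
    def d(self) -> int:
        return self.U.shape[1] - 1

    def validate(self) -> "Embedding":
        """Assert every row satisfies the hyperboloid constraint."""
        check_point(self.U)
        check_point(self.V)
        return self


def confidence_weights(data: InteractionData, c: float) -> np.ndarray:
    """Confidence matrix W: w_ij = c where r_ij = 1, else 1 (c >= 1)."""
    if c < 1:
        raise ValueError(f"confidence weight c must be >= 1, got {c}")
    return np.where(data.R == 1.0, float(c), 1.0)


def interaction_probability(u, v) -> np.ndarray:
    """Link probability p = sigmoid(-d_L^2(u, v)) for hyperboloid points.

    Strictly decreasing in the squared Lorentzian distance; evaluated via a
    numerically stable sigmoid, so very distant pairs underflow gracefully
    to 0 instead of overflowing.
    """
    return expit(-sq_lorentz_distance(u, v))


def pairwise_sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs squared Lorentzian distances -2 - 2 <x_i, y_j>_L.

    One matrix product with the metric signature folded into the last
    column; entries are clamped at 0 (exact zeros can round negative).
    """
    G = X[:, :-1] @ Y[:, :-1].T - np.outer(X[:, -1], Y[:, -1])
    return np.maximum(-2.0 - 2.0 * G, 0.0)


def predict_scores(emb: Embedding) -> np.ndarray:
    """Interaction-probability matrix: entry (i,j) = sigmoid(-d_L^2(u^i, v^j))."""
    return expit(-pairwise_sq_dists(emb.U, emb.V))


def _raw_sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # unclamped version: the loss must stay smooth in the ambient coordinates
    G = X[:, :-1] @ Y[:, :-1].T - np.outer(X[:, -1], Y[:, -1])
    return -2.0 - 2.0 * G


def _prior_terms(last: np.ndarray, alpha: float, d: int) -> float:
    """Per-row prior penalty alpha*arccosh^2(x_{d+1}) + (d-1) ln(sinh r / r)."""
    r = np.arccosh(np.maximum(last, 1.0))
    return float(np.sum(alpha * r**2 + (d - 1) * _log_sinhc(r)))


def loss(
    emb: Embedding,
    data: InteractionData,
    params: ModelParams,
    sim: Optional[SimilarityPair] = None,
) -> float:
    """Negative log-posterior (constants dropped) of the hyperbolic model.

    Sum of: the confidence-weighted logistic likelihood
    ``w_ij [ln(1 + e^{-d_L^2}) + r_ij d_L^2]``; per-row wrapped-normal prior
    penalties for U and V; and, when similarities are given, the
    neighborhood terms ``beta_U sum s_ij d_L^2(u^i,u^j)`` (same for V).

    Smooth in the ambient coordinates; raises :class:`NumericError` when the
    value is non-finite.
    """
    m, n = data.shape
    if emb.U.shape[0] != m or emb.V.shape[0] != n:
        raise ValueError("embedding and interaction-matrix shapes disagree")
    W = confidence_weights(data, params.c)
    D2 = _raw_sq_dists(emb.U, emb.V)
    value = float(np.sum(W * (np.logaddexp(0.0, -D2) + data.R * D2)))
    value += _prior_terms(emb.U[:, -1], params.alpha_U, params.d)
    value += _prior_terms(emb.V[:, -1], params.alpha_V, params.d)
    if sim is not None and sim.S is not None and params.beta_U > 0:
        value += params.beta_U * float(np.sum(sim.S * _raw_sq_dists(emb.U, emb.U)))
    if sim is not None and sim.T is not None and params.beta_V > 0:
        value += params.beta_V * float(np.sum(sim.T * _raw_sq_dists(emb.V, emb.V)))
    if not np.isfinite(value):
        raise NumericError(f"loss is non-finite: {value}")
    return value


def _dprior_dlast(last: np.ndarray, alpha: float, d: int) -> np.ndarray:
    """Derivative of the per-row prior penalty w.r.t. the time-like coordinate.

    2 alpha arccosh(x)/sqrt(x^2-1) + (d-1)(x arccosh(x) - sqrt(x^2-1)) /
    ((x^2-1) arccosh(x)).  With r = arccosh(x) the two factors are
    r/sinh(r) and (coth r - 1/r)/sinh r; both are evaluated by second-order
    series near x = 1 where the closed forms are 0/0.
    """
    r = np.arccosh(np.maximum(last, 1.0))
    small = r < 1e-4
    safe = np.where(small, 1.0, r)
    # arccosh(x)/sqrt(x^2 - 1) = r / sinh(r); series 1 - r^2/6 near 0
    r_over_sinh = np.where(small, 1.0 - r**2 / 6.0, safe / np.sinh(safe))
    # d/dx [ln(sinh r / r)] = (coth r - 1/r)/sinh r; series 1/3 - 7 r^2/90
    corr = np.where(
        small,
        1.0 / 3.0 - 7.0 * r**2 / 90.0,
        (1.0 / np.tanh(safe) - 1.0 / safe) / np.sinh(safe),
    )
    return 2.0 * alpha * r_over_sinh + (d - 1) * corr


def _likelihood_residual(
    emb: Embedding, data: InteractionData, params: ModelParams
) -> np.ndarray:
    W = confidence_weights(data, params.c)
    P = expit(-_raw_sq_dists(emb.U, emb.V))
    return W * (P - data.R)


def _gradient(
    X: np.ndarray,
    Y: np.ndarray,
    E: np.ndarray,
    alpha: float,
    beta: float,
    S: Optional[np.ndarray],
    d: int,
    flip_last: bool,
) -> np.ndarray:
    """Ambient gradient of the loss w.r.t. the rows of X.

    ``E`` is the (rows-of-X x rows-of-Y) weighted residual W*(P - R) seen
    from X's side.  Likelihood partials: 2 E Y_k for the space-like
    coordinates and -2 E Y_{d+1} for the time-like one.  The neighborhood
    term differentiates through d_L^2(x^i, x^j) with the symmetrized
    coefficients s~_ij = s_ij + s_ji because x^i occupies both sum slots.
    """
    grad = np.empty_like(X)
    grad[:, :-1] = 2.0 * E @ Y[:, :-1]
    grad[:, -1] = -2.0 * E @ Y[:, -1]
    grad[:, -1] += _dprior_dlast(X[:, -1], alpha, d)
    if S is not None and beta > 0:
        st = S + S.T
        grad[:, :-1] += -2.0 * beta * (st @ X[:, :-1])
        grad[:, -1] += 2.0 * beta * (st @ X[:, -1])
    if not np.all(np.isfinite(grad)):
        bad = int(np.where(~np.isfinite(grad).all(axis=1))[0][0])
        raise NumericError(f"non-finite gradient at row {bad}")
    if flip_last:
        grad = grad.copy()
        grad[:, -1] = -grad[:, -1]
    return grad


def ambient_gradient_U(
    emb: Embedding,
    data: InteractionData,
    params: ModelParams,
    sim: Optional[SimilarityPair] = None,
    flip_last: bool = True,
) -> np.ndarray:
    """Ambient Lorentzian gradient of the loss w.r.t. every drug row u^i.

    Row i stacks the analytic partial derivatives of the loss; with
    ``flip_last`` (the default) the time-like component is negated, which
    turns the vector of partials into the Lorentzian ambient gradient the
    Riemannian update consumes.  Set ``flip_last=False`` to obtain the raw
    partial derivatives (e.g. for finite-difference checks).
    """
    E = _likelihood_residual(emb, data, params)
    S = sim.S if sim is not None else None
    return _gradient(emb.U, emb.V, E, params.alpha_U, params.beta_U, S, params.d, flip_last)


def ambient_gradient_V(
    emb: Embedding,
    data: InteractionData,
    params: ModelParams,
    sim: Optional[SimilarityPair] = None,
    flip_last: bool = True,
) -> np.ndarray:
    """Ambient Lorentzian gradient w.r.t. every target row v^j (see
    :func:`ambient_gradient_U`)."""
    E = _likelihood_residual(emb, data, params)
    T = sim.T if sim is not None else None
    return _gradient(emb.V, emb.U, E.T, params.alpha_V, params.beta_V, T, params.d, flip_last)
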