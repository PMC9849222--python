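"""Alternating Riemannian gradient descent on a product of hyperboloids.

Each update of a latent row follows the standard hyperbolic gradient-descent
recipe: compute the ambient Lorentzian gradient (time-like component
negated), project it orthogonally onto the tangent space at the current
point, and move with the exponential map,

    u_new = Exp_u( -eta * grad_tangent ).

The full fit alternates a sweep over all drug rows (targets fixed) with a
sweep over all target rows (drugs fixed), full batch.  Two cheap heuristics
keep the descent away from the well-known instability of hyperbolic
optimization near "cliffs": the tangent gradient of each row is clipped to a
maximum Lorentzian norm, and the learning rate is annealed over a small
number of phases (default three, multiplying eta by ``lr_decay`` between
phases).  Initialization draws both embeddings from a tight wrapped normal
at the vertex, so the optimization starts in the flat, well-conditioned
neighborhood of the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .hmf_model import (
    Embedding,
    InteractionData,
    ModelParams,
    NumericError,
    SimilarityPair,
    ambient_gradient_U,
    ambient_gradient_V,
    loss,
)
from .lorentz_core import exp_map, lorentz_norm, origin, project_to_tangent, reproject
from .wrapped_normal import WrappedNormal

__all__ = ["OptimizerConfig", "FitResult", "riemannian_step", "fit"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings of the Riemannian descent.

    Parameters
    ----------
    eta
        Initial step size (> 0).
    epochs_per_phase
        Full U-sweep + V-sweep passes per annealing phase.
    phases
        Number of annealing phases; eta is multiplied by ``lr_decay``
        between consecutive phases.
    lr_decay
        Learning-rate decay factor per phase, in (0, 1).
    clip_norm
        Maximum Lorentzian norm of a per-row tangent gradient; rows
        exceeding it are rescaled.  ``math.inf`` disables clipping.
    seed
        Seed of the wrapped-normal initialization.
    init_sigma2
        Variance of the wrapped-normal initialization at the vertex; small
        values start the descent near the origin where the geometry is
        numerically benign.
    conv_tol
        Relative loss change across the final phase below which the fit is
        flagged as converged.
    """

    eta: float = 0.05
    epochs_per_phase: int = 40
    phases: int = 3
    lr_decay: float = 0.1
    clip_norm: float = 1.0
    seed: int = 0
    init_sigma2: float = 0.01
    conv_tol: float = 1e-6
    verbose: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0.0 < self.lr_decay < 1.0):
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.epochs_per_phase < 0 or self.phases < 1:
            raise ValueError("epochs_per_phase must be >= 0 and phases >= 1")


@dataclass
class FitResult:
    """Outcome of a fit: final embedding, per-epoch loss trace, convergence flag."""

    embedding: Embedding
    loss_trace: list = field(default_factory=list)
    converged: bool = False


def riemannian_step(
    u: np.ndarray,
    ambient_grad: np.ndarray,
    eta: float,
    clip_norm: float = math.inf,
) -> np.ndarray:
    """One hyperbolic gradient-descent step for one or many rows.

    ``ambient_grad`` is the Lorentzian ambient gradient (time-like component
    already negated).  It is projected to the tangent space at ``u``,
    optionally clipped to ``clip_norm`` in Lorentzian norm, and applied via
    ``Exp_u(-eta * g)``; the result is re-projected onto the hyperboloid.
    """
    if not np.all(np.isfinite(ambient_grad)):
        flat = np.atleast_2d(ambient_grad)
        bad = int(np.where(~np.isfinite(flat).all(axis=1))[0][0])
        raise NumericError(f"non-finite ambient gradient at row {bad}")
    g = project_to_tangent(u, ambient_grad)
    if np.isfinite(clip_norm):
        norms = lorentz_norm(g)
        scale = np.where(norms > clip_norm, clip_norm / np.maximum(norms, 1e-300), 1.0)
        g = g * np.asarray(scale)[..., None]
    return exp_map(u, -eta * g, validate=False)


def fit(
    data: InteractionData,
    params: ModelParams,
    sim: Optional[SimilarityPair] = None,
    config: OptimizerConfig = OptimizerConfig(),
    init: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> FitResult:
    """Fit the hyperbolic logistic MF model by alternating Riemannian descent.

    Initializes U and V from the wrapped normal G(mu_0, init_sigma2 I) —
    or from an explicit ``init=(U0, V0)`` pair of hyperboloid point
    matrices, e.g. the similarity-seeded start of
    :mod:`lorentzmf.initialization`.  Each epoch updates every drug row
    with the targets fixed, then every target row with the (updated) drugs
    fixed, and records the loss.  Deterministic given ``config.seed``.
    Raises :class:`~lorentzmf.hmf_model.NumericError` naming the epoch if
    the loss diverges.
    """
    m, n = data.shape
    if init is not None:
        U = np.array(init[0], dtype=float, copy=True)
        V = np.array(init[1], dtype=float, copy=True)
        if U.shape != (m, params.d + 1) or V.shape != (n, params.d + 1):
            raise ValueError("init matrices do not match (m, d+1)/(n, d+1)")
    else:
        rng = np.random.default_rng(config.seed)
        prior = WrappedNormal(origin(params.d), config.init_sigma2)
        U = prior.sample(m, rng)
        V = prior.sample(n, rng)
    emb = Embedding(U, V)

    trace: list[float] = []
    eta = config.eta
    epoch = 0
    for phase in range(config.phases):
        for _ in range(config.epochs_per_phase):
            gU = ambient_gradient_U(emb, data, params, sim)
            emb.U = reproject(riemannian_step(emb.U, gU, eta, config.clip_norm))
            gV = ambient_gradient_V(emb, data, params, sim)
            emb.V = reproject(riemannian_step(emb.V, gV, eta, config.clip_norm))
            try:
                value = loss(emb, data, params, sim)
            except NumericError as err:
                raise NumericError(f"divergence at epoch {epoch}: {err}") from err
            trace.append(value)
            if config.verbose:
                print(f"epoch {epoch:4d}  phase {phase}  eta {eta:.2e}  loss {value:.6f}")
            epoch += 1
        eta *= config.lr_decay

    converged = False
    if len(trace) >= 2:
        span = max(1, config.epochs_per_phase)
        first, last_ = trace[-span], trace[-1]
        converged = abs(first - last_) <= config.conv_tol * max(1.0, abs(last_))
    return FitResult(embedding=emb, loss_trace=trace, converged=converged)
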