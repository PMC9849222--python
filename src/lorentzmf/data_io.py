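"""Labeled-matrix file I/O and synthetic interaction-data generators.

On-disk dialect: tab-delimited text in the layout of the Yamanishi
gold-standard drug-target sets (first row = target identifiers, first
column = drug identifiers, cells 0/1 for interactions or reals in [0,1] for
similarities).  Some distributions of those sets ship transposed
(targets x drugs); ``read_interaction_matrix(..., transpose=True)`` covers
that.

The synthetic generators make the whole package testable without any
download.  ``generate_synthetic`` plants embeddings drawn from the wrapped
normal at the vertex and samples interactions from the model's own logistic
link, so fitting it is a well-posed recovery problem.
``generate_tree_synthetic`` instead embeds a regular tree in H^2 with equal
edge lengths (leaves = drugs, internal nodes = targets), the canonical
hierarchy that hyperbolic space represents with low distortion and flat
space does not.  Similarity matrices are derived from latent geodesic
distances through a Gaussian kernel with a median-heuristic bandwidth — a
generator choice, not part of the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .hmf_model import InteractionData, SimilarityPair, pairwise_sq_dists
from .lorentz_core import exp_map, hyperbolic_distance, log_map, lorentz_inner, origin
from .wrapped_normal import WrappedNormal

__all__ = [
    "FormatError",
    "SyntheticTruth",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_similarity_matrix",
    "write_labeled_matrix",
    "generate_synthetic",
    "generate_euclidean_synthetic",
    "generate_tree_synthetic",
]


class FormatError(ValueError):
    """Malformed labeled-matrix file."""


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as err:
        raise FormatError(f"{path}: ragged or unparseable table ({err})") from err
    if df.isna().any().any():
        raise FormatError(f"{path}: missing or ragged cells")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate row or column labels")
    return df


def read_interaction_matrix(path, transpose: bool = False) -> InteractionData:
    """Read a binary drug-target matrix (drugs x targets, tab-delimited).

    Cells must parse strictly as 0 or 1; the first offending cell is named
    in the error.  ``transpose=True`` reads targets-x-drugs distributions.
    """
    df = _read_table(path)
    if transpose:
        df = df.T
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as err:
        raise FormatError(f"{path}: non-numeric cell ({err})") from err
    bad = ~np.isin(values, (0.0, 1.0))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: non-binary cell {values[i, j]!r} at drug "
            f"{df.index[i]!r}, target {df.columns[j]!r}"
        )
    return InteractionData(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_interaction_matrix(data: InteractionData, path) -> None:
    """Write an interaction matrix in the tab-delimited labeled layout."""
    df = pd.DataFrame(data.R.astype(int), index=data.drug_ids, columns=data.target_ids)
    df.to_csv(path, sep="\t")


def write_labeled_matrix(values: np.ndarray, row_ids, col_ids, path) -> None:
    """Write a real labeled matrix; full double precision for exact round-trips."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labeled_matrix(path) -> tuple[np.ndarray, list, list]:
    """Read any real labeled matrix; returns (values, row_ids, col_ids)."""
    df = _read_table(path)
    try:
        values = df.to_numpy().astype(float)
    except (TypeError, ValueError) as err:
        raise FormatError(f"{path}: non-numeric cell ({err})") from err
    return values, list(df.index.astype(str)), list(df.columns.astype(str))


def read_similarity_matrix(path) -> tuple[np.ndarray, list]:
    """Read a square similarity matrix; symmetrize and clip tiny violations.

    Asymmetry within 1e-6 is repaired by averaging, beyond it is an error.
    Entries straying outside [0,1] by at most 1e-6 are clipped with a
    warning; larger excursions are errors.
    """
    values, rows, cols = read_labeled_matrix(path)
    if values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: similarity matrix must be square, got {values.shape}")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > 1e-6:
        raise FormatError(f"{path}: asymmetric similarity matrix (max |S - S'| = {asym:.3e})")
    if asym > 0:
        values = 0.5 * (values + values.T)
    excess = max(float(np.max(values, initial=0.0) - 1.0), float(-np.min(values, initial=0.0)))
    if excess > 1e-6:
        raise FormatError(f"{path}: similarity entries outside [0,1] by {excess:.3e}")
    if excess > 0:
        warnings.warn(f"{path}: clipping similarity entries to [0,1] (excess {excess:.3e})")
        values = np.clip(values, 0.0, 1.0)
    return values, rows


@dataclass
class SyntheticTruth:
    """A planted-model dataset: ground-truth embeddings plus sampled data."""

    U_true: np.ndarray
    V_true: np.ndarray
    data: InteractionData
    sim: SimilarityPair
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _gaussian_similarity(sqdist: np.ndarray) -> np.ndarray:
    """exp(-D2/tau) with tau = median off-diagonal squared distance."""
    n = sqdist.shape[0]
    off = sqdist[~np.eye(n, dtype=bool)]
    tau = float(np.median(off)) if off.size and np.median(off) > 0 else 1.0
    return np.exp(-sqdist / tau)


def generate_synthetic(
    m: int, n: int, d_true: int, sigma2: float, seed: int
) -> SyntheticTruth:
    """Plant wrapped-normal embeddings and sample interactions from the model.

    U_true (m rows) and V_true (n rows) are drawn from G(mu_0, sigma2 I) on
    H^{d_true}; each r_ij is Bernoulli with the model's own link probability
    sigmoid(-d_L^2(u^i, v^j)); similarities are Gaussian kernels of the
    planted geodesic distances.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    prior = WrappedNormal(origin(d_true), sigma2)
    U = prior.sample(m, rng)
    V = prior.sample(n, rng)
    P = expit(-pairwise_sq_dists(U, V))
    R = rng.binomial(1, P).astype(float)
    dU = np.arccosh(np.maximum(-_gram(U, U), 1.0))
    dV = np.arccosh(np.maximum(-_gram(V, V), 1.0))
    sim = SimilarityPair(_gaussian_similarity(dU**2), _gaussian_similarity(dV**2))
    data = InteractionData(R)
    return SyntheticTruth(
        U, V, data, sim,
        params={"m": m, "n": n, "d_true": d_true, "sigma2": sigma2, "seed": seed},
        meta={"model": "hyperbolic", "P": P},
    )


def _gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return X[:, :-1] @ Y[:, :-1].T - np.outer(X[:, -1], Y[:, -1])


def generate_euclidean_synthetic(
    m: int, n: int, d_true: int, sigma2: float, seed: int
) -> SyntheticTruth:
    """Plant a Euclidean logistic low-rank model (for baseline recovery tests).

    U, V ~ N(0, sigma2 I) in R^{d_true}; r_ij ~ Bernoulli(sigmoid(u . v));
    similarities are Gaussian kernels of Euclidean distances.
    """
    rng = np.random.default_rng(seed)
    U = rng.normal(0.0, np.sqrt(sigma2), size=(m, d_true))
    V = rng.normal(0.0, np.sqrt(sigma2), size=(n, d_true))
    P = expit(U @ V.T)
    R = rng.binomial(1, P).astype(float)

    def sqd(X):
        g = X @ X.T
        sq = np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g
        return np.maximum(sq, 0.0)

    sim = SimilarityPair(_gaussian_similarity(sqd(U)), _gaussian_similarity(sqd(V)))
    data = InteractionData(R)
    return SyntheticTruth(
        U, V, data, sim,
        params={"m": m, "n": n, "d_true": d_true, "sigma2": sigma2, "seed": seed},
        meta={"model": "euclidean", "P": P},
    )


# --- regular tree embedded in H^2 ------------------------------------------


def _tangent_frame(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lorentz-orthonormal basis of the tangent plane at p in H^2."""
    basis = []
    for e in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        v = e + lorentz_inner(p, e) * p  # project to tangent
        for b in basis:
            v = v - lorentz_inner(b, v) * b
        nrm = np.sqrt(max(lorentz_inner(v, v), 0.0))
        basis.append(v / nrm)
    return basis[0], basis[1]


def _tree_layout(branching: int, depth: int, edge_length: float):
    """Place a regular tree in H^2, root at the vertex, equal edge lengths.

    Children of the root are spread uniformly over the circle of directions;
    at every other node the b children fan out over the directions that
    avoid the incoming (parent) edge — the classic construction that embeds
    trees in the hyperbolic plane with low metric distortion.

    Returns (positions, parents, depths): arrays over nodes in BFS order.
    """
    mu0 = origin(2)
    positions = [mu0]
    parents = [-1]
    depths = [0]
    frontier = [0]
    for level in range(depth):
        next_frontier = []
        for node in frontier:
            p = positions[node]
            b1, b2 = _tangent_frame(p)
            if parents[node] < 0:
                angles = [2.0 * np.pi * k / branching for k in range(branching)]
            else:
                v_in = log_map(p, positions[parents[node]], validate=False)
                phi_in = np.arctan2(lorentz_inner(v_in, b2), lorentz_inner(v_in, b1))
                angles = [
                    phi_in + 2.0 * np.pi * (k + 1) / (branching + 1)
                    for k in range(branching)
                ]
            for theta in angles:
                direction = np.cos(theta) * b1 + np.sin(theta) * b2
                child = exp_map(p, edge_length * direction, validate=False)
                next_frontier.append(len(positions))
                positions.append(child)
                parents.append(node)
                depths.append(level + 1)
        frontier = next_frontier
    return np.array(positions), np.array(parents), np.array(depths)


def _tree_graph_distances(parents: np.ndarray) -> np.ndarray:
    """All-pairs path lengths (in edges) of the tree defined by ``parents``."""
    n = len(parents)
    ancestors = []
    for i in range(n):
        chain = {}
        j, k = i, 0
        while j >= 0:
            chain[j] = k
            j, k = parents[j], k + 1
        ancestors.append(chain)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = min(
                ancestors[i][a] + ancestors[j][a]
                for a in ancestors[i]
                if a in ancestors[j]
            )
            D[i, j] = D[j, i] = common
    return D


def generate_tree_synthetic(
    branching: int,
    depth: int,
    n_targets: int,
    seed: int,
    edge_length: float = 1.0,
) -> SyntheticTruth:
    """Hierarchy-structured synthetic data from a regular tree in H^2.

    Drugs sit at the b^depth leaves of a regular ``branching``-ary tree of
    the given ``depth`` embedded in the hyperbolic plane with equal edge
    lengths; targets sit at internal-node positions (cycled, with a small
    wrapped-normal jitter when a position is reused so targets stay
    distinct).  Interactions are Bernoulli draws from the logistic link on
    the squared Lorentzian distance.  ``meta['tree_dist']`` carries the
    graph metric (in edge units) between leaves for distortion checks.
    """
    if branching < 2 or depth < 1:
        raise ValueError("need branching >= 2 and depth >= 1")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    positions, parents, depths = _tree_layout(branching, depth, edge_length)
    leaves = np.flatnonzero(depths == depth)
    internal = np.flatnonzero(depths < depth)
    U = positions[leaves]

    V = np.empty((n_targets, 3))
    for t in range(n_targets):
        base = positions[internal[t % internal.size]]
        if t < internal.size:
            V[t] = base
        else:  # reused position: jitter to keep targets distinct
            V[t] = WrappedNormal(base, 0.05).sample(1, rng)[0]

    P = expit(-pairwise_sq_dists(U, V))
    R = rng.binomial(1, P).astype(float)
    dU = np.arccosh(np.maximum(-_gram(U, U), 1.0))
    dV = np.arccosh(np.maximum(-_gram(V, V), 1.0))
    sim = SimilarityPair(_gaussian_similarity(dU**2), _gaussian_similarity(dV**2))
    tree_dist = _tree_graph_distances(parents) * edge_length
    return SyntheticTruth(
        U, positions[internal], InteractionData(R), sim,
        params={
            "branching": branching, "depth": depth, "n_targets": n_targets,
            "seed": seed, "edge_length": edge_length,
        },
        meta={
            "model": "tree", "P": P, "V_used": V,
            "tree_dist": tree_dist[np.ix_(leaves, leaves)],
            "leaf_embedded_dist": hyperbolic_distance(
                U[:, None, :], U[None, :, :], validate=False
            ),
        },
    )
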