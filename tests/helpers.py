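"""Independent oracles used by the test suite.

Everything here is deliberately naive — explicit loops, discretization,
numerical minimization — and never calls the code paths it is used to
check.
"""

import numpy as np

from lorentzmf.lorentz_core import lift_to_hyperboloid, lorentz_inner


def discretized_geodesic_length(x, y, segments=10_000):
    """Geodesic length by chord summation along the plane section.

    The geodesic through two hyperboloid points is the intersection of the
    hyperboloid with the plane spanned by them; points along it are the
    hyperboloid normalizations of convex combinations.  Summing the ambient
    Lorentzian chord lengths of a fine polyline converges to the Riemannian
    length, independently of any arccosh formula.
    """
    ts = np.linspace(0.0, 1.0, segments + 1)
    mix = (1 - ts)[:, None] * x[None, :] + ts[:, None] * y[None, :]
    norms = np.sqrt(-lorentz_inner(mix, mix))
    curve = mix / norms[:, None]
    diffs = np.diff(curve, axis=0)
    seg = np.sqrt(np.maximum(lorentz_inner(diffs, diffs), 0.0))
    return float(seg.sum())


def brute_force_auc(labels, scores):
    """Exhaustive positive-negative pair counting, ties counted 1/2."""
    labels = np.asarray(labels, float).ravel()
    scores = np.asarray(scores, float).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_order(scores, seed):
    """Rank order by descending score, ties resolved by a seeded permutation.

    Implemented by explicit selection sort on (score, tiebreak) pairs so it
    shares no code with the library's lexsort-based ordering.
    """
    scores = list(np.asarray(scores, float).ravel())
    tiebreak = list(np.random.default_rng(seed).permutation(len(scores)))
    remaining = list(range(len(scores)))
    order = []
    while remaining:
        best = remaining[0]
        for i in remaining[1:]:
            if scores[i] > scores[best] or (
                scores[i] == scores[best] and tiebreak[i] < tiebreak[best]
            ):
                best = i
        order.append(best)
        remaining.remove(best)
    return order


def brute_force_average_precision(labels, scores, seed=0):
    labels = np.asarray(labels, float).ravel()
    order = brute_force_order(scores, seed)
    hits = 0
    precisions = []
    for rank, idx in enumerate(order, start=1):
        if labels[idx] == 1:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def brute_force_aupr(labels, scores, seed=0):
    """Step-wise PR area from first principles: sum of P * delta-recall."""
    labels = np.asarray(labels, float).ravel()
    order = brute_force_order(scores, seed)
    npos = labels.sum()
    hits = 0
    area = 0.0
    prev_recall = 0.0
    for rank, idx in enumerate(order, start=1):
        if labels[idx] == 1:
            hits += 1
        recall = hits / npos
        precision = hits / rank
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def brute_force_prec_at_k(labels, scores, k=10, seed=0):
    labels = np.asarray(labels, float).ravel()
    order = brute_force_order(scores, seed)
    return float(np.mean([labels[i] for i in order[:k]]))


def numeric_lorentz_frechet_mean(points, weights, d):
    """Minimize sum w_k d_L^2(x, p_k) over the hyperboloid numerically.

    Parametrized by the first d coordinates (the lift removes the
    constraint), solved with Nelder-Mead restarts; independent of the
    closed-form centroid.
    """
    from scipy.optimize import minimize

    points = np.asarray(points, float)
    weights = np.asarray(weights, float)

    def objective(z):
        x = lift_to_hyperboloid(z)
        d2 = -2.0 - 2.0 * lorentz_inner(points, x[None, :])
        return float(np.sum(weights * d2))

    best = None
    for start in [np.zeros(d)] + [p[:d] for p in points]:
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000})
        if best is None or res.fun < best.fun:
            best = res
    return lift_to_hyperboloid(best.x)
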