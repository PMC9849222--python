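"""Model components: link, weights, loss, and the analytic-gradient oracle."""

import numpy as np
import pytest

from conftest import random_points
from lorentzmf.hmf_model import (
    Embedding,
    InteractionData,
    ModelParams,
    SimilarityPair,
    ambient_gradient_U,
    ambient_gradient_V,
    confidence_weights,
    interaction_probability,
    loss,
    predict_scores,
)
from lorentzmf.lorentz_core import origin
from lorentzmf.wrapped_normal import WrappedNormal


def random_instance(rng, m, n, d, c=1.0, alpha=0.0, beta=0.0, with_sim=False):
    data = InteractionData((rng.random((m, n)) < 0.4).astype(float))
    emb = Embedding(random_points(rng, m, d, 0.7), random_points(rng, n, d, 0.7))
    params = ModelParams(d=d, c=c, alpha_U=alpha, alpha_V=alpha, beta_U=beta, beta_V=beta)
    sim = None
    if with_sim:
        S = rng.random((m, m))
        T = rng.random((n, n))
        sim = SimilarityPair((S + S.T) / 2, (T + T.T) / 2)
    return emb, data, params, sim


class TestConfidenceWeights:
    def test_values_and_degenerate_c(self):
        data = InteractionData(np.array([[1.0, 0.0]]))
        assert np.array_equal(confidence_weights(data, 5.0), [[5.0, 1.0]])
        assert np.array_equal(confidence_weights(data, 1.0), [[1.0, 1.0]])

    def test_c_below_one_rejected(self):
        with pytest.raises(ValueError):
            confidence_weights(InteractionData(np.eye(2)), 0.5)


class TestInteractionProbability:
    def test_coincident_points_score_half(self):
        mu0 = origin(2)
        assert interaction_probability(mu0, mu0) == pytest.approx(0.5)

    def test_known_squared_distance(self):
        # d_L^2 = ln 3  =>  p = (1/3)/(1 + 1/3) = 1/4
        t = np.arccosh(1 + np.log(3) / 2)
        v = np.array([np.sinh(t), 0, np.cosh(t)])
        assert interaction_probability(origin(2), v) == pytest.approx(0.25, abs=1e-12)

    def test_distant_pair_underflows_without_overflow(self):
        t = np.arccosh(1 + 25.0)  # d_L^2 = 50
        v = np.array([np.sinh(t), 0, np.cosh(t)])
        with np.errstate(over="raise"):
            p = interaction_probability(origin(2), v)
        assert 0 < p < 1e-20


class TestPredictScores:
    def test_matches_pairwise_loop(self, rng):
        emb = Embedding(random_points(rng, 5, 3), random_points(rng, 4, 3))
        S = predict_scores(emb)
        for i in range(5):
            for j in range(4):
                assert S[i, j] == pytest.approx(
                    interaction_probability(emb.U[i], emb.V[j]), abs=1e-12
                )
        assert np.all((S > 0) & (S < 1))

    def test_invariant_under_joint_rotation(self, rng):
        emb = Embedding(random_points(rng, 6, 3), random_points(rng, 5, 3))
        theta = 0.7
        rot = np.eye(4)
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        rotated = Embedding(emb.U @ rot.T, emb.V @ rot.T)
        assert np.allclose(predict_scores(emb), predict_scores(rotated), atol=1e-12)


class TestLoss:
    @pytest.mark.parametrize("r", [0.0, 1.0])
    def test_single_coincident_pair(self, r):
        # d_L^2 = 0: likelihood term is ln 2 regardless of the label
        emb = Embedding(origin(2)[None, :], origin(2)[None, :])
        data = InteractionData(np.array([[r]]))
        params = ModelParams(d=2, c=1.0, alpha_U=0.0, alpha_V=0.0)
        assert loss(emb, data, params) == pytest.approx(np.log(2), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        emb, data, params, _ = random_instance(rng, 6, 5, 3)
        perm = rng.permutation(6)
        permuted = Embedding(emb.U[perm], emb.V.copy())
        pdata = InteractionData(data.R[perm])
        assert loss(permuted, pdata, params) == pytest.approx(
            loss(emb, data, params), abs=1e-10
        )

    def test_matches_posterior_via_wrapped_normal_density(self, rng):
        # the practical loss must equal the negative log-posterior assembled
        # from the wrapped-normal log-density, up to an embedding-independent
        # constant: compare loss *differences* across random embeddings
        m, n, d, alpha = 6, 5, 3, 0.4
        data = InteractionData((rng.random((m, n)) < 0.4).astype(float))
        params = ModelParams(d=d, c=2.0, alpha_U=alpha, alpha_V=alpha)
        prior = WrappedNormal(origin(d), 1.0 / (2 * alpha))
        W = confidence_weights(data, params.c)

        def posterior_route(emb):
            from lorentzmf.hmf_model import pairwise_sq_dists

            D2 = pairwise_sq_dists(emb.U, emb.V)
            like = np.sum(W * (np.logaddexp(0.0, -D2) + data.R * D2))
            return (
                like
                - prior.log_density(emb.U).sum()
                - prior.log_density(emb.V).sum()
            )

        embs = [
            Embedding(random_points(rng, m, d, 0.6), random_points(rng, n, d, 0.6))
            for _ in range(10)
        ]
        offsets = [loss(e, data, params) - posterior_route(e) for e in embs]
        assert np.max(offsets) - np.min(offsets) < 1e-8

    def test_shape_mismatch_rejected(self, rng):
        emb, data, params, _ = random_instance(rng, 4, 3, 2)
        bad = InteractionData(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            loss(emb, bad, params)


def finite_difference(fun, X, eps=1e-6):
    grad = np.zeros_like(X)
    for idx in np.ndindex(X.shape):
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += eps
        Xm[idx] -= eps
        grad[idx] = (fun(Xp) - fun(Xm)) / (2 * eps)
    return grad


class TestAmbientGradients:
    @pytest.mark.parametrize(
        "m, n, d, c, alpha, beta",
        [
            (4, 3, 2, 1.0, 0.0, 0.0),
            (5, 4, 3, 5.0, 0.0, 0.0),
            (6, 5, 4, 1.0, 0.3, 0.0),
            (8, 6, 3, 5.0, 0.3, 0.1),
            (3, 6, 1, 5.0, 0.5, 0.2),  # d = 1: the (d-1) prior term vanishes
        ],
    )
    def test_matches_central_finite_differences(self, m, n, d, c, alpha, beta):
        for trial in range(4):
            rng = np.random.default_rng(1000 * trial + m * 10 + n)
            emb, data, params, sim = random_instance(
                rng, m, n, d, c, alpha, beta, with_sim=beta > 0
            )
            gU = ambient_gradient_U(emb, data, params, sim, flip_last=False)
            gV = ambient_gradient_V(emb, data, params, sim, flip_last=False)
            fdU = finite_difference(
                lambda U: loss(Embedding(U, emb.V), data, params, sim), emb.U
            )
            fdV = finite_difference(
                lambda V: loss(Embedding(emb.U, V), data, params, sim), emb.V
            )
            assert np.allclose(gU, fdU, rtol=1e-5, atol=1e-6)
            assert np.allclose(gV, fdV, rtol=1e-5, atol=1e-6)

    def test_single_pair_role_symmetry(self, rng):
        # d_L^2 is symmetric: for one drug-target pair with no prior the
        # gradient w.r.t. u equals the gradient w.r.t. v with roles swapped
        u = random_points(rng, 1, 3)
        v = random_points(rng, 1, 3)
        data = InteractionData(np.array([[1.0]]))
        params = ModelParams(d=3, c=1.0, alpha_U=0.0, alpha_V=0.0)
        gU = ambient_gradient_U(Embedding(u, v), data, params, flip_last=False)
        gV = ambient_gradient_V(Embedding(v, u), data, params, flip_last=False)
        assert np.allclose(gU, gV, atol=1e-12)

    def test_flip_negates_time_component_only(self, rng):
        emb, data, params, _ = random_instance(rng, 4, 3, 2, alpha=0.2)
        raw = ambient_gradient_U(emb, data, params, flip_last=False)
        flipped = ambient_gradient_U(emb, data, params, flip_last=True)
        assert np.allclose(raw[:, :-1], flipped[:, :-1])
        assert np.allclose(raw[:, -1], -flipped[:, -1])
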