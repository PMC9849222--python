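"""Folds, ranking metrics vs brute force, Euclidean baseline, benchmark."""

import numpy as np
import pytest

from helpers import (
    brute_force_auc,
    brute_force_aupr,
    brute_force_average_precision,
    brute_force_prec_at_k,
)
from lorentzmf.data_io import generate_euclidean_synthetic, generate_synthetic
from lorentzmf.evaluation import (
    CVPlan,
    UndefinedMetricError,
    auc,
    aupr,
    average_precision,
    cross_validate,
    euclidean_baseline_fit,
    euclidean_gradient_U,
    euclidean_gradient_V,
    euclidean_loss,
    euclidean_predict_scores,
    euclidean_weighted_profile,
    make_folds,
    prec_at_k,
    run_benchmark,
)
from lorentzmf.hmf_model import Embedding, InteractionData, ModelParams, SimilarityPair
from lorentzmf.optimizer import OptimizerConfig


class TestFolds:
    def test_pair_kfold_partitions_every_cell(self):
        data = InteractionData(np.zeros((4, 5)) + np.eye(4, 5))
        rounds = make_folds(CVPlan(k=5, rounds=2, seed=1), data)
        assert len(rounds) == 2
        for folds in rounds:
            coverage = np.zeros((4, 5), dtype=int)
            for train, test in folds:
                assert np.array_equal(train, ~test)
                coverage += test
            assert np.all(coverage == 1)

    def test_loocv_hides_one_drug_row_per_fold(self):
        data = InteractionData(np.ones((7, 3)))
        rounds = make_folds(CVPlan(scheme="loocv_drug"), data)
        assert len(rounds) == 1 and len(rounds[0]) == 7
        for i, (train, test) in enumerate(rounds[0]):
            expected = np.zeros((7, 3), dtype=bool)
            expected[i] = True
            assert np.array_equal(test, expected)

    def test_same_seed_same_folds(self):
        data = InteractionData(np.ones((6, 6)))
        a = make_folds(CVPlan(k=4, rounds=3, seed=9), data)
        b = make_folds(CVPlan(k=4, rounds=3, seed=9), data)
        for fa, fb in zip(a, b):
            for (tra, tea), (trb, teb) in zip(fa, fb):
                assert np.array_equal(tea, teb)

    def test_k_larger_than_cells_rejected(self):
        with pytest.raises(ValueError):
            make_folds(CVPlan(k=10), InteractionData(np.ones((2, 2))))


class TestMetrics:
    def test_auc_known_cases(self):
        assert auc([1, 0, 1, 0], [0.9, 0.8, 0.1, 0.2]) == 0.5
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_perfect_ranking_maxes_all_metrics(self):
        labels = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        scores = np.linspace(1, 0, 12)
        assert auc(labels, scores) == 1.0
        assert aupr(labels, scores) == 1.0
        assert average_precision(labels, scores) == 1.0
        assert prec_at_k(labels, scores, k=2) == 1.0

    def test_single_positive_at_top(self):
        assert average_precision([1, 0, 0], [0.9, 0.5, 0.1]) == 1.0

    def test_degenerate_labels_raise(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 1], [0.2, 0.3])
        with pytest.raises(UndefinedMetricError):
            aupr([0, 0], [0.2, 0.3])

    @pytest.mark.parametrize("trial", range(10))
    def test_all_metrics_equal_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(12, 21))
        labels = (rng.random(n) < 0.4).astype(float)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 1.0, 0.0
        scores = rng.random(n)  # continuous: no ties
        assert auc(labels, scores) == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)
        assert aupr(labels, scores, seed=trial) == pytest.approx(
            brute_force_aupr(labels, scores, seed=trial), abs=1e-12
        )
        assert average_precision(labels, scores, seed=trial) == pytest.approx(
            brute_force_average_precision(labels, scores, seed=trial), abs=1e-12
        )
        assert prec_at_k(labels, scores, k=10, seed=trial) == pytest.approx(
            brute_force_prec_at_k(labels, scores, k=10, seed=trial), abs=1e-12
        )

    def test_tied_scores_resolved_by_seeded_order(self):
        labels = [1, 0, 1, 0, 0, 1]
        scores = [0.5] * 6
        for seed in range(3):
            assert prec_at_k(labels, scores, k=3, seed=seed) == pytest.approx(
                brute_force_prec_at_k(labels, scores, k=3, seed=seed)
            )

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(4)
        labels = (rng.random(50) < 0.3).astype(float)
        scores = rng.random(50)
        assert auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert average_precision(labels, scores) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )


class TestEuclideanBaseline:
    def test_zero_latent_vectors_score_half(self):
        emb = Embedding(np.zeros((3, 2)), np.zeros((4, 2)))
        assert np.allclose(euclidean_predict_scores(emb), 0.5)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(8)
        m, n, d = 5, 4, 3
        data = InteractionData((rng.random((m, n)) < 0.5).astype(float))
        S = rng.random((m, m))
        T = rng.random((n, n))
        sim = SimilarityPair((S + S.T) / 2, (T + T.T) / 2)
        params = ModelParams(d=d, c=3.0, alpha_U=0.2, alpha_V=0.2, beta_U=0.1, beta_V=0.1)
        emb = Embedding(rng.normal(size=(m, d)), rng.normal(size=(n, d)))
        eps = 1e-6

        def fd(X, wrap):
            g = np.zeros_like(X)
            for idx in np.ndindex(X.shape):
                Xp, Xm = X.copy(), X.copy()
                Xp[idx] += eps
                Xm[idx] -= eps
                g[idx] = (euclidean_loss(wrap(Xp), data, params, sim)
                          - euclidean_loss(wrap(Xm), data, params, sim)) / (2 * eps)
            return g

        gU = euclidean_gradient_U(emb, data, params, sim)
        gV = euclidean_gradient_V(emb, data, params, sim)
        assert np.allclose(gU, fd(emb.U, lambda U: Embedding(U, emb.V)), rtol=1e-5, atol=1e-6)
        assert np.allclose(gV, fd(emb.V, lambda V: Embedding(emb.U, V)), rtol=1e-5, atol=1e-6)

    def test_fit_decreases_loss_and_is_deterministic(self):
        rng = np.random.default_rng(2)
        data = InteractionData((rng.random((8, 6)) < 0.5).astype(float))
        params = ModelParams(d=2, c=1.0, alpha_U=0.05, alpha_V=0.05)
        config = OptimizerConfig(eta=0.05, epochs_per_phase=30, seed=1)
        r1 = euclidean_baseline_fit(data, params, config=config)
        r2 = euclidean_baseline_fit(data, params, config=config)
        assert r1.loss_trace[-1] < r1.loss_trace[0]
        assert r1.loss_trace == r2.loss_trace

    def test_weighted_profile_is_similarity_average(self):
        U = np.arange(12, dtype=float).reshape(4, 3)
        S = np.zeros((4, 4))
        S[0, 1], S[0, 2] = 0.75, 0.25
        expected = 0.75 * U[1] + 0.25 * U[2]
        assert np.allclose(euclidean_weighted_profile(0, S, U, J=2), expected)


class TestCrossValidate:
    def test_report_aggregation_recomputable(self):
        truth = generate_synthetic(12, 10, 2, 1.0, seed=0)
        params = ModelParams(d=2, c=2.0, alpha_U=0.2, alpha_V=0.2)
        config = OptimizerConfig(eta=0.05, epochs_per_phase=10, seed=0)
        report = cross_validate(truth.data, params, config, CVPlan(k=4, rounds=2, seed=0))
        agg = report.aggregate()
        for name, vals in report.per_round.items():
            assert len(vals) == 2
            assert agg[name][0] == pytest.approx(np.mean(vals))
            assert agg[name][1] == pytest.approx(np.std(vals))
            assert 0.0 <= agg[name][0] <= 1.0

    def test_loocv_runs_with_profile_coldstart(self):
        truth = generate_synthetic(8, 12, 2, 1.0, seed=3)
        params = ModelParams(d=2, c=2.0, alpha_U=0.2, alpha_V=0.2, beta_U=0.1, beta_V=0.1)
        config = OptimizerConfig(eta=0.05, epochs_per_phase=8, seed=0)
        report = cross_validate(
            truth.data, params, config, CVPlan(scheme="loocv_drug"),
            truth.sim, use_profile_coldstart=True,
        )
        assert len(report.per_round["AUC"]) == 1

    def test_methods_share_folds_given_shared_plan(self):
        # the paired-comparison contract: folds depend only on the plan
        data = InteractionData(np.ones((5, 4)) * np.eye(5, 4))
        a = make_folds(CVPlan(k=3, rounds=1, seed=5), data)
        b = make_folds(CVPlan(k=3, rounds=1, seed=5), data)
        assert all(
            np.array_equal(ta[1], tb[1]) for ta, tb in zip(a[0], b[0])
        )


class TestBenchmark:
    def test_single_grid_point_two_rounds(self):
        truth = generate_synthetic(10, 8, 2, 1.0, seed=1)
        plan = CVPlan(k=4, rounds=2, seed=0)
        config = OptimizerConfig(eta=0.05, epochs_per_phase=8, seed=0)
        grids = {"hyperbolic": [{"d": 2, "c": 2.0, "alpha_U": 0.2, "alpha_V": 0.2,
                                 "beta_U": 0.0, "beta_V": 0.0}]}
        out = run_benchmark(truth.data, methods=("hyperbolic",), plan=plan,
                            grids=grids, config=config)
        report = out["hyperbolic"]["report"]
        assert len(report.per_round["AUC"]) == 2
        assert out["hyperbolic"]["selection"]["n_combos"] == 1

    def test_empty_grid_rejected(self):
        truth = generate_synthetic(6, 5, 2, 1.0, seed=1)
        with pytest.raises(ValueError):
            run_benchmark(truth.data, methods=("hyperbolic",),
                          plan=CVPlan(k=3, rounds=1), grids={"hyperbolic": []})
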