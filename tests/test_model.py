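import math

import numpy as np
import pytest

from drmrr import (
    GTDConfig,
    SolverConfig,
    SyntheticSpec,
    btilde_norm,
    dual_exponent,
    evaluate,
    fit,
    generate_realizable_gtd_dataset,
    gtd_matrix,
    objective,
    predict_gtd,
    rank_by_gtd,
    tune_epsilon,
)
from drmrr.model import DRMRRModel, _objective_arrays


def irls_erm_oracle(X, Theta, iters=800, delta=1e-10):
    """Independent minimiser of the mean residual 2-norm: Weiszfeld-style
    iteratively reweighted least squares (no shared code with the solver)."""
    B = np.linalg.lstsq(X, Theta, rcond=None)[0]
    for _ in range(iters):
        R = Theta - X @ B
        w = 1.0 / np.maximum(np.linalg.norm(R, axis=1), delta)
        sw = np.sqrt(w)[:, None]
        B = np.linalg.lstsq(X * sw, Theta * sw, rcond=None)[0]
    return B


def realizable(T=40, p=6, K=3, seed=0, noise=0.0):
    spec = SyntheticSpec(T=T, n_range=(5, 10), p=p, seed=seed, noise_sd=noise)
    return generate_realizable_gtd_dataset(spec, K=K)


class TestDualExponent:
    def test_pairs(self):
        assert dual_exponent(2.0) == 2.0
        assert dual_exponent(1.0) == math.inf
        assert dual_exponent(math.inf) == 1.0
        assert dual_exponent(3.0) == pytest.approx(1.5)

    def test_invalid(self):
        with pytest.raises(ValueError):
            dual_exponent(0.5)


class TestBtildeNorm:
    def test_zero_matrix_gives_identity_block_norm(self):
        for s in (1.0, 2.0, math.inf):
            assert btilde_norm(np.zeros((4, 3)), s) == 1.0

    def test_single_entry_rank_one(self):
        B = np.zeros((3, 2))
        B[1, 0] = -2.5
        assert btilde_norm(B, 2.0) == pytest.approx(math.sqrt(1 + 2.5**2))

    def test_spectral_matches_brute_force_and_power_iteration(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            B = rng.standard_normal((4, 3)) * rng.uniform(0.1, 3)
            got = btilde_norm(B, 2.0)
            Bt = np.vstack([-B, np.eye(3)])  # Btilde'
            # random-unit-vector lower bound never exceeds the norm
            V = rng.standard_normal((500, 3))
            lower = max(
                np.linalg.norm(Bt @ (v / np.linalg.norm(v))) for v in V
            )
            assert lower <= got + 1e-9
            # power iteration on Bt'Bt converges to the same value
            v = rng.standard_normal(3)
            for _ in range(400):
                v = Bt.T @ (Bt @ v)
                v /= np.linalg.norm(v)
            assert np.linalg.norm(Bt @ v) == pytest.approx(got, abs=1e-8)

    def test_never_exceeds_frobenius_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            B = rng.standard_normal((5, 4))
            assert btilde_norm(B, 2.0) <= math.sqrt(1 + (B**2).sum()) + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            btilde_norm(np.array([[np.nan]]), 2.0)


class TestObjective:
    def test_zero_residual_zero_epsilon(self):
        ds, targets, B_star = realizable(seed=1)
        assert objective(B_star, ds, targets, epsilon=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_b_zero_reduces_to_target_norms_plus_epsilon(self):
        ds, targets, _ = realizable(seed=2)
        Theta = np.vstack([t.values for t in targets])
        expected = np.linalg.norm(Theta, axis=1).mean()
        B0 = np.zeros((ds.p, Theta.shape[1]))
        assert objective(B0, ds, targets, epsilon=0.0) == pytest.approx(expected)
        assert objective(B0, ds, targets, epsilon=0.3) == pytest.approx(expected + 0.3)

    def test_linear_in_epsilon_at_fixed_b(self):
        ds, targets, B_star = realizable(seed=3)
        base = objective(B_star, ds, targets, epsilon=0.0)
        reg = btilde_norm(B_star, 2.0)
        for eps in (0.1, 0.2):
            assert objective(B_star, ds, targets, epsilon=eps) == pytest.approx(base + eps * reg)

    def test_convexity_probe(self):
        ds, targets, _ = realizable(seed=4, noise=0.3)
        rng = np.random.default_rng(0)
        K = targets[0].values.shape[1]
        for _ in range(20):
            B1, B2 = rng.standard_normal((2, ds.p, K))
            t = rng.uniform(0.01, 0.99)
            lhs = objective(t * B1 + (1 - t) * B2, ds, targets, epsilon=0.1)
            rhs = t * objective(B1, ds, targets, epsilon=0.1) + (1 - t) * objective(
                B2, ds, targets, epsilon=0.1
            )
            assert lhs <= rhs + 1e-9


class TestFit:
    def test_noiseless_recovery(self):
        ds, targets, B_star = realizable(T=60, p=8, K=3, seed=5)
        model = fit(ds, GTDConfig(K=3), epsilon=0.0, targets=targets)
        assert np.abs(model.B - B_star).max() < 1e-3

    def test_large_epsilon_shrinks_b_toward_zero(self):
        # sqrt(1 + sigma^2) is flat at sigma = 0, so the optimum is near but
        # not exactly zero: sigma* ~ (residual slope)/epsilon
        ds, targets, _ = realizable(seed=6, noise=0.2)
        model = fit(ds, GTDConfig(K=3), epsilon=50.0, targets=targets)
        Theta = np.vstack([t.values for t in targets])
        limit = np.linalg.norm(Theta, axis=1).mean() + 50.0
        assert np.abs(model.B).max() < 0.05
        assert model.objective_value == pytest.approx(limit, rel=1e-3)
        assert model.objective_value <= limit + 1e-9

    def test_deterministic_given_seed(self):
        ds, targets, _ = realizable(seed=7, noise=0.5)
        kwargs = dict(epsilon=0.05, targets=targets, solver=SolverConfig(seed=3))
        a = fit(ds, GTDConfig(K=3), **kwargs)
        b = fit(ds, GTDConfig(K=3), **kwargs)
        assert np.array_equal(a.B, b.B)

    def test_erm_limit_matches_irls_oracle(self):
        ds, targets, _ = realizable(T=25, p=5, K=2, seed=8, noise=0.4)
        model = fit(ds, GTDConfig(K=2), epsilon=0.0, targets=targets)
        X = np.vstack([q.features for q in ds])
        Theta = np.vstack([t.values for t in targets])
        oracle_obj = _objective_arrays(irls_erm_oracle(X, Theta), X, Theta, 0.0, 2)
        assert model.objective_value == pytest.approx(oracle_obj, abs=1e-4)

    def test_regularization_path_monotone(self):
        ds, targets, _ = realizable(T=25, p=5, K=2, seed=9, noise=0.4)
        vals = [
            fit(ds, GTDConfig(K=2), epsilon=eps, targets=targets).objective_value
            for eps in (0.0, 0.02, 0.1, 0.5, 2.0)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_residual_term_nondecreasing_in_epsilon(self):
        ds, targets, _ = realizable(T=25, p=5, K=2, seed=10, noise=0.4)
        X = np.vstack([q.features for q in ds])
        Theta = np.vstack([t.values for t in targets])
        resid = []
        for eps in (0.0, 0.1, 1.0):
            m = fit(ds, GTDConfig(K=2), epsilon=eps, targets=targets)
            resid.append(_objective_arrays(m.B, X, Theta, 0.0, 2))
        assert all(a <= b + 1e-7 for a, b in zip(resid, resid[1:]))

    def test_gtd_targets_built_when_not_supplied(self, small_dataset):
        cfg = GTDConfig(K=3)
        model = fit(small_dataset, cfg, epsilon=0.0)
        targets = [gtd_matrix(q, cfg) for q in small_dataset]
        assert model.objective_value == pytest.approx(
            objective(model.B, small_dataset, targets, 0.0), abs=1e-9
        )

    @pytest.mark.parametrize("r", [1.0, math.inf])
    def test_other_norm_orders_decrease_objective(self, r):
        ds, targets, _ = realizable(T=20, p=4, K=2, seed=11, noise=0.3)
        solver = SolverConfig(max_iterations=3000)
        m = fit(ds, GTDConfig(K=2), epsilon=0.01, r=r, targets=targets, solver=solver)
        B0 = np.zeros_like(m.B)
        assert m.objective_value < objective(B0, ds, targets, 0.01, r)

    def test_unsupported_r_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            fit(small_dataset, GTDConfig(K=2), r=3.0)


class TestPredictAndRank:
    def test_predict_is_linear_map(self):
        cfg = GTDConfig(K=2)
        model = DRMRRModel(B=np.array([[1.0, 0.0], [0.0, 2.0]]), r=2.0, epsilon=0.0, config=cfg)
        out = predict_gtd(model, np.eye(2))
        assert np.allclose(out, np.array([[1.0, 0.0], [0.0, 2.0]]))

    def test_dimension_mismatch_rejected(self):
        model = DRMRRModel(B=np.ones((3, 2)), r=2.0, epsilon=0.0, config=GTDConfig(K=2))
        with pytest.raises(ValueError):
            predict_gtd(model, np.ones((4, 5)))

    def test_cyclic_scoring_hand_trace(self):
        theta = np.array([[0.9, 0.1], [0.5, 0.8], [0.2, 0.3]])
        assert rank_by_gtd(theta).order.tolist() == [0, 1, 2]

    def test_k1_reduces_to_argsort(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal((7, 1))
        assert rank_by_gtd(col).order.tolist() == np.argsort(-col[:, 0]).tolist()

    def test_ties_pick_lowest_row(self):
        theta = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert rank_by_gtd(theta).order.tolist() == [0, 1]

    def test_output_always_permutation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            theta = rng.standard_normal((int(rng.integers(1, 10)), int(rng.integers(1, 5))))
            order = rank_by_gtd(theta).order
            assert sorted(order.tolist()) == list(range(theta.shape[0]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_by_gtd(np.zeros((0, 2)))


class TestEvaluateAndTune:
    def test_perfect_recovery_end_to_end(self):
        ds, targets, B_star = realizable(T=50, p=6, K=3, seed=12)
        model = fit(ds, GTDConfig(K=3), epsilon=0.0, targets=targets)
        spec = SyntheticSpec(T=15, n_range=(5, 10), p=6, seed=99, planted_B=B_star)
        held_out, _, _ = generate_realizable_gtd_dataset(spec)
        rep = evaluate(model, held_out, ks=[5])
        assert rep.means["NDCG@5"] == pytest.approx(1.0)

    def test_metrics_in_range_and_deterministic(self, small_dataset):
        cfg = GTDConfig(K=3)
        model = fit(small_dataset, cfg, epsilon=0.01)
        a = evaluate(model, small_dataset, ks=[3, 5])
        b = evaluate(model, small_dataset, ks=[3, 5])
        assert a.means == b.means
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in a.means.values())

    def test_tune_selects_by_validation_ndcg(self, small_dataset):
        cfg = GTDConfig(K=3)
        model, results = tune_epsilon(small_dataset, small_dataset, [0.01], cfg)
        assert model.epsilon == 0.01 and set(results) == {0.01}


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, small_dataset):
        cfg = GTDConfig(K=3)
        model = fit(small_dataset, cfg, epsilon=0.02)
        path = tmp_path / "model.json"
        model.save(path)
        back = DRMRRModel.load(path)
        assert np.array_equal(back.B, model.B)
        assert back.epsilon == model.epsilon and back.r == model.r
        assert back.config == model.config
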