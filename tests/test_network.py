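"""Prediction network: forward/cost/gradient contracts, training, RF tools."""

import numpy as np
import pytest

from predrf import network
from predrf.data import PastFuturePair


def _finite_diff(params, U, V, lam, eps=1e-6):
    out = {}
    for key in ("W_in", "b_hidden", "W_out", "b_out"):
        arr = getattr(params, key)
        grad = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            arr[i] += eps
            cp = network.cost(params, U, V, lam)
            arr[i] -= 2 * eps
            cm = network.cost(params, U, V, lam)
            arr[i] += eps
            grad[i] = (cp - cm) / (2 * eps)
        out[key] = grad
    return out


class TestForward:
    def test_zero_network_logistic(self):
        params = network.NetworkParams(
            W_in=np.zeros((3, 4)), b_hidden=np.zeros(3),
            W_out=np.zeros((2, 3)), b_out=np.zeros(2), nonlinearity="logistic",
        )
        S, V_hat = network.forward(params, np.ones((5, 4)))
        assert np.allclose(S, 0.5)
        assert np.allclose(V_hat, 0.0)

    def test_hand_computed_case(self):
        """1 hidden unit, 2 inputs, 1 output, checked by pencil arithmetic."""
        params = network.NetworkParams(
            W_in=np.array([[1.0, -2.0]]), b_hidden=np.array([0.5]),
            W_out=np.array([[3.0]]), b_out=np.array([-1.0]), nonlinearity="logistic",
        )
        U = np.array([[2.0, 1.0]])  # a = 0.5 + 2 - 2 = 0.5
        S, V_hat = network.forward(params, U)
        s = 1 / (1 + np.exp(-0.5))
        assert np.isclose(S[0, 0], s)
        assert np.isclose(V_hat[0, 0], 3 * s - 1)

    def test_linear_superposition(self, rng):
        params = network.init_params(6, 4, 3, "linear", seed=0)
        a = rng.standard_normal((5, 6))
        b = rng.standard_normal((5, 6))
        _, va = network.forward(params, a)
        _, vb = network.forward(params, b)
        _, vab = network.forward(params, a + b)
        bias = params.b_out
        assert np.allclose(vab, va + vb - bias, atol=1e-10)

    def test_nonfinite_rejected(self):
        params = network.init_params(3, 2, 2, seed=0)
        with pytest.raises(ValueError):
            network.forward(params, np.array([[np.nan, 1, 2]]))


class TestCost:
    def test_perfect_prediction_zero_lambda(self):
        params = network.NetworkParams(
            W_in=np.zeros((2, 3)), b_hidden=np.zeros(2),
            W_out=np.zeros((2, 2)), b_out=np.array([1.0, -1.0]),
        )
        V = np.tile([1.0, -1.0], (4, 1))
        assert network.cost(params, np.zeros((4, 3)), V, 0.0) == 0.0

    def test_penalty_only(self):
        """Zero-error net with one weight = -2 and lambda = 0.5 -> E = 1."""
        params = network.NetworkParams(
            W_in=np.array([[-2.0, 0.0]]), b_hidden=np.zeros(1),
            W_out=np.zeros((1, 1)), b_out=np.zeros(1),
        )
        E = network.cost(params, np.zeros((3, 2)), np.zeros((3, 1)), 0.5)
        assert np.isclose(E, 1.0)

    def test_cost_dominates_penalty(self, rng):
        params = network.init_params(4, 3, 2, seed=1)
        U = rng.standard_normal((6, 4))
        V = rng.standard_normal((6, 2))
        lam = 0.1
        penalty = lam * (np.abs(params.W_in).sum() + np.abs(params.W_out).sum())
        assert network.cost(params, U, V, lam) >= penalty


class TestGradient:
    @pytest.mark.parametrize("nonlinearity", list(network.NONLINEARITIES))
    def test_matches_finite_differences(self, nonlinearity, rng):
        params = network.init_params(5, 4, 3, nonlinearity, seed=2)
        U = rng.standard_normal((7, 5))
        V = rng.standard_normal((7, 3))
        lam = 0.01
        analytic = network.gradient(params, U, V, lam)
        numeric = _finite_diff(params, U, V, lam)
        for key in analytic:
            scale = np.max(np.abs(numeric[key])) + 1e-12
            assert np.max(np.abs(analytic[key] - numeric[key])) / scale < 1e-5

    def test_zero_gradient_at_least_squares_optimum(self, rng):
        """Construct the linear lambda=0 global optimum in closed form."""
        U = rng.standard_normal((50, 4))
        V = rng.standard_normal((50, 2))
        X = np.hstack([U, np.ones((50, 1))])
        beta = np.linalg.lstsq(X, V, rcond=None)[0]  # [5 x 2]
        params = network.NetworkParams(
            W_in=np.eye(4), b_hidden=np.zeros(4),
            W_out=beta[:4].T, b_out=beta[4], nonlinearity="linear",
        )
        grads = network.gradient(params, U, V, 0.0)
        assert np.linalg.norm(grads["W_out"]) < 1e-8
        assert np.linalg.norm(grads["b_out"]) < 1e-8

    def test_gradient_step_decreases_cost(self, rng):
        params = network.init_params(6, 4, 3, seed=3)
        U = rng.standard_normal((20, 6))
        V = rng.standard_normal((20, 3))
        before = network.cost(params, U, V, 0.01)
        grads = network.gradient(params, U, V, 0.01)
        for key, g in grads.items():
            getattr(params, key)[...] -= 1e-3 * g
        assert network.cost(params, U, V, 0.01) < before


class TestTrain:
    def test_copy_task_solved(self, rng):
        """Future = last past frame: exactly solvable, MSE goes to ~0."""
        U = rng.standard_normal((3000, 32))
        V = U[:, -8:].copy()
        pair = PastFuturePair(U=U, V=V, feature_shape=(8,), n_past=4, n_future=1)
        cfg = network.TrainConfig(n_hidden=16, lam=0.0, epochs=200, lr=3e-3,
                                  nonlinearity="linear", seed=0)
        params, _ = network.train(pair, cfg)
        assert network.validation_mse(params, U, V) < 0.01

    def test_training_improves_prediction(self, texture_clip_dataset):
        from predrf import data

        ds = data.normalize_dataset(texture_clip_dataset)
        pair = data.split_past_future(ds)
        init = network.init_params(pair.I, 16, pair.K, "logistic", seed=0)
        initial = network.validation_mse(init, pair.U, pair.V)
        cfg = network.TrainConfig(n_hidden=16, lam=1e-5, epochs=10, seed=0)
        params, history = network.train(pair, cfg, pair)
        assert history["val_mse"][-1] < initial

    def test_seed_repeat_identical_parameters(self, rng):
        U = rng.standard_normal((400, 10))
        V = rng.standard_normal((400, 3))
        pair = PastFuturePair(U=U, V=V, feature_shape=(1,), n_past=10, n_future=3)
        cfg = network.TrainConfig(n_hidden=5, lam=1e-4, epochs=5, seed=42)
        p1, _ = network.train(pair, cfg)
        p2, _ = network.train(pair, cfg)
        assert np.array_equal(p1.W_in, p2.W_in)
        assert np.array_equal(p1.b_out, p2.b_out)

    def test_empty_training_set_rejected(self):
        pair = PastFuturePair(U=np.zeros((0, 4)), V=np.zeros((0, 2)),
                              feature_shape=(2,), n_past=2, n_future=1)
        with pytest.raises(ValueError):
            network.train(pair, network.TrainConfig(n_hidden=2))


class TestRfExtraction:
    def test_planted_row_recovered(self, rng):
        params = network.init_params(28, 4, 7, seed=0)
        planted = rng.standard_normal(28)
        params.W_in[2] = planted
        rfset = network.extract_rfs(params, (4, 7))
        # row reshaped [time x freq] then time moved last -> [freq x time]
        assert np.array_equal(rfset.rfs[2], planted.reshape(4, 7).T)
        assert len(rfset) == 4

    def test_unflatten_flatten_identity(self, rng):
        params = network.init_params(12, 3, 4, seed=1)
        rfset = network.extract_rfs(params, (3, 2, 2))
        back = np.moveaxis(rfset.rfs, -1, 1).reshape(3, 12)
        assert np.array_equal(back, params.W_in)

    def test_geometry_mismatch_rejected(self):
        params = network.init_params(12, 3, 4, seed=1)
        with pytest.raises(ValueError):
            network.extract_rfs(params, (5, 3))


class TestPruneInactive:
    def test_one_percent_threshold(self):
        rfset = network.RfSet(rfs=np.zeros((3, 2, 2)), strengths=np.array([100.0, 2.0, 0.5]))
        pruned = network.prune_inactive(rfset)
        assert pruned.active_mask.tolist() == [True, True, False]

    def test_equal_strengths_none_pruned(self):
        rfset = network.RfSet(rfs=np.zeros((4, 2, 2)), strengths=np.full(4, 3.0))
        assert network.prune_inactive(rfset).active_mask.all()

    def test_pruned_units_negligible_for_prediction(self, rng):
        U = rng.standard_normal((500, 10))
        V = rng.standard_normal((500, 3))
        pair = PastFuturePair(U=U, V=V, feature_shape=(1,), n_past=10, n_future=3)
        cfg = network.TrainConfig(n_hidden=8, lam=5e-3, epochs=60, lr=3e-3, seed=1)
        params, _ = network.train(pair, cfg)
        rfset = network.prune_inactive(network.extract_rfs(params, (10, 1)))
        before = network.validation_mse(params, U, V)
        # an inactive unit's activity is ~constant; removing it means zeroing
        # its output weights and folding that constant into the output bias
        S, _ = network.forward(params, U)
        zeroed = params.copy()
        pruned = ~rfset.active_mask
        zeroed.b_out += zeroed.W_out[:, pruned] @ S.mean(axis=0)[pruned]
        zeroed.W_out[:, pruned] = 0.0
        assert pruned.any()
        assert abs(network.validation_mse(zeroed, U, V) - before) < 1e-3


class TestSignConvention:
    @pytest.mark.parametrize("nonlinearity", ["logistic", "tanh", "linear"])
    def test_flip_preserves_predictions(self, nonlinearity, rng):
        params = network.init_params(8, 4, 3, nonlinearity, seed=5)
        U = rng.standard_normal((10, 8))
        _, before = network.forward(params, U)
        flipped = network.normalize_sign(params.copy(), (4, 2))
        _, after = network.forward(flipped, U)
        assert np.allclose(before, after, atol=1e-10)

    def test_double_flip_is_identity(self):
        params = network.init_params(6, 3, 2, seed=6)
        once = network._flip_unit(params, 1)
        twice = network._flip_unit(once, 1)
        for key in ("W_in", "b_hidden", "W_out", "b_out"):
            assert np.allclose(getattr(twice, key), getattr(params, key), atol=1e-12)

    def test_negative_leading_unit_flipped(self):
        from predrf import synth

        planted = synth.make_planted_strf(n_freq=4, n_time=8, center_channel=2,
                                          spectral_sd=1.0, exc_latency=1, inh_latency=4)
        params = network.init_params(32, 2, 4, seed=7)
        params.W_in[0] = -planted.values.T.ravel()  # negative-leading row
        out = network.normalize_sign(params, (8, 4))
        rf = out.W_in[0].reshape(8, 4)
        assert rf[-2:].sum() > 0

    def test_relu_flip_rejected(self):
        params = network.init_params(6, 3, 2, "relu", seed=8)
        with pytest.raises(ValueError):
            network._flip_unit(params, 0)

    def test_cost_invariant_under_flip(self, rng):
        params = network.init_params(8, 4, 3, "logistic", seed=9)
        U = rng.standard_normal((10, 8))
        V = rng.standard_normal((10, 3))
        flipped = network._flip_unit(params, 2)
        # MSE part identical; L1 part too (absolute values)
        assert np.isclose(
            network.cost(params, U, V, 0.05), network.cost(flipped, U, V, 0.05), atol=1e-10
        )


class TestGridSearch:
    def test_single_cell_matches_direct_training(self, rng):
        U = rng.standard_normal((300, 8))
        V = rng.standard_normal((300, 2))
        pair = PastFuturePair(U=U, V=V, feature_shape=(2,), n_past=4, n_future=1)
        base = network.TrainConfig(epochs=5, seed=3)
        rows = network.grid_search(pair, pair, [4], [1e-3], base)
        assert len(rows) == 1
        assert rows[0]["val_mse"] == min(r["val_mse"] for r in rows)

    def test_absurd_lambda_collapses_weights(self, rng):
        """lambda = 1e3 drives all weights to ~0; the predictor reduces to
        its output bias and validation MSE approaches var(V)."""
        U = rng.standard_normal((1000, 4))
        V = rng.standard_normal((1000, 2))
        pair = PastFuturePair(U=U, V=V, feature_shape=(2,), n_past=2, n_future=1)
        base = network.TrainConfig(n_hidden=2, epochs=1500, lr=3e-4, seed=0)
        rows = network.grid_search(pair, pair, [2], [1e3], base)
        params = rows[0]["params"]
        assert np.abs(params.W_in).sum() + np.abs(params.W_out).sum() < 1e-3
        assert abs(rows[0]["val_mse"] - V.var()) < 0.05 * V.var()

    def test_empty_grid_rejected(self, rng):
        pair = PastFuturePair(U=np.zeros((5, 4)), V=np.zeros((5, 2)),
                              feature_shape=(2,), n_past=2, n_future=1)
        with pytest.raises(ValueError):
            network.grid_search(pair, pair, [], [1e-3])


class TestResponseWeightedAverage:
    def test_linear_network_recovers_composed_map(self):
        params = network.init_params(30, 10, 5, "linear", seed=1)
        rwa = network.response_weighted_average(params, n_samples=100_000, seed=2)
        lin = params.W_out @ params.W_in
        cosine = np.sum(rwa * lin) / (np.linalg.norm(rwa) * np.linalg.norm(lin))
        assert cosine > 0.99

    def test_split_half_consistency_for_trained_like_net(self):
        params = network.init_params(20, 8, 4, "logistic", seed=3)
        params.W_out *= 3.0  # give outputs some gain
        a = network.response_weighted_average(params, n_samples=100_000, seed=10)
        b = network.response_weighted_average(params, n_samples=100_000, seed=11)
        corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert corr > 0.9


class TestPopulationSparsity:
    def test_constant_responses_zero(self):
        s, mean_s = network.population_sparsity(np.full((10, 3), 2.0))
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_one_hot_response_one(self):
        r = np.zeros((10, 1))
        r[4, 0] = 5.0
        s, _ = network.population_sparsity(r)
        assert np.isclose(s[0], 1.0)

    def test_bounded_unit_interval(self, rng):
        r = rng.random((50, 20))
        s, _ = network.population_sparsity(r)
        assert np.all((s >= -1e-12) & (s <= 1.0 + 1e-12))

    def test_negative_responses_rejected(self):
        with pytest.raises(ValueError):
            network.population_sparsity(np.array([[1.0, -0.1], [0.5, 0.2]]))


def test_params_hdf5_roundtrip(tmp_path):
    params = network.init_params(6, 3, 2, "tanh", seed=0)
    path = str(tmp_path / "p.h5")
    network.save_params(path, params)
    loaded = network.load_params(path)
    assert loaded.nonlinearity == "tanh"
    assert np.array_equal(loaded.W_in, params.W_in)
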