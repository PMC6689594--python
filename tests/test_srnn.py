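"""Stacked RNN: initialization spectra, recurrence, BPTT gradients, training."""

import numpy as np
import pytest

from hyotrack.srnn import (SRNNConfig, SRNNParams, backward, forward,
                           init_params, load_params, mse_loss, predict_pixels,
                           save_params, train)
from hyotrack.targets import HyoidAnnotation, TargetScaler


def tiny_config(**kw):
    defaults = dict(n_layers=2, units=4, input_dim=3, output_dim=2, seed=0,
                    max_epochs=50, patience=10)
    defaults.update(kw)
    return SRNNConfig(**defaults)


class TestInitParams:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_recurrent_matrices_are_spd_with_unit_top_eigenvalue(self, seed):
        params = init_params(tiny_config(seed=seed, units=16))
        for W in params.W:
            assert np.allclose(W, W.T)
            eig = np.linalg.eigvalsh(W)
            assert eig[0] > 0
            assert abs(eig[-1] - 1.0) < 1e-6
            assert np.all(eig[:-1] < 1.0)

    def test_dense_matrices_bounded_and_biases_zero(self):
        params = init_params(tiny_config(seed=5))
        for arr in (params.R, params.U, *params.V):
            assert np.max(np.abs(arr)) <= 0.01
        for b in params.b:
            assert np.all(b == 0.0)

    def test_deterministic_given_seed(self):
        a = init_params(tiny_config(seed=9))
        b = init_params(tiny_config(seed=9))
        for x, y in zip(a.arrays(), b.arrays()):
            assert np.array_equal(x, y)


class TestForward:
    def test_all_zero_parameters_give_zero_output(self):
        cfg = tiny_config()
        p = init_params(cfg)
        zero = SRNNParams([np.zeros_like(w) for w in p.W],
                          [np.zeros_like(v) for v in p.V],
                          np.zeros_like(p.R), np.zeros_like(p.U),
                          [np.zeros_like(b) for b in p.b])
        X = np.random.default_rng(0).uniform(size=(5, 3))
        assert np.all(forward(zero, X) == 0.0)

    def test_hand_rolled_single_unit_recurrence(self):
        # one layer, one unit: h(0)=relu(1)=1, h(1)=relu(0.5*1+1)=1.5
        params = SRNNParams(W=[np.array([[0.5]])], V=[],
                            R=np.array([[1.0, 0.0, 0.0]]),
                            U=np.array([[2.0]]),
                            b=[np.zeros(1), np.zeros(1)])
        X = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        Y = forward(params, X)
        assert np.allclose(Y, [[2.0], [3.0]])

    def test_hidden_states_nonnegative(self):
        params = init_params(tiny_config(seed=2))
        X = np.random.default_rng(1).normal(size=(7, 3))
        _, H = forward(params, X, return_cache=True)
        assert np.all(H >= 0.0)

    def test_matches_straight_line_reference(self):
        """Oracle equivalence: independent loop-and-index recurrence."""
        cfg = tiny_config(n_layers=3, units=5, seed=11)
        params = init_params(cfg)
        rng = np.random.default_rng(4)
        for arr in (params.R, params.U, *params.V):
            arr += rng.normal(0, 0.3, arr.shape)
        X = rng.normal(size=(6, 3))
        m, u = cfg.n_layers, cfg.units

        h = {(k, -1): np.zeros(u) for k in range(m)}
        ref = []
        for t in range(X.shape[0]):
            h[(0, t)] = np.maximum(
                params.W[0] @ h[(0, t - 1)] + params.R @ X[t] + params.b[0], 0)
            for k in range(1, m):
                h[(k, t)] = np.maximum(
                    params.W[k] @ h[(k, t - 1)]
                    + params.V[k - 1] @ h[(k - 1, t)] + params.b[k], 0)
            ref.append(params.U @ h[(m - 1, t)] + params.b[m])
        assert np.allclose(forward(params, X), np.array(ref))

    def test_dimension_mismatch_rejected(self):
        params = init_params(tiny_config())
        with pytest.raises(ValueError):
            forward(params, np.zeros((4, 7)))


class TestGradients:
    def test_bptt_matches_central_differences(self):
        """Analytic gradients vs finite differences on a 2-unit, 3-frame net."""
        cfg = tiny_config(n_layers=2, units=2, input_dim=3, seed=3)
        params = init_params(cfg)
        rng = np.random.default_rng(7)
        # move away from the tiny init (and from relu kinks)
        for arr in params.arrays():
            arr += rng.normal(0, 0.4, arr.shape)
        X = rng.normal(size=(3, 3)) + 0.5
        T = rng.normal(size=(3, 2))
        Y, H = forward(params, X, return_cache=True)
        grads = backward(params, X, T, Y, H)
        eps = 1e-6
        for p_arr, g_arr in zip(params.arrays(), grads.arrays()):
            it = np.nditer(p_arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p_arr[idx]
                p_arr[idx] = orig + eps
                lp = mse_loss(forward(params, X), T)
                p_arr[idx] = orig - eps
                lm = mse_loss(forward(params, X), T)
                p_arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g_arr[idx] == pytest.approx(
                    num, rel=1e-4, abs=1e-8)


class TestTrain:
    def _toy_data(self, n, cfg, seed=0):
        rng = np.random.default_rng(seed)
        data = []
        for _ in range(n):
            X = rng.uniform(size=(8, cfg.input_dim))
            Y = np.column_stack([X[:, 0] * 0.5 + 0.2, X[:, 1] * 0.3])
            data.append((X, Y))
        return data

    def test_overfits_single_sequence(self):
        cfg = tiny_config(units=8, max_epochs=500, patience=500,
                          learning_rate=5e-3)
        data = self._toy_data(1, cfg)
        params, hist = train(init_params(cfg), data, data, cfg)
        assert hist.train_losses[-1] < 0.1 * hist.train_losses[0]

    def test_early_stop_and_best_epoch_contract(self):
        cfg = tiny_config(units=8, max_epochs=200, patience=5,
                          learning_rate=5e-3)
        tr = self._toy_data(4, cfg, seed=1)
        va = self._toy_data(2, cfg, seed=2)
        params, hist = train(init_params(cfg), tr, va, cfg)
        assert hist.best_epoch == int(np.argmin(hist.val_losses))
        if "early" in hist.stop_reason:
            assert hist.n_epochs <= hist.best_epoch + cfg.patience + 1

    def test_returns_parameters_of_best_validation_epoch(self):
        cfg = tiny_config(units=8, max_epochs=60, patience=8,
                          learning_rate=1e-2)
        tr = self._toy_data(4, cfg, seed=1)
        va = self._toy_data(2, cfg, seed=2)
        params, hist = train(init_params(cfg), tr, va, cfg)
        val = np.mean([np.mean((forward(params, X) - Y) ** 2)
                       for X, Y in va])
        assert val == pytest.approx(min(hist.val_losses), rel=1e-6)

    def test_deterministic_given_seed(self):
        cfg = tiny_config(units=4, max_epochs=20, patience=20)
        tr = self._toy_data(3, cfg, seed=1)
        va = self._toy_data(1, cfg, seed=2)
        _, h1 = train(init_params(cfg), tr, va, cfg)
        _, h2 = train(init_params(cfg), tr, va, cfg)
        assert h1.train_losses == h2.train_losses
        assert h1.val_losses == h2.val_losses


class TestPredictPixels:
    def _reference(self, n):
        c2 = np.tile([500.0, 450.0], (n, 1))
        c4 = np.tile([500.0, 570.0], (n, 1))
        ant = np.column_stack([np.linspace(460, 450, n),
                               np.linspace(480, 455, n)])
        return HyoidAnnotation(ant, c2, c4)

    def test_zero_params_give_constant_pixel_trajectory_and_box_area(self):
        cfg = tiny_config(input_dim=10)
        p = init_params(cfg)
        zero = SRNNParams([np.zeros_like(w) for w in p.W],
                          [np.zeros_like(v) for v in p.V],
                          np.zeros_like(p.R), np.zeros_like(p.U),
                          [np.zeros_like(b) for b in p.b])
        ref = self._reference(5)
        scaler = TargetScaler().fit(
            [np.array([[0.0, 0.0], [0.1, 0.2]])])
        px, boxes = predict_pixels(zero, np.zeros((5, 10)), scaler, ref)
        assert np.allclose(px, px[0])
        assert all(b.area == pytest.approx(35.0 ** 2) for b in boxes)

    def test_unfitted_scaler_rejected(self):
        cfg = tiny_config(input_dim=10)
        with pytest.raises(ValueError):
            predict_pixels(init_params(cfg), np.zeros((3, 10)),
                           TargetScaler(), self._reference(3))


def test_save_load_round_trip(tmp_path):
    cfg = tiny_config(seed=13)
    params = init_params(cfg)
    path = tmp_path / "model.npz"
    save_params(path, params, cfg)
    loaded, loaded_cfg = load_params(path)
    for a, b in zip(params.arrays(), loaded.arrays()):
        assert np.array_equal(a, b)
    assert loaded_cfg == cfg
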