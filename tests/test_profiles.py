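"""Feed-forward profile network (LM / Bayesian regularization) and the
PLS-direct linear baseline."""

import numpy as np
import pytest

from dissosurrogate.profiles import (MinMaxScaler, ProfileANN, ann_forward,
                                     init_ann, neuron_sweep, pls_direct_fit,
                                     train_br, train_lm)


def tiny_net(H=1, n_in=2, n_out=2, rng=None):
    rng = rng or np.random.default_rng(0)
    return init_ann(H, rng, n_inputs=n_in, n_outputs=n_out)


class TestForward:
    def test_zero_weights_map_to_target_midpoint(self, rng):
        net = tiny_net(H=3, n_in=2, n_out=4, rng=rng)
        net.W1[:], net.b1[:], net.W2[:], net.b2[:] = 0, 0, 0, 0
        X = rng.normal(size=(5, 2))
        Y = rng.uniform(10, 90, size=(5, 4))
        net.in_scaler.fit(X)
        net.out_scaler.fit(Y)
        out = net.forward(X)
        midpoint = (Y.min(axis=0) + Y.max(axis=0)) / 2
        np.testing.assert_allclose(out, np.tile(midpoint, (5, 1)), atol=1e-12)

    def test_hand_computed_single_hidden_neuron(self):
        net = ProfileANN(W1=np.array([[0.5, -1.0]]), b1=np.array([0.1]),
                         W2=np.array([[2.0], [-0.5]]), b2=np.array([0.3, 0.7]))
        net.in_scaler.fit(np.array([[-1.0, -1.0], [1.0, 1.0]]))   # identity map
        net.out_scaler.fit(np.array([[-1.0, -1.0], [1.0, 1.0]]))
        x = np.array([[0.2, 0.4]])
        h = np.tanh(0.5 * 0.2 - 1.0 * 0.4 + 0.1)
        expected = np.array([2.0 * h + 0.3, -0.5 * h + 0.7])
        np.testing.assert_allclose(net.forward(x)[0], expected, atol=1e-12)

    def test_unfitted_scaler_rejected(self, rng):
        net = tiny_net(rng=rng)
        with pytest.raises(RuntimeError, match="not fitted"):
            ann_forward(net, np.zeros((1, 2)))

    def test_outputs_finite_for_extreme_inputs(self, rng):
        net = tiny_net(H=4, rng=rng)
        X = rng.normal(size=(10, 2))
        Y = rng.normal(size=(10, 2))
        train_br(net, X, Y, max_epochs=5)
        out = net.forward(np.array([[1e6, -1e6]]))
        assert np.all(np.isfinite(out))


class TestLevenbergMarquardt:
    def test_converges_on_noise_free_linear_target(self, rng):
        X = rng.uniform(-1, 1, size=(25, 3))
        Y = X @ np.array([[1.0, -2.0], [0.5, 1.0], [2.0, 0.3]]) + 1.0
        net = init_ann(2, np.random.default_rng(3), n_inputs=3, n_outputs=2)
        run = train_lm(net, X, Y, max_epochs=500)
        assert net.diagnostics["final_mse"] < 1e-6

    def test_training_sse_nonincreasing_at_accepted_steps(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 4))
        net = init_ann(3, np.random.default_rng(1), n_inputs=3, n_outputs=4)
        run = train_lm(net, X, Y, max_epochs=50)
        mse = run.history["train_mse"]
        assert all(b <= a + 1e-12 for a, b in zip(mse, mse[1:]))

    def test_patience_zero_returns_pre_divergence_weights(self, rng):
        X = rng.normal(size=(30, 3))
        Y = np.tanh(X) @ rng.normal(size=(3, 5)) + 0.3 * rng.normal(size=(30, 5))
        Xv = rng.normal(size=(8, 3))
        Yv = np.tanh(Xv) @ rng.normal(size=(3, 5))
        net = init_ann(4, np.random.default_rng(2), n_inputs=3, n_outputs=5)
        run = train_lm(net, X, Y, Xv, Yv, max_epochs=100, patience=0)
        val = run.history["val_mse"]
        # the returned network achieves the best recorded validation MSE
        Yv_s = net.out_scaler.transform(Yv)
        pred_s = net.out_scaler.transform(net.forward(Xv))
        assert np.mean((pred_s - Yv_s) ** 2) == pytest.approx(min(val), rel=1e-9)

    def test_needs_enough_samples(self, rng):
        net = init_ann(5, rng, n_inputs=2, n_outputs=2)
        with pytest.raises(ValueError):
            train_lm(net, np.zeros((3, 2)), np.zeros((3, 2)))


class TestBayesianRegularization:
    def test_effective_parameters_bounded_by_weight_count(self, rng):
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 4))
        net = init_ann(4, np.random.default_rng(0), n_inputs=3, n_outputs=4)
        run = train_br(net, X, Y, max_epochs=30)
        assert all(0.0 <= g <= net.n_weights for g in run.history["gamma"])

    def test_shrinks_weights_relative_to_unregularized_lm(self):
        """With a generous hidden layer on noisy data, BR's weight-decay
        prior yields smaller weight norms than plain LM (median over seeds)."""
        norms_lm, norms_br = [], []
        for k in range(10):
            rng = np.random.default_rng(k)
            X = rng.normal(size=(40, 3))
            Y = (np.tanh(X @ rng.normal(size=(3, 4)))
                 + 0.5 * rng.normal(size=(40, 4)))
            net_lm = init_ann(10, np.random.default_rng(1000 + k),
                              n_inputs=3, n_outputs=4)
            net_br = init_ann(10, np.random.default_rng(1000 + k),
                              n_inputs=3, n_outputs=4)
            train_lm(net_lm, X, Y, max_epochs=60)
            train_br(net_br, X, Y, max_epochs=60)
            def sq(net):
                return (np.sum(net.W1 ** 2) + np.sum(net.b1 ** 2)
                        + np.sum(net.W2 ** 2) + np.sum(net.b2 ** 2))
            norms_lm.append(sq(net_lm))
            norms_br.append(sq(net_br))
        assert np.median(norms_br) < np.median(norms_lm)

    def test_bit_identical_under_fixed_seed(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 5))
        nets = []
        for _ in range(2):
            net = init_ann(3, np.random.default_rng(42), n_inputs=3, n_outputs=5)
            train_br(net, X, Y, max_epochs=20, seed=42)
            nets.append(net)
        np.testing.assert_array_equal(nets[0].W1, nets[1].W1)
        np.testing.assert_array_equal(nets[0].W2, nets[1].W2)


class TestNeuronSweep:
    def test_reduced_sweep_reproducible(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 4))
        Xt = rng.normal(size=(5, 3))
        Yt = rng.normal(size=(5, 4))
        a = neuron_sweep(X, Y, Xt, Yt, trainer="br", runs=2, h_values=(1, 2),
                         seed=77, max_epochs=10)
        b = neuron_sweep(X, Y, Xt, Yt, trainer="br", runs=2, h_values=(1, 2),
                         seed=77, max_epochs=10)
        np.testing.assert_array_equal(a.mean_summed_rmsep, b.mean_summed_rmsep)
        assert a.best_run.summed_rmsep == b.best_run.summed_rmsep
        assert a.best_run.summed_rmsep == min(
            r.summed_rmsep for h in a.runs for r in a.runs[h])

    def test_unknown_trainer_and_empty_test_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            neuron_sweep(X, Y, X[:0], Y[:0], trainer="br", runs=1, h_values=(1,))
        with pytest.raises(ValueError):
            neuron_sweep(X, Y, X, Y, trainer="adam", runs=1, h_values=(1,))


class TestPlsDirect:
    def test_full_rank_matches_multiresponse_ols_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        B = rng.normal(size=(3, 6))
        Y = X @ B + 2.0 + 0.1 * rng.normal(size=(30, 6))
        model = pls_direct_fit(X, Y, n_lv=3)
        A = np.column_stack([np.ones(30), X])
        coef = np.linalg.lstsq(A, Y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ coef, atol=1e-6)

    def test_mean_inputs_predict_mean_profile(self, rng):
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 5))
        model = pls_direct_fit(X, Y, n_lv=2)
        np.testing.assert_allclose(model.predict(X.mean(axis=0)[None, :])[0],
                                   Y.mean(axis=0), atol=1e-10)

    def test_n_lv_capped_by_input_dimension(self, rng):
        with pytest.raises(ValueError):
            pls_direct_fit(rng.normal(size=(10, 3)), rng.normal(size=(10, 5)),
                           n_lv=4)

    def test_linear_profiles_fit_but_hill_nonlinearity_fails(self, rng):
        """The linear baseline handles linear dose-response but cannot track a
        saturating polymer effect at the extremes of the range."""
        hpmc = np.linspace(5, 35, 40)
        X = np.column_stack([np.full(40, 8.0) + 0.01 * rng.normal(size=40),
                             hpmc, np.full(40, 95.7) + rng.normal(size=40)])
        t = np.linspace(0, 1, 10)
        linear = np.outer(hpmc, t)
        m_lin = pls_direct_fit(X, linear, n_lv=3)
        assert np.max(np.abs(m_lin.predict(X) - linear)) < 1e-6
        hill = hpmc ** 7 / (19.0 ** 7 + hpmc ** 7)
        nonlin = np.outer(100 * hill, t)
        m_non = pls_direct_fit(X, nonlin, n_lv=3)
        resid = np.abs(m_non.predict(X) - nonlin).max(axis=1)
        edges = (hpmc < 12) | (hpmc > 30)
        assert resid[edges].max() > 5.0


class TestScaler:
    def test_roundtrip_and_degenerate_feature(self, rng):
        X = np.column_stack([rng.normal(size=10), np.full(10, 3.0)])
        sc = MinMaxScaler().fit(X)
        Xs = sc.transform(X)
        assert Xs[:, 0].min() == -1.0 and Xs[:, 0].max() == 1.0
        np.testing.assert_allclose(Xs[:, 1], -1.0)
        np.testing.assert_allclose(sc.inverse_transform(Xs)[:, 0], X[:, 0],
                                   atol=1e-12)
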