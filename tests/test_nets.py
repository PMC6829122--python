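"""Neural-network mechanics: Xavier initialization, seeded starting weights,
the early-stopping rules, backprop correctness, and learning sanity bounds."""

import numpy as np
import pytest

from gpbench.datatypes import AlignmentError
from gpbench.nets import (
    AnnArchitecture,
    CnnPredictor,
    CnnSettings,
    MlpPredictor,
    TrainingFailedError,
    WeightInit,
    build_train_cnn,
    early_stopping_epoch,
    keras_early_stopping_epoch,
    mlp_layer_shapes,
    one_hot_encode,
    seed_hidden_weights,
    train_ann,
    xavier_init,
)
from gpbench.simulate import make_split_plan, simulate_genotypes, simulate_trait


class TestXavierInit:
    def test_deterministic_bitwise(self):
        a = xavier_init([(100, 20), (20, 1)], seed=5)
        b = xavier_init([(100, 20), (20, 1)], seed=5)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_variance_scaling(self):
        init = xavier_init([(8000, 50)], seed=6)
        target = 2.0 / (8000 + 50)
        assert abs(init.weights[0].var() - target) / target < 0.10

    def test_biases_zero(self):
        init = xavier_init([(30, 10), (10, 1)], seed=7)
        for b in init.biases:
            assert np.all(b == 0)


class TestSeededWeights:
    def _base(self, p=200, H=20, seed=1):
        return xavier_init(mlp_layer_shapes(p, AnnArchitecture((H,))), seed=seed)

    def test_quarter_of_nodes_seeded(self, rng):
        base = self._base()
        out = seed_hidden_weights(base, rng.normal(size=200), fraction=0.25, noise_seed=2)
        assert len(out.seeded_node_indices) == 5  # round(0.25 * 20)
        assert out.provenance.startswith("seeded:")

    def test_fraction_zero_is_noop(self, rng):
        base = self._base()
        out = seed_hidden_weights(base, rng.normal(size=200), fraction=0.0)
        assert out is base

    def test_rescaled_seed_sd_matches_xavier_remainder(self, rng):
        base = self._base()
        scores = rng.exponential(size=200)  # arbitrary scale and sign pattern
        out = seed_hidden_weights(
            base, scores, fraction=0.25, noise_seed=3, center_scores=True
        )
        sd_rest = out.weights[0][:, 5:].std()
        centered = scores - scores.mean()
        seed_vec = centered * (sd_rest / centered.std())
        assert seed_vec.std() == pytest.approx(sd_rest, abs=1e-6)
        # multiplicative noise: seeded column = seed_vec * N(0, sd_rest) draws
        noise = np.random.default_rng(3).normal(0.0, sd_rest, size=200)
        assert np.allclose(out.weights[0][:, 0], seed_vec * noise)

    def test_additive_noise_preserves_sign_structure(self, rng):
        # rescaled seed and noise have equal sd: additive perturbation keeps
        # ~3/4 of the donor signs, while multiplicative noise randomizes them
        base = self._base(p=2000)
        scores = rng.normal(size=2000) * 10
        add = seed_hidden_weights(
            base, scores, fraction=0.25, noise_seed=4, noise_mode="additive"
        )
        mult = seed_hidden_weights(
            base, scores, fraction=0.25, noise_seed=4, noise_mode="multiplicative"
        )
        agree_add = np.mean(np.sign(add.weights[0][:, 0]) == np.sign(scores))
        agree_mult = np.mean(np.sign(mult.weights[0][:, 0]) == np.sign(scores))
        assert agree_add > 0.65
        assert abs(agree_mult - 0.5) < 0.1
        assert agree_add > agree_mult

    def test_unseeded_weights_untouched(self, rng):
        base = self._base()
        out = seed_hidden_weights(base, rng.normal(size=200), noise_seed=5)
        assert np.array_equal(out.weights[0][:, 5:], base.weights[0][:, 5:])
        for wl_out, wl_base in zip(out.weights[1:], base.weights[1:]):
            assert np.array_equal(wl_out, wl_base)
        for bl_out, bl_base in zip(out.biases, base.biases):
            assert np.array_equal(bl_out, bl_base)

    def test_wrong_score_length_raises(self, rng):
        with pytest.raises(AlignmentError):
            seed_hidden_weights(self._base(), rng.normal(size=17))


class TestEarlyStoppingRules:
    def test_flat_from_epoch_five_stops_at_twenty(self):
        # 10-epoch burn-in + 10 consecutive flat epochs
        trace = [1.0, 0.8, 0.6, 0.5, 0.4] + [0.4] * 30
        assert early_stopping_epoch(trace) == 20

    def test_steadily_improving_never_stops(self):
        trace = [1.0 * 0.99**t for t in range(60)]  # 1% drop each epoch
        assert early_stopping_epoch(trace) is None

    def test_flat_run_interrupted_resets_counter(self):
        trace = [1.0] * 18 + [0.5] + [0.5] * 30
        # epochs 11..18 flat (8), epoch 19 jumps, flat resumes at 20
        assert early_stopping_epoch(trace) == 29

    def test_keras_rule_counts_non_improving_epochs(self):
        trace = [1.0, 0.9, 0.8] + [0.85] * 12
        assert keras_early_stopping_epoch(trace, patience=10) == 13
        assert keras_early_stopping_epoch([1.0 * 0.9**t for t in range(30)]) is None


class TestBackprop:
    def test_mlp_gradients_match_numerical(self, rng):
        arch = AnnArchitecture(
            (6, 5), activation="sigmoid", dropout_rate=0.0, l2_penalty=0.01
        )
        X = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        model = MlpPredictor(arch, xavier_init([(4, 6), (6, 5), (5, 1)], seed=1))
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for pi, p in enumerate(model.params):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = p[ix]
                p[ix] = old + eps
                up, _ = model.loss_and_grads(X, y)
                p[ix] = old - eps
                dn, _ = model.loss_and_grads(X, y)
                p[ix] = old
                num = (up - dn) / (2 * eps)
                assert abs(num - grads[pi][ix]) < 1e-5 * (abs(num) + 1.0)

    def test_cnn_gradients_match_numerical(self, rng):
        s = CnnSettings(
            n_filters=3, kernel_width=3, pool_width=2, dense_width=4,
            dropout_rate=0.0, bn_momentum=1.0,
        )
        model = CnnPredictor(10, s, seed=2)
        Xoh = one_hot_encode(rng.integers(-1, 2, size=(6, 10)))
        y = rng.normal(size=6)
        _, grads = model.loss_and_grads(Xoh, y, train=True)
        eps = 1e-6
        for pi, p in enumerate(model.params):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = p[ix]
                p[ix] = old + eps
                up, _ = model.loss_and_grads(Xoh, y, train=True)
                p[ix] = old - eps
                dn, _ = model.loss_and_grads(Xoh, y, train=True)
                p[ix] = old
                num = (up - dn) / (2 * eps)
                assert abs(num - grads[pi][ix]) < 2e-3 * (abs(num) + 1e-2)


class TestTrainAnn:
    def _split_data(self, n=300, p=60, h2=0.9, seed=30):
        G = simulate_genotypes(n, p, seed=seed)
        pheno, _ = simulate_trait(G, n_qtl=8, h2=h2, seed=seed + 1)
        y = pheno.values[:, 0]
        plan = make_split_plan(
            n, n_replicates=1, validation_fraction_of_train=0.2, seed=seed + 2
        )
        sp = plan.replicates[0]
        X = G.X()
        return (X[sp.train], y[sp.train], X[sp.validation], y[sp.validation],
                X[sp.test], y[sp.test])

    def test_seed_determinism(self):
        Xt, yt, Xv, yv, _, _ = self._split_data()
        arch = AnnArchitecture((10,), learning_rate=1e-2)
        m1, t1 = train_ann(Xt, yt, Xv, yv, arch, max_epochs=40, seed=9)
        m2, t2 = train_ann(Xt, yt, Xv, yv, arch, max_epochs=40, seed=9)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        assert t1.val_mse == t2.val_mse

    def test_degenerate_network_triggers_restart(self):
        Xt, yt, Xv, yv, _, _ = self._split_data()
        shapes = mlp_layer_shapes(Xt.shape[1], AnnArchitecture((10,)))
        dead = WeightInit(
            weights=[np.zeros(s) for s in shapes],
            biases=[np.zeros(s[1]) for s in shapes],
        )
        arch = AnnArchitecture((10,), activation="relu", learning_rate=1e-12)
        # learning rate ~0: the all-zero net cannot escape, every restart
        # re-uses the same dead init -> training failure
        with pytest.raises(TrainingFailedError):
            train_ann(
                Xt, yt, Xv, yv, arch, init=dead, max_epochs=25, seed=10,
                reinit=lambda attempt: dead, max_restarts=2,
            )
        # with real restarts (fresh Xavier draws) training recovers
        model, trace = train_ann(
            Xt, yt, Xv, yv, arch2 := AnnArchitecture((10,), learning_rate=1e-2),
            init=dead, max_epochs=60, seed=10,
        )
        assert trace.restarts_used >= 1
        assert np.var(model.predict(Xv)) > 0

    def test_l2_penalty_shrinks_weights_and_predictions(self):
        Xt, yt, Xv, yv, Xte, _ = self._split_data()
        norms, spreads = [], []
        for l2 in (0.0, 0.05, 5.0):
            arch = AnnArchitecture(
                (10,), learning_rate=1e-2, dropout_rate=0.0, l2_penalty=l2
            )
            m, _ = train_ann(Xt, yt, Xv, yv, arch, max_epochs=80, seed=11)
            norms.append(sum(np.linalg.norm(w) for w in m.weights))
            spreads.append(np.var(m.predict(Xte)))
        assert norms[0] > norms[1] > norms[2]
        assert spreads[0] > spreads[2]

    def test_learns_additive_trait_after_selection_scale(self):
        # n=800, p=100 (as if after selection), h2=0.8
        rs = []
        for seed in range(10):
            G = simulate_genotypes(800, 100, seed=600 + seed)
            pheno, _ = simulate_trait(G, n_qtl=15, h2=0.8, seed=700 + seed)
            y = pheno.values[:, 0]
            plan = make_split_plan(
                800, n_replicates=1, validation_fraction_of_train=0.2, seed=seed
            )
            sp = plan.replicates[0]
            X = G.X()
            arch = AnnArchitecture((50,), activation="sigmoid", learning_rate=1e-2)
            m, _ = train_ann(
                X[sp.train], y[sp.train], X[sp.validation], y[sp.validation],
                arch, max_epochs=200, seed=seed,
            )
            rs.append(np.corrcoef(m.predict(X[sp.test]), y[sp.test])[0, 1])
        assert np.median(rs) > 0.5


class TestCnn:
    def test_one_hot_encoding_sums_to_marker_count(self, toy_dataset):
        G, _, _ = toy_dataset
        oh = one_hot_encode(G)
        assert oh.shape == (G.n_lines, G.n_markers, 3)
        assert np.all(oh.sum(axis=2) == 1.0)
        assert np.all(oh.sum(axis=(1, 2)) == G.n_markers)

    def test_output_one_value_per_line(self, toy_dataset):
        G, pheno, _ = toy_dataset
        model = CnnPredictor(G.n_markers, CnnSettings(n_filters=4, dense_width=8), seed=1)
        pred = model.predict(G)
        assert pred.shape == (G.n_lines,)

    def test_learns_additive_trait(self):
        rs = []
        for seed in range(10):
            G = simulate_genotypes(1000, 200, seed=800 + seed)
            pheno, _ = simulate_trait(G, n_qtl=20, h2=0.8, seed=900 + seed)
            y = pheno.values[:, 0]
            plan = make_split_plan(
                1000, n_replicates=1, validation_fraction_of_train=0.2, seed=seed
            )
            sp = plan.replicates[0]
            model, _ = build_train_cnn(
                G.subset_lines(sp.train), y[sp.train],
                G.subset_lines(sp.validation), y[sp.validation],
                CnnSettings(max_epochs=120), seed=seed,
            )
            pred = model.predict(G.subset_lines(sp.test))
            rs.append(np.corrcoef(pred, y[sp.test])[0, 1])
        assert np.median(rs) > 0.3
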