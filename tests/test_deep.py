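import dataclasses

import numpy as np
import pytest
from sklearn.decomposition import PCA

import mokl
from mokl.deep import (DeepMKLClassifier, DeepMKLConfig, DeepMKLNet,
                       build_network, fit_kpca, train_deep_mkl,
                       transform_kpca, tune_deep_mkl)
from mokl.kernels import gaussian_kernel, linear_kernel

SMALL = dict(hidden=[8, 8, 4], head_hidden=8, dropout=0.1, lr=1e-3,
             batch_size=16, epochs=30, seed=0, sigma=0.05, n_components=5)


class TestKpca:
    def test_linear_kernel_equals_pca_scores(self, rng):
        X = rng.normal(size=(25, 6))
        Xc = X - X.mean(axis=0)
        emb = fit_kpca(linear_kernel(Xc), 3, train_X=Xc)
        pca_scores = PCA(n_components=3).fit_transform(Xc)
        # equality up to per-component sign
        for l in range(3):
            assert (np.allclose(emb.scores[:, l], pca_scores[:, l], atol=1e-8)
                    or np.allclose(emb.scores[:, l], -pca_scores[:, l],
                                   atol=1e-8))

    def test_full_spectrum_reconstructs_centered_kernel(self, rng):
        X = rng.normal(size=(15, 4))
        K = gaussian_kernel(X, 0.3)
        from sklearn.preprocessing import KernelCenterer
        Kc = KernelCenterer().fit_transform(K.values)
        n_pos = int(np.sum(np.linalg.eigvalsh(Kc) > 1e-10))
        emb = fit_kpca(K, n_pos, train_X=X)
        Z = emb.scores
        np.testing.assert_allclose(Z @ Z.T, Kc, atol=1e-6)

    def test_duplicate_samples_identical_embeddings(self, rng):
        X = rng.normal(size=(10, 3))
        X[4] = X[2]
        emb = fit_kpca(gaussian_kernel(X, 0.2), 3, train_X=X)
        np.testing.assert_allclose(emb.scores[4], emb.scores[2], atol=1e-8)

    def test_transform_training_rows_consistency(self, rng):
        X = rng.normal(size=(20, 5))
        emb = fit_kpca(gaussian_kernel(X, 0.1), 6, train_X=X)
        np.testing.assert_allclose(transform_kpca(emb, X), emb.scores,
                                   atol=1e-8)

    def test_transform_matches_explicit_centering_algebra(self, rng):
        Xtr = rng.normal(size=(18, 4))
        Xte = rng.normal(size=(5, 4))
        sigma = 0.25
        emb = fit_kpca(gaussian_kernel(Xtr, sigma), 4, train_X=Xtr)
        got = transform_kpca(emb, Xte)
        # independent derivation from the centered-kernel algebra:
        # k~(x, x_i) = k(x, x_i) - mean_r k(x, x_r) - mean_r k(x_r, x_i)
        #              + grand_mean(K_train)
        from mokl.kernels import cross_kernel, KernelParams
        Ktr = gaussian_kernel(Xtr, sigma).values
        Kc = cross_kernel(Xte, Xtr, KernelParams("gaussian_rbf", sigma)).values
        Kt = (Kc - Kc.mean(axis=1, keepdims=True)
              - Ktr.mean(axis=0)[None, :] + Ktr.mean())
        expected = Kt @ (emb.eigvecs / np.sqrt(emb.eigvals))
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        X = rng.normal(size=(8, 2))
        with pytest.raises(ValueError):
            fit_kpca(gaussian_kernel(X, 0.3), 8)


class TestArchitecture:
    def test_single_omic_concat_is_plain_mlp(self):
        cfg = DeepMKLConfig(**SMALL)
        net = DeepMKLNet(1, [5], 2, cfg)
        x = np.random.default_rng(0).normal(size=(6, 5))
        out = net.forward([x], train=False)
        assert out.shape == (6, 2)

    def test_concat_fused_width(self):
        cfg = DeepMKLConfig(**{**SMALL, "hidden": [4, 4, 2]})
        net = DeepMKLNet(3, [5, 5, 5], 2, cfg)
        assert net.head_block.layers[0].W.shape[0] == 6   # 3 omics x width 2

    def test_parameter_count_closed_form(self):
        hidden, head, M, d, n_cls = [200, 200, 100], 64, 3, 120, 2
        cfg = DeepMKLConfig(hidden=hidden, head_hidden=head, fusion="concat",
                            dropout=0.5, epochs=1)
        net = DeepMKLNet(M, [d] * M, n_cls, cfg)

        def block_params(n_in, n_out):
            return (n_in + 1) * n_out + 2 * n_out     # dense + batchnorm

        expected = M * (block_params(d, 200) + block_params(200, 200)
                        + block_params(200, 100))
        expected += block_params(100 * M, head)       # head block on concat
        expected += (head + 1) * n_cls                # output layer
        assert net.n_params == expected

    def test_weighted_sum_adds_m_scalars(self):
        base = DeepMKLConfig(**{**SMALL, "fusion": "sum"})
        ws = DeepMKLConfig(**{**SMALL, "fusion": "weighted_sum"})
        n1 = DeepMKLNet(3, [5, 5, 5], 2, base).n_params
        n2 = DeepMKLNet(3, [5, 5, 5], 2, ws).n_params
        assert n2 - n1 == 3

    def test_cross_modal_layer_count(self):
        cfg = DeepMKLConfig(**{**SMALL, "hidden": [8, 8, 4, 4],
                               "cross_modal": True})
        net = DeepMKLNet(3, [5, 5, 5], 2, cfg)
        # one dedicated cross layer per ordered pair: M*(M-1) = 6
        n_cross = sum(1 for row in net.cross for b in row if b is not None)
        assert n_cross == 6

    def test_wrong_depth_rejected(self):
        with pytest.raises(ValueError, match="layers"):
            DeepMKLConfig(**{**SMALL, "hidden": [8, 8], "cross_modal": False})


class TestFusionModes:
    def test_sum_equals_weighted_sum_with_unit_scalars(self, rng):
        xs = [rng.normal(size=(7, 5)) for _ in range(3)]
        cfg_sum = DeepMKLConfig(**{**SMALL, "fusion": "sum"})
        cfg_ws = DeepMKLConfig(**{**SMALL, "fusion": "weighted_sum"})
        net_s = DeepMKLNet(3, [5, 5, 5], 2, cfg_sum)
        net_w = DeepMKLNet(3, [5, 5, 5], 2, cfg_ws)
        # same seed -> identical per-omic weights; scalars initialized at 1
        np.testing.assert_allclose(net_w.fusion_scalars, 1.0)
        np.testing.assert_allclose(net_s.forward(xs, train=False),
                                   net_w.forward(xs, train=False), atol=1e-12)

    def test_permuted_omics_with_permuted_head(self, rng):
        # concat fusion: permuting the omics and permuting the head's input
        # blocks accordingly leaves the logits unchanged
        xs = [rng.normal(size=(6, 4)), rng.normal(size=(6, 5)),
              rng.normal(size=(6, 3))]
        cfg = DeepMKLConfig(**{**SMALL, "fusion": "concat", "dropout": 0.0})
        net = DeepMKLNet(3, [4, 5, 3], 2, cfg)
        ref = net.forward(xs, train=False)
        perm = [2, 0, 1]
        net_p = DeepMKLNet(3, [xs[i].shape[1] for i in perm], 2, cfg)
        # copy subnet parameters in permuted order
        for mp, m in enumerate(perm):
            for bp, b in zip(net_p.subnets[mp], net.subnets[m]):
                for pp, p in zip(bp.params, b.params):
                    pp[...] = p
                bn_p, bn = bp.layers[3], b.layers[3]
                bn_p.running_mean[...] = bn.running_mean
                bn_p.running_var[...] = bn.running_var
        # permute the head dense rows by omic block (width 4 each)
        w = SMALL["hidden"][-1]
        rows = np.arange(3 * w).reshape(3, w)
        order = np.concatenate([rows[m] for m in perm])
        net_p.head_block.layers[0].W[...] = net.head_block.layers[0].W[order]
        net_p.head_block.layers[0].b[...] = net.head_block.layers[0].b
        for lay_p, lay in [(net_p.head_block.layers[3], net.head_block.layers[3])]:
            for pp, p in zip(lay_p.params, lay.params):
                pp[...] = p
            lay_p.running_mean[...] = lay.running_mean
            lay_p.running_var[...] = lay.running_var
        net_p.head_out.W[...] = net.head_out.W
        net_p.head_out.b[...] = net.head_out.b
        got = net_p.forward([xs[i] for i in perm], train=False)
        np.testing.assert_allclose(got, ref, atol=1e-10)


class TestTraining:
    def _separable(self, rng, n=60, d=4):
        y = np.repeat([0, 1], n // 2)
        xs = [rng.normal(size=(n, d)) + 3.0 * y[:, None],
              rng.normal(size=(n, d))]
        return xs, y

    def test_separable_embeddings_high_accuracy(self, rng):
        xs, y = self._separable(rng)
        cfg = DeepMKLConfig(**{**SMALL, "epochs": 100})
        model = train_deep_mkl(xs, y, cfg)
        pred = np.argmax(model.net.forward(xs, train=False), axis=1)
        assert np.mean(pred == y) >= 0.95
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_zero_epochs_untrained(self, rng):
        xs, y = self._separable(rng)
        cfg = DeepMKLConfig(**{**SMALL, "epochs": 0})
        model = train_deep_mkl(xs, y, cfg)
        assert model.loss_trace == []
        assert not model.trained

    def test_same_seed_identical_weights(self, rng):
        xs, y = self._separable(rng, n=40)
        cfg = DeepMKLConfig(**{**SMALL, "epochs": 10})
        m1 = train_deep_mkl(xs, y, cfg)
        m2 = train_deep_mkl(xs, y, cfg)
        for p1, p2 in zip(m1.net.params, m2.net.params):
            np.testing.assert_array_equal(p1, p2)

    def test_eval_forward_batch_size_independent(self, rng):
        xs, y = self._separable(rng, n=40)
        cfg = DeepMKLConfig(**{**SMALL, "epochs": 5})
        model = train_deep_mkl(xs, y, cfg)
        full = model.net.forward(xs, train=False)
        half = np.vstack([model.net.forward([x[:20] for x in xs], train=False),
                          model.net.forward([x[20:] for x in xs], train=False)])
        np.testing.assert_allclose(full, half, atol=1e-12)

    def test_misaligned_embeddings_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            train_deep_mkl([rng.normal(size=(10, 3)),
                            rng.normal(size=(9, 3))],
                           np.zeros(10), DeepMKLConfig(**SMALL))


class TestTuning:
    def test_search_space_of_one(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:80]
        sub = [b.values[:80] for b in blocks]
        base = DeepMKLConfig(**{**SMALL, "epochs": 5})
        cfg = tune_deep_mkl(sub, y, {"sigma": [0.01]}, budget=4, folds=3,
                            seed=0, base=base)
        assert cfg.sigma == 0.01
        assert cfg.n_evaluated == 1

    def test_budget_covers_space_is_exhaustive(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:80]
        sub = [b.values[:80] for b in blocks]
        base = DeepMKLConfig(**{**SMALL, "epochs": 5})
        space = {"sigma": [0.005, 0.05], "n_components": [3, 5]}
        cfg = tune_deep_mkl(sub, y, space, budget=10, folds=3, seed=0,
                            base=base)
        assert cfg.n_evaluated == 4
        # exhaustive oracle: every candidate scored identically by hand
        best = None
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        splits = list(skf.split(np.zeros(len(y)), y))
        for s in space["sigma"]:
            for d in space["n_components"]:
                c = dataclasses.replace(base, sigma=s, n_components=d)
                accs = []
                for tr, va in splits:
                    clf = DeepMKLClassifier(c).fit([X[tr] for X in sub], y[tr])
                    accs.append(np.mean(clf.predict([X[va] for X in sub])
                                        == y[va]))
                score = np.mean(accs)
                if best is None or score > best[0]:
                    best = (score, s, d)
        assert (cfg.sigma, cfg.n_components) == (best[1], best[2])

    def test_fixed_seed_same_sampled_configs(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:80]
        sub = [b.values[:80] for b in blocks]
        base = DeepMKLConfig(**{**SMALL, "epochs": 3})
        space = {"sigma": [0.003, 0.01, 0.03, 0.1], "n_components": [3, 5]}
        c1 = tune_deep_mkl(sub, y, space, budget=3, folds=3, seed=7, base=base)
        c2 = tune_deep_mkl(sub, y, space, budget=3, folds=3, seed=7, base=base)
        assert (c1.sigma, c1.n_components) == (c2.sigma, c2.n_components)

    def test_zero_budget_rejected(self, scenario_a):
        blocks, labels, _ = scenario_a
        with pytest.raises(ValueError, match="budget"):
            tune_deep_mkl([b.values for b in blocks], labels.encoded(),
                          {"sigma": [0.1]}, budget=0)


def test_radial_scenario_deep_beats_linear_concat(scenario_b):
    """Concentric classes: the RBF-embedded deep model must beat a linear
    early-integration SVM, the nonlinearity motivation for kernel fusion."""
    blocks, labels, _ = scenario_b
    y = labels.encoded()
    tr, te = mokl.stratified_split(y, 0.3, 0)
    trb = [b.values[tr] for b in blocks]
    teb = [b.values[te] for b in blocks]
    cfg = DeepMKLConfig(hidden=[32, 32, 16], head_hidden=16,
                        fusion="weighted_sum", dropout=0.3, lr=1e-3,
                        epochs=100, seed=0, sigma=0.05, n_components=8)
    deep_acc = np.mean(DeepMKLClassifier(cfg).fit(trb, y[tr]).predict(teb)
                       == y[te])
    lin = mokl.MKLClassifier("concat", kernel="linear", cost=1.0).fit(trb, y[tr])
    lin_acc = np.mean(lin.predict(teb) == y[te])
    assert deep_acc > lin_acc
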