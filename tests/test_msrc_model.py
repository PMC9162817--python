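"""Architecture construction, forward contracts, oracle equivalence,
parameter counting, and the scikit-learn estimator surface."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from copnet import backend as B
from copnet import net_core as nc
from copnet.msrc_model import (
    BuiltModel,
    ModelSpec,
    SwayNetClassifier,
    build_model,
    count_parameters,
)


def conv_layers_of(model):
    convs = []

    def walk(layer, in_main):
        if isinstance(layer, B.Conv1dSame):
            convs.append((layer, in_main))
        elif isinstance(layer, B.Sequential):
            for sub in layer.layers:
                walk(sub, in_main)
        elif isinstance(layer, B.ResidualBlock):
            walk(layer.main, in_main)
            if layer.shortcut is not None:
                walk(layer.shortcut, False)
        elif isinstance(layer, B.ParallelConcat):
            for br in layer.branches:
                walk(br, in_main)

    walk(model.net, True)
    return convs


class TestBuildTopology:
    def test_msrc_has_twelve_main_convs_in_three_branches(self):
        model = build_model(ModelSpec(), seed=0)
        convs = conv_layers_of(model)
        main = [c for c, in_main in convs if in_main]
        projections = [c for c, in_main in convs if not in_main]
        assert len(main) == 12  # 3 branches x 2 blocks x 2 convs
        assert len(projections) == 3  # one 2->filters projection per branch
        assert sorted({c.k for c in main}) == [3, 10, 20]

    def test_nn_single_hidden_layer_of_1000(self):
        model = build_model(ModelSpec.for_kind("nn"), seed=0)
        dense = [l for l in model.net.layers if isinstance(l, B.Dense)]
        assert [d.n_out for d in dense] == [1000, 3]

    def test_dnn_hidden_stack(self):
        model = build_model(ModelSpec.for_kind("dnn"), seed=0)
        dense = [l for l in model.net.layers if isinstance(l, B.Dense)]
        assert [d.n_out for d in dense] == [1000, 1000, 500, 3]

    def test_dscnn_single_branch_kernel(self):
        model = build_model(ModelSpec.for_kind("dscnn"), seed=0)
        convs = conv_layers_of(model)
        assert {c.k for c, in_main in convs if in_main} == {10}
        assert not any(isinstance(l, B.ParallelConcat) for l in model.net.layers)

    def test_wores_shapes_match_msrc_minus_projections(self):
        msrc = build_model(ModelSpec(), seed=3)
        wores = build_model(ModelSpec.for_kind("wores"), seed=3)
        m_main = [c.W.value.shape for c, im in conv_layers_of(msrc) if im]
        w_all = [c.W.value.shape for c, _ in conv_layers_of(wores)]
        assert m_main == w_all

    def test_degenerate_pooling_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(ModelSpec(n_in=4, blocks_per_branch=3, pool_size=4), seed=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="transformer")

    def test_spec_dict_roundtrip(self):
        spec = ModelSpec.for_kind("dscnn", filters_per_conv=7)
        assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestForwardContracts:
    @pytest.fixture
    def model(self):
        return build_model(ModelSpec(), seed=0)

    @pytest.fixture
    def batch(self):
        return np.random.default_rng(0).standard_normal((16, 2, 200))

    def test_probability_rows(self, model, batch):
        p = model.forward(batch)
        assert p.shape == (16, 3)
        assert np.all(p > 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, model, batch):
        np.testing.assert_array_equal(model.forward(batch), model.forward(batch))

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((4, 2, 100)))

    def test_features_shape_and_purity(self, model, batch):
        f = model.extract_features(batch)
        assert f.shape == (16, 128)
        dup = np.stack([batch[0], batch[0]])
        fd = model.extract_features(dup)
        np.testing.assert_array_equal(fd[0], fd[1])

    def test_features_ignore_classifier_head(self, model, batch):
        ref = model.extract_features(batch)
        final = model.net.layers[-1]
        keep = final.W.value.copy()
        final.W.value[...] = 0.0
        np.testing.assert_array_equal(model.extract_features(batch), ref)
        final.W.value[...] = keep


class TestOracleEquivalence:
    def test_single_conv_toy_matches_net_core_composition(self):
        """One branch / one block / one filter, hand-set weights: the
        trainable network must reproduce conv -> leaky relu -> maxpool ->
        fc -> softmax composed from the oracle ops."""
        spec = ModelSpec(
            kind="dscnn",
            blocks_per_branch=1,
            convs_per_block=1,
            filters_per_conv=1,
            single_scale_kernel=5,
            fc_hidden=4,
            residual=False,
            n_in=40,
        )
        model = build_model(spec, seed=1)
        rng = np.random.default_rng(42)
        x = rng.standard_normal((1, 2, 40))

        conv = conv_layers_of(model)[0][0]
        fc1, fc2 = [l for l in model.net.layers if isinstance(l, B.Dense)]

        got = model.forward(x)[0]

        w = conv.W.value[0].astype(float)
        pre = (
            nc.conv1d_same(x[0, 0], nc.ConvFilter(w[0])).values
            + nc.conv1d_same(x[0, 1], nc.ConvFilter(w[1])).values
            + float(conv.b.value[0])
        )
        feat = nc.maxpool1d(nc.leaky_relu(pre, spec.leaky_slope), 2).values
        hid = nc.leaky_relu(
            feat @ fc1.W.value.astype(float) + fc1.b.value, spec.leaky_slope
        )
        logits = hid @ fc2.W.value.astype(float) + fc2.b.value
        expected = nc.softmax(logits)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_zeroed_block_reduces_to_activated_shortcut(self):
        """With all conv weights/biases zero, a residual block outputs
        LeakyReLU(projection(x)) — the short-cut path alone."""
        spec = ModelSpec(branch_kernel_sizes=(3,), filters_per_conv=4, n_in=16)
        model = build_model(spec, seed=0)
        block1 = [l for l in model.net.layers if isinstance(l, B.ResidualBlock)][0]
        assert block1.shortcut is not None  # 2 -> 4 channels needs projection
        for conv in block1.main.layers:
            conv.W.value[...] = 0.0
            conv.b.value[...] = 0.0
        x = np.random.default_rng(1).standard_normal((3, 16, 2)).astype(B.DTYPE)
        out = block1.forward(x)
        shortcut_out = block1.shortcut.forward(x)
        np.testing.assert_allclose(
            out,
            np.where(shortcut_out < 0, 0.01 * shortcut_out, shortcut_out),
            atol=1e-7,
        )

    def test_identity_shortcut_block_passes_input_through(self):
        """Second-block residual (matching channels): zero weights give
        LeakyReLU(x) exactly."""
        spec = ModelSpec(branch_kernel_sizes=(3,), filters_per_conv=2, n_in=16)
        model = build_model(spec, seed=0)
        block2 = [l for l in model.net.layers if isinstance(l, B.ResidualBlock)][1]
        assert block2.shortcut is None
        for conv in block2.main.layers:
            conv.W.value[...] = 0.0
            conv.b.value[...] = 0.0
        x = np.random.default_rng(2).standard_normal((2, 8, 2)).astype(B.DTYPE)
        np.testing.assert_allclose(
            block2.forward(x), np.where(x < 0, 0.01 * x, x), atol=1e-7
        )

    def test_same_padding_keeps_length_at_every_conv(self):
        model = build_model(ModelSpec(), seed=0)
        for conv, _ in conv_layers_of(model):
            x = np.random.default_rng(0).standard_normal((2, 50, conv.c_in))
            assert conv.forward(x).shape == (2, 50, conv.c_out)


class TestParameterCount:
    def test_nn_closed_form(self):
        model = build_model(ModelSpec.for_kind("nn"), seed=0)
        # 400*1000 + 1000 hidden, 1000*3 + 3 head
        assert count_parameters(model) == 401_000 + 3_003

    def test_monotone_in_filters(self):
        small = build_model(ModelSpec(filters_per_conv=10), seed=0)
        large = build_model(ModelSpec(filters_per_conv=20), seed=0)
        assert count_parameters(large) > count_parameters(small)

    def test_seed_invariant(self):
        a = build_model(ModelSpec(), seed=0)
        b = build_model(ModelSpec(), seed=99)
        assert count_parameters(a) == count_parameters(b)


class TestCheckpoint:
    def test_save_load_reproduces_forward(self, tmp_path):
        from copnet.msrc_model import load_model, save_model

        model = build_model(ModelSpec(n_in=40, filters_per_conv=3), seed=4)
        x = np.random.default_rng(0).standard_normal((5, 2, 40))
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.spec == model.spec
        np.testing.assert_array_equal(back.forward(x), model.forward(x))


class TestTraining:
    def test_loss_decreases_on_separable_toy_data(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.standard_normal((n, 2, 40))
        y = np.arange(n) % 3
        X *= (0.3 + y[:, None, None]).astype(float)  # scale encodes class
        model = build_model(ModelSpec(n_in=40, filters_per_conv=4), seed=0)
        hist = model.fit_minibatch(X, y, epochs=8, batch_size=8,
                                   learning_rate=1e-3, seed=0)
        assert len(hist) == 8
        assert hist[-1] < hist[0]

    def test_training_reproducible_from_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((24, 2, 40))
        y = np.arange(24) % 3
        outs = []
        for _ in range(2):
            m = build_model(ModelSpec(n_in=40, filters_per_conv=2), seed=5)
            m.fit_minibatch(X, y, epochs=2, batch_size=8, learning_rate=1e-3, seed=9)
            outs.append(m.forward(X))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_zero_learning_rate_is_null_update(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((16, 2, 40))
        y = np.arange(16) % 3
        m = build_model(ModelSpec(n_in=40, filters_per_conv=2), seed=0)
        before = m.forward(X)
        m.fit_minibatch(X, y, epochs=2, batch_size=8, learning_rate=0.0, seed=0)
        np.testing.assert_array_equal(m.forward(X), before)


class TestEstimator:
    @pytest.fixture
    def toy_xy(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((45, 2, 40))
        y = np.repeat(["H", "M", "N"], 15)
        X *= (0.3 + 2.0 * np.arange(45)[:, None, None] // 15).astype(float)
        return X, y

    def test_fit_predict_labels(self, toy_xy):
        X, y = toy_xy
        clf = SwayNetClassifier(
            kind="msrc", n_in=40, filters_per_conv=2, epochs=3,
            learning_rate=1e-3, random_state=0,
        )
        clf.fit(X, y)
        assert list(clf.classes_) == ["H", "M", "N"]
        pred = clf.predict(X)
        assert set(pred) <= set(y)
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(clf.classes_[proba.argmax(axis=1)], pred)

    def test_flattened_input_accepted(self, toy_xy):
        X, y = toy_xy
        clf = SwayNetClassifier(kind="nn", n_in=40, epochs=2, random_state=0)
        clf.fit(X.reshape(len(X), -1), y)
        assert clf.predict(X.reshape(len(X), -1)).shape == (45,)

    def test_transform_returns_hidden_features(self, toy_xy):
        X, y = toy_xy
        clf = SwayNetClassifier(
            kind="dscnn", n_in=40, filters_per_conv=2, fc_hidden=16,
            epochs=2, random_state=0,
        ).fit(X, y)
        assert clf.transform(X).shape == (45, 16)

    def test_clone_and_params_roundtrip(self):
        clf = SwayNetClassifier(kind="wores", epochs=7, filters_per_conv=5)
        other = clone(clf)
        assert other.get_params() == clf.get_params()

    def test_unfitted_raises(self):
        with pytest.raises(NotFittedError):
            SwayNetClassifier().predict(np.zeros((1, 2, 200)))

    def test_refit_same_seed_reproduces(self, toy_xy):
        X, y = toy_xy
        cfg = dict(kind="nn", n_in=40, epochs=2, random_state=3)
        p1 = SwayNetClassifier(**cfg).fit(X, y).predict_proba(X)
        p2 = SwayNetClassifier(**cfg).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)
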