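import math

import numpy as np
import pytest

from dgat.model import (
    DGATClassifier,
    DGATResults,
    EvalReport,
    ModelConfig,
    build_model,
    cross_entropy,
    evaluate,
    loss,
    train,
)
from dgat.montage import DEFeatureTensor, load_montage


def _toy_tensor(rng, montage, n_bands=4, n_per_class=30, n_classes=2, sep=2.0):
    """Linearly separable DE-like features: class shifts one channel group."""
    n = montage.n_channels
    t = n_per_class * n_classes
    values = rng.normal(0, 0.5, (t, n, n_bands))
    labels = np.repeat(np.arange(n_classes), n_per_class)
    for c in range(n_classes):
        values[labels == c, : n // 2, c % n_bands] += sep * (c + 1)
    trial_index = np.arange(t)
    return DEFeatureTensor(
        values=values,
        band_edges=np.array([[4, 8], [8, 13], [13, 30], [30, 45]], float)[:n_bands],
        window_s=4.0,
        montage=montage,
        labels=labels,
        trial_index=trial_index,
    )


class TestBuildModel:
    def test_seed62_five_band_three_class_shapes(self, rng):
        cfg = ModelConfig(n_classes=3, seed=0)
        net = build_model(cfg, load_montage("seed62"), n_bands=5)
        logits = net.forward(rng.normal(size=(2, 62, 5)))
        assert logits.shape == (2, 3)
        assert net.layers[0].params.f_in == 5
        assert net.layers[0].state.w0.shape == (62, 62)

    def test_deap32_binary_shapes(self, rng):
        cfg = ModelConfig(n_classes=2, seed=0)
        net = build_model(cfg, load_montage("deap32"), n_bands=4)
        assert net.forward(rng.normal(size=(3, 32, 4))).shape == (3, 2)

    def test_same_seed_identical_parameters(self):
        cfg = ModelConfig(n_classes=3, seed=42)
        m = load_montage("synth16")
        a = build_model(cfg, m, 4).parameters()
        b = build_model(cfg, m, 4).parameters()
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestLoss:
    def test_uniform_logits_log_c(self):
        logits = np.zeros((10, 4))
        labels = np.arange(10) % 4
        assert loss(logits, labels) == pytest.approx(math.log(4))

    def test_perfect_logits_approach_l2_term(self, rng):
        labels = np.array([0, 1, 2])
        logits = np.full((3, 3), -50.0)
        logits[np.arange(3), labels] = 50.0
        params = [rng.normal(size=(4, 4)), rng.normal(size=7)]
        l2 = 1e-3
        expected = l2 * sum(float(np.sum(p**2)) for p in params)
        assert loss(logits, labels, params, l2) == pytest.approx(expected, abs=1e-12)

    def test_l2_difference_is_exactly_lambda_norm(self, rng):
        logits = rng.normal(size=(6, 3))
        labels = rng.integers(0, 3, 6)
        params = {"w": rng.normal(size=(5, 5))}
        lam = 0.01
        diff = loss(logits, labels, params, lam) - loss(logits, labels, params, 0.0)
        assert diff == pytest.approx(lam * float(np.sum(params["w"] ** 2)))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="labels"):
            cross_entropy(np.zeros((2, 3)), np.array([0, 3]))

    def test_gradient_matches_finite_difference(self, rng):
        logits = rng.normal(size=(5, 4))
        labels = rng.integers(0, 4, 5)
        _, grad = cross_entropy(logits.copy(), labels)
        eps = 1e-6
        for i in range(5):
            for j in range(4):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (cross_entropy(lp, labels)[0] - cross_entropy(lm, labels)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        cfg = ModelConfig(n_classes=2, seed=3, epochs=50, patience=50)
        res = DGATClassifier(t, cfg).fit()
        assert res.evaluate(t).accuracy == 1.0

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        cfg = ModelConfig(n_classes=2, seed=3, epochs=0)
        res = DGATClassifier(t, cfg).fit()
        fresh = build_model(cfg, montage, t.n_bands).parameters()
        for k, v in res.net.parameters().items():
            assert np.array_equal(v, fresh[k])
        assert res.history == []

    def test_seed_reproducibility_end_to_end(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage, n_per_class=15)
        cfg = ModelConfig(n_classes=2, seed=9, epochs=20, dropout=0.2)
        r1 = DGATClassifier(t, cfg).fit()
        r2 = DGATClassifier(t, cfg).fit()
        for k, v in r1.net.parameters().items():
            assert np.array_equal(v, r2.net.parameters()[k])
        assert r1.history == r2.history
        assert np.array_equal(r1.adjacency(), r2.adjacency())

    def test_divergence_aborts_with_diagnostic(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage, n_per_class=10)
        # an absurd learning rate overflows the parameters after one step
        cfg = ModelConfig(n_classes=2, seed=0, epochs=3, lr=1e200, batch_size=8)
        with pytest.raises(RuntimeError, match="diverged"):
            DGATClassifier(t, cfg).fit()


class TestEvaluate:
    def test_confusion_arithmetic(self):
        rep = EvalReport.from_confusion(np.array([[3, 1], [2, 4]]))
        assert rep.accuracy == pytest.approx(0.7)

    def test_all_correct_diagonal(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        res = DGATClassifier(t, ModelConfig(n_classes=2, seed=3, epochs=50, patience=50)).fit()
        rep = res.evaluate(t)
        assert rep.accuracy == 1.0
        assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_empty_set_rejected(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage, n_per_class=5)
        net = build_model(ModelConfig(n_classes=2), montage, t.n_bands)
        with pytest.raises(ValueError, match="empty"):
            evaluate(net, np.zeros((0, 16, 4)), np.zeros(0, dtype=int))

    def test_untrained_balanced_accuracy_near_chance(self, rng):
        """A fresh (near-constant) classifier scores ~1/C on balanced data."""
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage, n_classes=3, n_per_class=60, sep=0.0)
        cfg = ModelConfig(n_classes=3, seed=1, epochs=0)
        rep = DGATClassifier(t, cfg).fit().evaluate(t)
        assert abs(rep.accuracy - 1 / 3) < 0.15


class TestCheckpoint:
    def test_save_load_roundtrip_predictions(self, rng, tmp_path):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        cfg = ModelConfig(n_classes=2, seed=3, epochs=15)
        res = DGATClassifier(t, cfg).fit()
        path = tmp_path / "ckpt.npz"
        res.save(path)
        back = DGATResults.load(path, t)
        assert np.array_equal(back.predict(t), res.predict(t))
        assert np.array_equal(back.adjacency(), res.adjacency())
        assert back.config == cfg

    def test_summary_mentions_structure(self, rng):
        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        res = DGATClassifier(t, ModelConfig(n_classes=2, seed=3, epochs=5)).fit()
        s = res.summary()
        assert "16" in s and "Adam" in s and "beta=0.5" in s

    def test_history_csv(self, rng, tmp_path):
        import pandas as pd

        montage = load_montage("synth16")
        t = _toy_tensor(rng, montage)
        res = DGATClassifier(t, ModelConfig(n_classes=2, seed=3, epochs=5)).fit()
        path = tmp_path / "history.csv"
        res.history_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["epoch", "loss", "accuracy"]
        assert len(df) == len(res.history)
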