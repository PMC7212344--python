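"""QA classifier: construction, augmentation, oversampling, training."""

import numpy as np
import pytest

from segqa import model, qa
from segqa.model import ClassifierConfig


def toy_config(**kw):
    defaults = dict(channel_set=("ct", "prob", "unc"), head="levels3",
                    input_size=16, base_lr=0.05, max_iterations=40,
                    eval_interval=20, seed=0)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


def separable_data(n=90, size=16, seed=0):
    """Three-regime synthetic set: class encoded in channel means."""
    rng = np.random.default_rng(seed)
    x, y = [], []
    for k in range(n):
        cls = k % 3
        base = np.full((3, size, size), 0.15 + 0.3 * cls, dtype=np.float32)
        x.append(base + rng.normal(0, 0.03, base.shape).astype(np.float32))
        y.append(cls)
    x, y = np.asarray(x), np.asarray(y)
    cut1, cut2 = int(n * 0.6), int(n * 0.8)
    mk = lambda sl: {"x": x[sl], "level": y[sl], "dsc_class": y[sl],
                     "dsc": y[sl] / 2.0, "patient_id": np.array(["p"] * len(y[sl]), dtype=object)}
    return {"train": mk(slice(0, cut1)), "val": mk(slice(cut1, cut2)),
            "test": mk(slice(cut2, n))}


class TestBuildModel:
    def test_levels3_softmax_sums_to_one(self):
        m = model.build_model(toy_config())
        x = np.random.default_rng(1).random((4, 3, 16, 16)).astype(np.float32)
        scores = model.predict(m, x)["scores"]
        assert scores.shape == (4, 3)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_dsc101_head_width(self):
        m = model.build_model(toy_config(head="dsc101"))
        x = np.zeros((2, 3, 16, 16), dtype=np.float32)
        assert model.predict(m, x)["scores"].shape == (2, 101)

    def test_single_channel_input_accepted(self):
        m = model.build_model(toy_config(channel_set=("prob",)))
        x = np.zeros((2, 1, 16, 16), dtype=np.float32)
        assert model.predict(m, x)["scores"].shape == (2, 3)

    def test_unknown_backbone_and_head_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            toy_config(backbone="vgg")
        with pytest.raises(ValueError, match="head"):
            toy_config(head="levels5")

    def test_resnet101_not_trainable_here(self):
        with pytest.raises(NotImplementedError, match="resnet101|small_cnn"):
            model.build_model(toy_config(backbone="resnet101"))


class TestAugment:
    def test_identity_when_disabled(self):
        x = np.random.default_rng(2).random((3, 16, 16)).astype(np.float32)
        out = model.augment(x, np.random.default_rng(0), flip_lr=False,
                            random_crop=False, rotation_range_deg=0.0)
        np.testing.assert_array_equal(out, x)

    def test_flip_is_involution(self):
        x = np.random.default_rng(3).random((2, 8, 8)).astype(np.float32)
        # seed chosen so the flip branch fires (rng.random() < 0.5)
        seed = next(s for s in range(20)
                    if np.random.default_rng(s).random() < 0.5)
        once = model.augment(x, np.random.default_rng(seed), flip_lr=True,
                             random_crop=False, rotation_range_deg=0.0)
        twice = model.augment(once, np.random.default_rng(seed), flip_lr=True,
                              random_crop=False, rotation_range_deg=0.0)
        np.testing.assert_array_equal(twice, x)

    def test_preserves_shape_and_channels(self):
        x = np.random.default_rng(4).random((3, 24, 24)).astype(np.float32)
        out = model.augment(x, np.random.default_rng(1))
        assert out.shape == x.shape

    def test_deterministic_under_fixed_generator_state(self):
        x = np.random.default_rng(5).random((3, 24, 24)).astype(np.float32)
        a = model.augment(x, np.random.default_rng(9))
        b = model.augment(x, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestOversampleMinority:
    def test_balances_to_majority(self):
        labels = [0] * 100 + [1] * 50 + [2] * 10
        out = model.oversample_minority(list(range(160)), labels, seed=0)
        out_labels = np.array(labels, dtype=object)[np.array(out)]
        counts = {c: int((out_labels == c).sum()) for c in (0, 1, 2)}
        assert counts == {0: 100, 1: 100, 2: 100}
        # all originals retained
        assert set(range(160)) <= set(out)

    def test_already_balanced_unchanged(self):
        labels = [0, 1, 2] * 5
        out = model.oversample_minority(list(range(15)), labels, seed=0)
        assert sorted(out) == list(range(15))

    def test_single_class_unchanged(self):
        out = model.oversample_minority([10, 11, 12], [1, 1, 1], seed=0)
        assert out == [10, 11, 12]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            model.oversample_minority([], [])


class TestTrain:
    def test_initial_loss_is_uniform_softmax_cross_entropy(self):
        data = separable_data()
        m = model.build_model(toy_config(max_iterations=1, oversample=False))
        m = model.train(m, data)
        assert m.training_history[0]["loss"] == pytest.approx(np.log(3), abs=1e-4)

    def test_learns_separable_regimes(self):
        data = separable_data()
        cfg = toy_config(max_iterations=150, eval_interval=25,
                         rotation_range_deg=0.0, random_crop=False)
        m = model.train(model.build_model(cfg), data)
        pred = model.predict(m, data["train"]["x"])
        train_acc = (pred["hard"] == data["train"]["level"]).mean()
        assert train_acc > 0.95

    def test_fixed_seed_reproducible_history(self):
        data = separable_data()
        cfg = toy_config(max_iterations=30)
        h1 = model.train(model.build_model(cfg), data).training_history
        h2 = model.train(model.build_model(cfg), data).training_history
        assert [e["loss"] for e in h1] == [e["loss"] for e in h2]

    def test_empty_split_rejected(self):
        data = separable_data()
        data["val"] = {k: v[:0] for k, v in data["val"].items()}
        with pytest.raises(ValueError, match="nonempty"):
            model.train(model.build_model(toy_config()), data)


class TestPredict:
    def test_argmax_and_tie_rule(self):
        m = model.build_model(toy_config())
        # untrained head is all-zero -> every class ties -> argmax = class 0
        x = np.random.default_rng(6).random((5, 3, 16, 16)).astype(np.float32)
        assert (model.predict(m, x)["hard"] == 0).all()

    def test_dsc101_inverse_discretization(self):
        m = model.build_model(toy_config(head="dsc101"))
        x = np.zeros((3, 3, 16, 16), dtype=np.float32)
        out = model.predict(m, x)
        np.testing.assert_allclose(out["pred_dsc"], out["hard"] / 100.0)

    def test_channel_mismatch_named(self):
        m = model.build_model(toy_config(channel_set=("ct", "prob")))
        with pytest.raises(ValueError, match="prob"):
            model.predict(m, np.zeros((2, 3, 16, 16), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path):
        data = separable_data()
        m = model.train(model.build_model(toy_config(max_iterations=10)), data)
        m.save(tmp_path / "ckpt.npz")
        back = model.TrainedQAModel.load(tmp_path / "ckpt.npz")
        x = data["test"]["x"]
        np.testing.assert_allclose(model.predict(back, x)["scores"],
                                   model.predict(m, x)["scores"], atol=1e-6)
        assert back.config.channel_set == m.config.channel_set
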