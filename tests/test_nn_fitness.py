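"""Fitness-engine tests: model assembly, freezing semantics, separability
learning, seeded determinism, divergence survival, losses/optimizers on a
gradient-checked stack, and the two-stage cascade routing."""

import numpy as np
import pytest

from sparrowtune.codec import LOSSES, OPTIMIZERS, TrainingConfig
from sparrowtune.fitness import (
    BACKBONE_WIDTHS,
    BackboneSpec,
    TransferImageClassifier,
    build_model,
    cascade_predict,
    evaluate_fitness,
)
from sparrowtune.fixtures import FixtureSpec, generate_image_set
from sparrowtune.nn import Conv2D, Dense, GlobalAvgPool, MaxPool2, NeuralNetwork, ReLU
from sparrowtune.nn.losses import LOSS_FUNCTIONS, chain_through_softmax, softmax
from sparrowtune.pipeline import split_dataset


def _cfg(**kw):
    base = dict(
        loss="categorical_crossentropy",
        batch_size=8,
        dropout=0.0,
        tl_learn_ratio=100,
        optimizer="adam",
        scaler="minmax",
    )
    base.update(kw)
    return TrainingConfig(**base)


class TestBuildModel:
    def test_softmax_rows_normalized(self, rng):
        model = build_model("surrogate-tiny", _cfg(), n_classes=4, rng=rng)
        x = rng.uniform(0, 1, (5, 128, 128, 3))
        probs = model.predict_proba(x)
        assert probs.shape == (5, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_full_ratio_everything_trainable(self, rng):
        model = build_model("surrogate-tiny", _cfg(tl_learn_ratio=100), 3, rng=rng)
        assert model.n_trainable_params == model.n_params

    def test_minimal_ratio_trains_top_block_only(self, rng):
        model = build_model("surrogate-tiny", _cfg(tl_learn_ratio=1), 3, rng=rng)
        convs = [l for l in model.layers if isinstance(l, Conv2D)]
        assert [c.trainable for c in convs] == [False, False, True]

    def test_zero_ratio_freezes_backbone(self, rng):
        model = build_model("surrogate-tiny", _cfg(tl_learn_ratio=0), 3, rng=rng)
        convs = [l for l in model.layers if isinstance(l, Conv2D)]
        assert not any(c.trainable for c in convs)
        head = model.layers[-1]
        assert head.trainable

    def test_freezing_monotone_in_ratio(self, rng):
        counts = [
            build_model("VGG16", _cfg(tl_learn_ratio=r), 3,
                        rng=np.random.default_rng(0)).n_trainable_params
            for r in (0, 1, 20, 40, 60, 80, 100)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_unknown_backbone_lists_valid_names(self):
        with pytest.raises(ValueError, match="surrogate-tiny"):
            build_model("ResNet50", _cfg(), 3)

    def test_all_named_backbones_construct_and_run(self, rng):
        x = rng.uniform(0, 1, (2, 32, 32, 3))
        for name in BACKBONE_WIDTHS:
            model = build_model(name, _cfg(), 4, rng=np.random.default_rng(1))
            assert model.predict_proba(x).shape == (2, 4)

    def test_pretrained_request_warns(self):
        with pytest.warns(UserWarning, match="random initialisation"):
            build_model(BackboneSpec("VGG16", pretrained_init=True), _cfg(), 3)


class TestGradients:
    """Finite-difference check of the backward pass through the full stack."""

    @pytest.mark.parametrize("loss", sorted(LOSS_FUNCTIONS))
    def test_loss_gradients_match_finite_differences(self, loss, rng):
        y = np.eye(3)[rng.integers(0, 3, 6)]
        z = rng.standard_normal((6, 3))
        p = softmax(z)
        value, dp = LOSS_FUNCTIONS[loss](y, p)
        dz = chain_through_softmax(p, dp)
        eps = 1e-6
        for i in range(6):
            for j in range(3):
                zp = z.copy()
                zp[i, j] += eps
                vp, _ = LOSS_FUNCTIONS[loss](y, softmax(zp))
                zm = z.copy()
                zm[i, j] -= eps
                vm, _ = LOSS_FUNCTIONS[loss](y, softmax(zm))
                num = (vp - vm) / (2 * eps)
                assert num == pytest.approx(dz[i, j], abs=1e-4)

    def test_conv_stack_gradient_check(self, rng):
        layers = [Conv2D(3, 4, rng), ReLU(), MaxPool2(), GlobalAvgPool(),
                  Dense(4, 2, rng)]
        net = NeuralNetwork(layers, "categorical_crossentropy", "sgd", seed=0)
        x = rng.uniform(0, 1, (3, 8, 8, 3))
        y = np.eye(2)[[0, 1, 0]]

        def loss_at(Wflat):
            layers[0].params["W"] = Wflat.reshape(layers[0].params["W"].shape)
            p = softmax(net._forward_logits(x, False))
            v, _ = LOSS_FUNCTIONS["categorical_crossentropy"](y, p)
            return v

        W0 = layers[0].params["W"].copy()
        p = softmax(net._forward_logits(x, False))
        _, dp = LOSS_FUNCTIONS["categorical_crossentropy"](y, p)
        grad = chain_through_softmax(p, dp)
        for layer in reversed(layers):
            grad = layer.backward(grad)
        analytic = layers[0].grads["W"].ravel().copy()
        flat = W0.ravel().copy()
        idx = rng.choice(flat.size, 10, replace=False)
        eps = 1e-6
        for k in idx:
            fp = flat.copy(); fp[k] += eps
            fm = flat.copy(); fm[k] -= eps
            num = (loss_at(fp) - loss_at(fm)) / (2 * eps)
            assert num == pytest.approx(analytic[k], abs=1e-5)
        layers[0].params["W"] = W0


class TestTraining:
    def test_separable_blobs_high_accuracy(self):
        """On strongly separable 2-class fixtures a few epochs reach the
        accuracy a linear probe would (near-perfect)."""
        data = generate_image_set(
            FixtureSpec({"lo": 25, "hi": 25}, image_size=16,
                        signal_strength=1.0, noise_sd=4.0, seed=2)
        )
        X, y = data.as_arrays()
        clf = TransferImageClassifier(epochs=5, batch_size=8, random_state=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_overfits_single_batch(self, rng):
        X = rng.uniform(0, 255, (8, 16, 16, 3))
        y = np.array([0, 1] * 4)
        clf = TransferImageClassifier(
            epochs=50, batch_size=8, random_state=1, scaler="standard"
        )
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_seeded_determinism(self, three_class_set):
        X, y = three_class_set.as_arrays()
        a = TransferImageClassifier(epochs=2, random_state=3).fit(X, y)
        b = TransferImageClassifier(epochs=2, random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    @pytest.mark.parametrize("loss", LOSSES)
    def test_every_loss_trains(self, loss, three_class_set):
        X, y = three_class_set.as_arrays()
        clf = TransferImageClassifier(loss=loss, epochs=1, random_state=0)
        clf.fit(X[:24], y[:24])
        assert clf.epochs_run_ == 1 and not clf.diverged_

    @pytest.mark.parametrize("optimizer", OPTIMIZERS)
    def test_every_optimizer_trains(self, optimizer, three_class_set):
        X, y = three_class_set.as_arrays()
        clf = TransferImageClassifier(optimizer=optimizer, epochs=1, random_state=0)
        clf.fit(X[:24], y[:24])
        assert clf.epochs_run_ == 1


@pytest.fixture(scope="module")
def splits(three_class_set):
    return split_dataset(three_class_set, 0.8, seed=0)


@pytest.fixture(scope="module")
def stage_models():
    ct = generate_image_set(
        FixtureSpec.four_class(counts=(12, 12, 12, 12), image_size=16, seed=7)
    )
    histo = generate_image_set(
        FixtureSpec.five_class(counts=(10, 10, 10, 10, 10), image_size=16, seed=8)
    )
    Xc, yc = ct.as_arrays()
    Xh, yh = histo.as_arrays()
    ct_clf = TransferImageClassifier(epochs=6, batch_size=8, random_state=0)
    ct_clf.fit(Xc, np.array(ct.class_names)[yc])
    h_clf = TransferImageClassifier(epochs=6, batch_size=8, random_state=0)
    h_clf.fit(Xh, np.array(histo.class_names)[yh])
    return ct, histo, ct_clf, h_clf


class TestEvaluateFitness:

    def test_holdout_fitness_scores_validation(self, splits):
        train, val, test = splits
        res = evaluate_fitness("surrogate-tiny", _cfg(), train, val,
                               epochs=3, seed=0)
        assert 0.0 <= res.score <= 1.0
        assert res.score == res.metric_report.accuracy
        assert res.evaluation_mode == "holdout"
        assert res.epochs_run == 3

    def test_whole_dataset_mode_recorded(self, splits):
        train, val, _ = splits
        res = evaluate_fitness("surrogate-tiny", _cfg(), train, val, epochs=1,
                               seed=0, evaluation_mode="whole-dataset")
        assert res.evaluation_mode == "whole-dataset"

    def test_divergence_yields_zero_not_crash(self, splits, monkeypatch):
        """A non-finite training loss must surface as score 0 with the
        ``diverged`` flag, never as an exception the optimizer would see."""
        train, val, _ = splits
        from sparrowtune.nn.network import DivergenceError, NeuralNetwork

        def exploding_fit(self, *args, **kwargs):
            raise DivergenceError("non-finite loss")

        monkeypatch.setattr(NeuralNetwork, "fit", exploding_fit)
        res = evaluate_fitness("surrogate-tiny", _cfg(), train, val, epochs=1, seed=0)
        assert res.score == 0.0
        assert res.diverged is True
        assert res.metric_report is None

    def test_same_seed_same_score(self, splits):
        train, val, _ = splits
        a = evaluate_fitness("surrogate-tiny", _cfg(), train, val, epochs=2, seed=5)
        b = evaluate_fitness("surrogate-tiny", _cfg(), train, val, epochs=2, seed=5)
        assert a.score == b.score

    def test_bad_epochs_rejected(self, splits):
        train, val, _ = splits
        with pytest.raises(ValueError):
            evaluate_fitness("surrogate-tiny", _cfg(), train, val, epochs=0)


class TestCascade:
    def test_normal_routes_without_grade(self, stage_models):
        ct, _, ct_clf, h_clf = stage_models
        normals = [im for im, lab in zip(ct.images, ct.labels) if lab == "Normal"]
        for im in normals:
            rec = cascade_predict(ct_clf, h_clf, im)
            if rec["stage1"] == "Normal":
                assert rec["grade"] is None
                assert rec["note"] == "no further grading"
                return
        pytest.fail("no Normal prediction produced")

    def test_tumor_with_slide_gets_grade(self, stage_models):
        ct, histo, ct_clf, h_clf = stage_models
        tumors = [im for im, lab in zip(ct.images, ct.labels) if lab == "Tumor"]
        graded = False
        for im in tumors:
            rec = cascade_predict(ct_clf, h_clf, im, histo.images[0])
            if rec["stage1"] == "Tumor":
                assert rec["grade"] in histo.class_names
                graded = True
        assert graded

    def test_tumor_without_slide_is_pending(self, stage_models):
        ct, _, ct_clf, h_clf = stage_models
        tumors = [im for im, lab in zip(ct.images, ct.labels) if lab == "Tumor"]
        for im in tumors:
            rec = cascade_predict(ct_clf, h_clf, im)
            if rec["stage1"] == "Tumor":
                assert rec["pending"] is True
                assert rec["note"] == "grading pending"
                return
        pytest.fail("no Tumor prediction produced")

    def test_cascade_accuracy_near_stage_product(self, stage_models):
        """Empirical composition bound: joint accuracy of the two stages is
        at least the product of the standalone accuracies minus 0.05."""
        ct, histo, ct_clf, h_clf = stage_models
        Xc, yc = ct.as_arrays()
        Xh, yh = histo.as_arrays()
        ct_names = np.array(ct.class_names)
        h_names = np.array(histo.class_names)
        acc_ct = (ct_clf.predict(Xc) == ct_names[yc]).mean()
        acc_h = (h_clf.predict(Xh) == h_names[yh]).mean()
        joint_hits = 0
        n = 0
        for im_ct, lab_ct in zip(ct.images, ct.labels):
            for im_h, lab_h in zip(histo.images[:5], histo.labels[:5]):
                rec = cascade_predict(ct_clf, h_clf, im_ct, im_h)
                stage1_ok = rec["stage1"] == lab_ct
                if lab_ct == "Tumor":
                    ok = stage1_ok and rec["grade"] == lab_h
                else:
                    ok = stage1_ok
                joint_hits += ok
                n += 1
        joint = joint_hits / n
        # non-Tumor rows only need stage 1, so the product is a lower bound
        assert joint >= acc_ct * acc_h - 0.05
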