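import numpy as np
import pytest

from fluorograde.annotate import CropRecord
from fluorograde.errors import ConfigurationError
from fluorograde.metrics import MetricsReport, TaskSpec
from fluorograde.models import (
    AugmentationSpec,
    DESK_SPECS,
    ModelSpec,
    FULL_SPECS,
    augment,
    build_model,
    finetune,
    load_model,
    records_to_arrays,
    save_model,
    select_fold,
    train,
)


def tiny_spec(**kw):
    base = dict(
        family="classifier_cnn", input_shape=(16, 16, 2), base_filters=2,
        init="xavier_uniform", loss="binary_cross_entropy", lr=1e-3,
        epochs=3, batch_size=16, seed=0,
    )
    base.update(kw)
    return ModelSpec(**base)


class TestBuildModel:
    def test_identical_specs_give_identical_weights(self):
        a, b = build_model(tiny_spec()), build_model(tiny_spec())
        assert a.n_params() == b.n_params()
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        c = build_model(tiny_spec(seed=1))
        assert any(
            not np.array_equal(wa, wc)
            for wa, wc in zip(a.get_weights(), c.get_weights())
        )

    def test_deeper_unet_has_strictly_more_parameters(self):
        shallow = build_model(
            ModelSpec("unet_4c3e", (64, 64, 2), base_filters=4, out_channels=3)
        )
        deep = build_model(
            ModelSpec("unet_6c5e", (64, 64, 2), base_filters=4, out_channels=3)
        )
        assert deep.n_params() > shallow.n_params()

    def test_classifier_requires_two_channels(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("classifier_cnn", (64, 64, 3))

    def test_input_divisibility_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("unet_6c5e", (48, 48, 2))

    def test_unet_forward_shapes(self):
        m = build_model(ModelSpec("unet_4c3e", (32, 32, 2), base_filters=2, out_channels=3))
        out = m.predict(np.zeros((2, 32, 32, 2)))
        assert out.shape == (2, 32, 32, 3)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0)  # softmax head

    def test_published_hyperparameter_registry(self):
        epi = FULL_SPECS["epithelial_unet"]
        assert (epi.loss, epi.lr, epi.epochs, epi.batch_size) == ("dice", 0.001, 30, 32)
        cls = FULL_SPECS["classifier"]
        assert (cls.loss, cls.lr, cls.epochs) == ("binary_cross_entropy", 0.0001, 20)
        seg = FULL_SPECS["cancer_unet"]
        assert (seg.loss, seg.lr, seg.epochs) == (
            "sparse_categorical_cross_entropy", 0.02, 20,
        )


def make_crop_record(rng, label=1, size=8):
    seg = rng.integers(0, 3, (size, size))
    return CropRecord(
        box=(0, size, 0, size),
        draq5_crop=rng.normal(size=(size, size)),
        eosin_crop=rng.normal(size=(size, size)),
        core_id="c0",
        patient_id="p0",
        raw_label=label,
        task_labels={TaskSpec.HIGH_VS_HEALTHY: 1, TaskSpec.CANCER_SEG: seg},
    )


class TestAugment:
    def test_default_schedule_produces_3500_crops(self, rng):
        crops = [make_crop_record(rng, size=2)]
        spec = AugmentationSpec(seed=0)
        assert spec.total == 3500
        assert spec.n_flip == 1000 and spec.n_rot == 1500
        out = augment(crops, spec)
        assert len(out) == 3500

    def test_flip_is_an_involution(self, rng):
        rec = make_crop_record(rng)
        one = AugmentationSpec(n_flip=1, n_rot=0, n_noise=0, n_blur_noise=0, seed=0)
        once = augment([rec], one)[0]
        twice = augment([once], one)[0]
        np.testing.assert_array_equal(twice.draq5_crop, rec.draq5_crop)
        np.testing.assert_array_equal(
            twice.task_labels[TaskSpec.CANCER_SEG], rec.task_labels[TaskSpec.CANCER_SEG]
        )

    def test_geometric_transforms_move_mask_with_channels(self, rng):
        rec = make_crop_record(rng)
        spec = AugmentationSpec(n_flip=0, n_rot=30, n_noise=0, n_blur_noise=0, seed=1)
        for out in augment([rec], spec):
            # mask of the rotation equals rotation of the mask: the rotated
            # channel/mask pair stays pixel-aligned
            k = next(
                k for k in (1, 2, 3)
                if np.array_equal(out.draq5_crop, np.rot90(rec.draq5_crop, k))
            )
            np.testing.assert_array_equal(
                out.task_labels[TaskSpec.CANCER_SEG],
                np.rot90(rec.task_labels[TaskSpec.CANCER_SEG], k),
            )

    def test_noise_and_blur_never_touch_the_mask(self, rng):
        rec = make_crop_record(rng)
        spec = AugmentationSpec(n_flip=0, n_rot=0, n_noise=5, n_blur_noise=5, seed=2)
        for out in augment([rec], spec):
            np.testing.assert_array_equal(
                out.task_labels[TaskSpec.CANCER_SEG], rec.task_labels[TaskSpec.CANCER_SEG]
            )
            assert not np.array_equal(out.draq5_crop, rec.draq5_crop)

    def test_sampled_parameters_stay_in_range(self, rng):
        """Noise variance ~ U(0, 0.5) and blur sigma ~ U(0, 5): the realized
        per-crop noise variance stays within the attainable band."""
        rec = make_crop_record(rng, size=32)
        spec = AugmentationSpec(n_flip=0, n_rot=0, n_noise=300, n_blur_noise=0, seed=3)
        variances = [
            np.var(out.draq5_crop - rec.draq5_crop) for out in augment([rec], spec)
        ]
        assert min(variances) >= 0.0
        assert max(variances) <= 0.5 * 1.3  # sampling slack at 32x32


class TestTrain:
    def test_selected_epoch_is_validation_argmin(self, rng):
        n = 64
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 1, (n, 16, 16, 2))
        x[y == 1, :, :, 0] += 1.5
        model = build_model(tiny_spec(epochs=5))
        model, hist = train(model, (x[:48], y[:48]), (x[48:], y[48:]), tiny_spec(epochs=5))
        assert hist.selected_epoch == int(np.argmin(hist.val_loss))
        assert len(hist.val_loss) == 5

    def test_separable_problem_is_learned(self, rng):
        """Class = elevated mean DRAQ5 intensity: a tiny CNN must solve it."""
        n = 96
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 1, (n, 16, 16, 2))
        x[y == 1, :, :, 0] += 1.5
        spec = tiny_spec(epochs=12, base_filters=4, lr=3e-3)
        model = build_model(spec)
        model, hist = train(model, (x[:72], y[:72]), (x[72:], y[72:]), spec)
        assert hist.train_loss[-1] < hist.train_loss[0]
        preds = (model.predict(x[:72]).ravel() >= 0.5).astype(int)
        assert (preds == y[:72]).mean() >= 0.9

    def test_restores_best_epoch_weights(self, rng):
        n = 48
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 1, (n, 16, 16, 2))
        x[y == 1, :, :, 0] += 1.0
        spec = tiny_spec(epochs=4)
        model = build_model(spec)
        model, hist = train(model, (x[:32], y[:32]), (x[32:], y[32:]), spec)
        # the restored weights must reproduce the recorded minimum val loss
        loss = _val_loss(model, x[32:], y[32:])
        assert loss == pytest.approx(min(hist.val_loss), abs=1e-9)

    def test_empty_sets_rejected(self, rng):
        model = build_model(tiny_spec())
        with pytest.raises(ConfigurationError):
            train(model, (np.zeros((0, 16, 16, 2)), np.zeros(0)), (np.zeros((1, 16, 16, 2)), np.zeros(1)), tiny_spec())


def _val_loss(model, x, y):
    from fluorograde.nn import bce_with_logits

    z = model.forward(x)
    return bce_with_logits(z, y)[0]


class TestFinetune:
    def test_zero_epochs_is_a_noop(self, rng):
        model = build_model(tiny_spec())
        before = model.get_weights()
        x = rng.normal(size=(8, 16, 16, 2))
        y = rng.integers(0, 2, 8)
        model, hist = finetune(model, (x, y), (x, y), lr=1e-4, epochs=0)
        for wa, wb in zip(before, model.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_default_classifier_finetune_lr(self):
        from fluorograde.models import FINETUNE_DEFAULTS

        assert FINETUNE_DEFAULTS["classifier"] == (2e-5, 20)
        assert FINETUNE_DEFAULTS["segmentation"] == (0.01, 10)

    def test_adapts_to_shifted_distribution(self, rng):
        """Pretrain on distribution A, finetune on shifted B: the validation
        loss on B after finetuning is not worse (median over 5 seeds)."""
        deltas = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            spec = tiny_spec(epochs=4, seed=seed)

            def dataset(shift, n=48):
                y = r.integers(0, 2, n)
                x = r.normal(0, 1, (n, 16, 16, 2))
                x[y == 1, :, :, 0] += shift
                return x, y

            xa, ya = dataset(+1.5)
            xb, yb = dataset(-1.5)
            model = build_model(spec)
            model, _ = train(model, (xa, ya), (xa, ya), spec)
            before = _val_loss(model, xb, yb)
            model, _ = finetune(model, (xb[:32], yb[:32]), (xb[32:], yb[32:]), lr=1e-3, epochs=4, base_spec=spec)
            after = _val_loss(model, xb, yb)
            deltas.append(after - before)
        assert np.median(deltas) <= 0.0


class TestSelectFold:
    def test_max_kappa_with_earliest_tie(self):
        reports = [
            MetricsReport(TaskSpec.HIGH_VS_HEALTHY, n=1, kappa=k)
            for k in (0.4, 0.7, 0.1, 0.7, 0.2)
        ]
        assert select_fold(reports, "max_kappa") == 1

    def test_max_dice_sum(self):
        dice_sets = [
            {"background": 0.9, "healthy": 0.2, "cancer": 0.4},
            {"background": 0.8, "healthy": 0.5, "cancer": 0.3},
            {"background": 0.7, "healthy": 0.3, "cancer": 0.4},
            {"background": 0.9, "healthy": 0.5, "cancer": 0.5},
        ]
        reports = [
            MetricsReport(TaskSpec.CANCER_SEG, n=1, dice_per_class=d) for d in dice_sets
        ]
        assert select_fold(reports, "max_dice_sum") == 3

    def test_single_fold(self):
        assert select_fold([MetricsReport(TaskSpec.HIGH_VS_LOW, n=1, kappa=0.1)]) == 0


class TestCheckpointRoundtrip:
    def test_save_and_load_reproduce_predictions(self, tmp_path, rng):
        spec = tiny_spec()
        model = build_model(spec)
        x = rng.normal(size=(4, 16, 16, 2))
        save_model(model, spec, tmp_path / "m.npz")
        loaded, spec2 = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(model.predict(x), loaded.predict(x))
        assert spec2.family == spec.family
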