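"""Cascade: model head, augmentation group, CV plans, training contracts,
and the two-stage gating rule."""

import numpy as np
import pytest

from dermaflim import cascade
from dermaflim.cascade import (
    ArchConfig,
    AugmentConfig,
    CascadePrediction,
    TrainConfig,
    augment,
    build_model,
    cascade_predict,
    class_weight_vector,
    make_cv_plan,
    train,
)
from dermaflim.nn import Dense, Dropout, GlobalAvgPool, Sequential
from dermaflim.patches import MPTPatch


def make_patch(rng, subject="S01", has_cells=True, diagnosis="AD", value=None):
    px = rng.random((200, 200, 3)).astype(np.float32) if value is None else np.full(
        (200, 200, 3), value, dtype=np.float32
    )
    return MPTPatch(pixels=px, subject_id=subject, has_cells=has_cells, diagnosis=diagnosis)


def constant_model(logit: float) -> Sequential:
    """A gate stub: channel-independent constant logit, one dropout layer."""
    net = Sequential([GlobalAvgPool(), Dense(3, 1), Dropout(0.0)])
    dense = net.layers[1]
    dense.W[...] = 0.0
    dense.b[...] = logit
    return net


class TestBuildModel:
    def test_output_is_probability(self, rng):
        model = build_model(ArchConfig(seed=0))
        x = rng.random((2, 3, 200, 200)).astype(np.float32)
        p = model.predict_proba(x)
        assert p.shape == (2,)
        assert np.all((p >= 0) & (p <= 1))

    def test_deterministic_without_dropout(self, rng):
        model = build_model(ArchConfig(seed=0, dropout_rate=0.0))
        x = rng.random((1, 3, 200, 200)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    @pytest.mark.parametrize("blocks,growth", [(2, 4), (4, 8)])
    def test_head_is_single_unit_regardless_of_backbone(self, blocks, growth, rng):
        model = build_model(ArchConfig(seed=1, n_blocks=blocks, growth=growth))
        x = rng.random((3, 3, 200, 200)).astype(np.float32)
        assert model.forward(x).shape == (3,)

    def test_invalid_arch_rejected(self):
        with pytest.raises(ValueError):
            build_model(ArchConfig(n_blocks=0))
        with pytest.raises(ValueError):
            build_model(ArchConfig(dropout_rate=1.5))


class TestAugment:
    def test_horizontal_reflection_is_involution(self, rng):
        patch = make_patch(rng)
        once = cascade._dihedral(patch.pixels, 0, True)
        twice = cascade._dihedral(once, 0, True)
        np.testing.assert_array_equal(twice, patch.pixels)

    def test_dihedral_variants_are_distinct(self, rng):
        patch = make_patch(rng)
        variants = augment(patch, AugmentConfig(scales=()))
        assert len(variants) == 8
        flat = [v.pixels.tobytes() for v in variants]
        assert len(set(flat)) == 8

    def test_labels_and_shape_preserved(self, rng):
        patch = make_patch(rng, diagnosis="healthy", has_cells=False)
        for v in augment(patch):
            assert v.pixels.shape == (200, 200, 3)
            assert v.diagnosis == "healthy" and v.has_cells is False

    def test_scale_one_is_identity(self, rng):
        px = rng.random((200, 200, 3)).astype(np.float32)
        np.testing.assert_array_equal(cascade._scale_pixels(px, 1.0), px)

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            cascade._scale_pixels(rng.random((200, 200, 3)), 0.0)

    def test_scaling_preserves_shape(self, rng):
        px = rng.random((200, 200, 3)).astype(np.float32)
        for f in (0.8, 1.25):
            assert cascade._scale_pixels(px, f).shape == (200, 200, 3)


class TestCVPlan:
    def test_ten_subjects_give_ten_runs(self):
        subjects = [f"S{i:02d}" for i in range(1, 11)]
        plan = make_cv_plan(subjects, seed=4)
        assert len(plan.runs) == 10
        assert sorted(r.test_subject for r in plan.runs) == subjects
        for r in plan.runs:
            assert len(r.train_subjects) == 8

    def test_three_subjects_minimum(self):
        plan = make_cv_plan(["a", "b", "c"], seed=0)
        for r in plan.runs:
            assert len(r.train_subjects) == 1

    def test_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(["a", "b"], seed=0)

    def test_no_leakage_over_many_random_subject_sets(self):
        """Disjointness invariants hold for 100 random subject sets."""
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(3, 15))
            subjects = [f"P{trial}_{i}" for i in range(n)]
            plan = make_cv_plan(subjects, seed=int(rng.integers(2**31 - 1)))
            plan.validate()
            for r in plan.runs:
                assert r.test_subject not in r.train_subjects
                assert r.test_subject != r.tune_subject
                assert r.tune_subject not in r.train_subjects
                assert set(r.train_subjects) | {r.test_subject, r.tune_subject} == set(
                    subjects
                )


class TestClassWeights:
    def test_inverse_frequency_balances_class_sums(self):
        """With 3:1 imbalance, the summed weight per class is equal, so each
        class contributes equally to the objective."""
        y = np.array([1, 1, 1, 0], dtype=np.float32)
        w = class_weight_vector(y, "balanced")
        assert w[y > 0.5].sum() == pytest.approx(w[y <= 0.5].sum())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weight_vector(np.ones(4, dtype=np.float32), "balanced")


def small_train_config(**kw):
    defaults = dict(
        hyper_grid={"dropout_rate": [0.2], "learning_rate": [0.01], "momentum": [0.9]},
        epochs_max=12,
        patience=3,
        min_epochs=1,
        batch_size=8,
        augment_train=False,
        seed=0,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


def blob_patches(rng, n_per_class=8):
    """Separable classes: bright patches with cells vs dark without."""
    out = []
    for i in range(n_per_class):
        out.append(make_patch(rng, subject=f"A{i%2}", has_cells=True, value=0.8))
        out.append(make_patch(rng, subject=f"A{i%2}", has_cells=False, value=0.2))
    for p in out:
        p.pixels += rng.normal(0, 0.02, p.pixels.shape).astype(np.float32)
        np.clip(p.pixels, 0, 1, out=p.pixels)
    return out


class TestTrain:
    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        patches = blob_patches(rng)
        tune = [make_patch(rng, subject="T", has_cells=True, value=0.8),
                make_patch(rng, subject="T", has_cells=False, value=0.2)]
        arch = ArchConfig(seed=2, n_blocks=1, growth=2, fc_units=4, input_pool=8)
        model = build_model(arch)
        model, history, best = train(model, patches, tune, small_train_config(), task="cells")
        X = np.stack([p.pixels.transpose(2, 0, 1) for p in patches])
        y = np.array([p.has_cells for p in patches])
        acc = ((model.predict_proba(X) >= 0.5) == y).mean()
        assert acc == 1.0

    def test_subject_overlap_rejected(self, rng):
        patches = blob_patches(rng)
        with pytest.raises(ValueError, match="overlap"):
            train(build_model(ArchConfig(seed=0, n_blocks=1, growth=2)), patches,
                  patches[:2], small_train_config(), task="cells")

    def test_single_class_training_set_rejected(self, rng):
        patches = [make_patch(rng, subject="A", has_cells=True) for _ in range(4)]
        tune = [make_patch(rng, subject="T", has_cells=False)]
        with pytest.raises(ValueError, match="both classes"):
            train(build_model(ArchConfig(seed=0, n_blocks=1, growth=2)), patches,
                  tune, small_train_config(), task="cells")

    def test_early_stopping_halts_on_stalled_tune_loss(self, rng):
        """With a tuning set the model cannot improve on (constant inputs,
        mixed labels), training stops after patience epochs."""
        patches = blob_patches(rng)
        tune = [make_patch(rng, subject="T", has_cells=True, value=0.5),
                make_patch(rng, subject="T", has_cells=False, value=0.5)]
        cfg = small_train_config(epochs_max=40, patience=3, min_epochs=1)
        arch = ArchConfig(seed=2, n_blocks=1, growth=2, fc_units=4, input_pool=8)
        _, history, _ = train(build_model(arch), patches, tune, cfg, task="cells")
        assert history.epoch.max() + 1 < 40

    def test_grid_search_returns_best_point(self, rng):
        patches = blob_patches(rng)
        tune = [make_patch(rng, subject="T", has_cells=True, value=0.8),
                make_patch(rng, subject="T", has_cells=False, value=0.2)]
        cfg = small_train_config(
            hyper_grid={"dropout_rate": [0.2], "learning_rate": [0.01, 1e-7],
                        "momentum": [0.9]},
            epochs_max=8, patience=2,
        )
        arch = ArchConfig(seed=2, n_blocks=1, growth=2, fc_units=4, input_pool=8)
        _, history, best = train(build_model(arch), patches, tune, cfg, task="cells")
        assert best["learning_rate"] == 0.01  # the learnable rate wins
        assert set(history.grid_index) == {0, 1}


class TestCascadePredict:
    def test_gate_blocks_stage_two(self, rng):
        patch = make_patch(rng)
        pred = cascade_predict(constant_model(-2.0), constant_model(5.0), patch, seed=1)
        assert pred.decision == "no_cells"
        assert pred.p_ad is None and pred.u_ad is None

    def test_gate_passes_to_ad(self, rng):
        patch = make_patch(rng)
        pred = cascade_predict(constant_model(3.0), constant_model(2.0), patch, seed=1)
        assert pred.decision == "AD"
        assert pred.p_ad == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-6)

    def test_gate_passes_to_healthy(self, rng):
        patch = make_patch(rng)
        pred = cascade_predict(constant_model(3.0), constant_model(-2.0), patch, seed=1)
        assert pred.decision == "healthy"

    def test_probability_exactly_at_threshold_is_positive(self, rng):
        patch = make_patch(rng)
        pred = cascade_predict(constant_model(0.0), constant_model(1.0), patch,
                               threshold=0.5, seed=1)
        assert pred.p_cells == 0.5
        assert pred.decision == "AD"  # >= rule: the tie gates through

    def test_invalid_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            cascade_predict(constant_model(0.0), constant_model(0.0),
                            make_patch(rng), threshold=1.5)
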