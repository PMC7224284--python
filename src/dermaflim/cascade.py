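"""Two-stage classification cascade for MPT patches.

Stage 1 (the cell gate) decides whether a 200x200x3 patch shows living
epidermal cells; only gated-positive patches reach stage 2, which diagnoses
atopic dermatitis. Both stages share the same small densely-connected
convolutional backbone with a dropout-regularised fully-connected head and a
single sigmoid output, trained with class-weighted binary cross-entropy,
SGD with momentum, label-preserving augmentation of the training set only,
and grid search with early stopping on a held-out tuning subject.

Model selection and evaluation are subject-wise: leave-one-subject-out
cross-validation with a second subject held out for tuning, so no subject
ever contributes to both training and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.transform import rescale

from .nn import (
    SGD,
    Adam,
    AvgPool2D,
    Dense,
    DenseBlock,
    Dropout,
    GlobalAvgPool,
    MaxPool2D,
    ReLU,
    Sequential,
    bce_with_logits,
)
from .patches import PATCH_SIDE, MPTPatch

log = logging.getLogger(__name__)

__all__ = [
    "ArchConfig",
    "AugmentConfig",
    "TrainConfig",
    "CVPlan",
    "CVRun",
    "CascadePrediction",
    "build_model",
    "augment",
    "random_augment",
    "make_cv_plan",
    "train",
    "cascade_predict",
    "run_loocv",
]


@dataclass(frozen=True)
class ArchConfig:
    """Backbone geometry. The default is a small 4-block densely-connected
    CNN trainable from random initialization on one CPU."""

    in_channels: int = 3
    input_pool: int = 4  # 200 px -> 50 px working resolution
    n_blocks: int = 4
    growth: int = 8
    fc_units: int = 16
    dropout_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1 or self.growth < 1 or self.fc_units < 1:
            raise ValueError("architecture sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


def build_model(config: ArchConfig | None = None) -> Sequential:
    """Assemble the patch classifier: densely-connected conv blocks with
    max-pool transitions, global average pooling, and a dropout + single
    sigmoid-unit head. Output is one probability per patch."""
    cfg = config or ArchConfig()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x11AD]))
    layers: list = [AvgPool2D(cfg.input_pool)]
    c = cfg.in_channels
    for b in range(cfg.n_blocks):
        layers.append(DenseBlock(c, cfg.growth, rng=rng))
        c += cfg.growth
        if b < cfg.n_blocks - 1:
            layers.append(MaxPool2D(2))
    layers += [
        GlobalAvgPool(),
        Dense(c, cfg.fc_units, rng=rng),
        ReLU(),
        Dropout(cfg.dropout_rate),
        Dense(cfg.fc_units, 1, rng=rng),
    ]
    return Sequential(layers)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Label-preserving augmentation switches: the 8 dihedral variants
    (rotations by multiples of 90 deg, horizontal/vertical reflection) plus
    re-scalings with center crop/pad back to the patch size."""

    rotation: bool = True
    h_reflect: bool = True
    v_reflect: bool = True
    scales: tuple = (0.9, 1.1)
    # optional per-sample constant channel offsets emulating
    # subject-to-subject lifetime/gain variation (off by default: it slows
    # convergence more than it helps generalization at this training scale)
    channel_jitter: float = 0.0


def _scale_pixels(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Zoom by ``factor`` and center-crop / reflect-pad back to the input
    side, so the output shape matches the input shape."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return pixels
    side_in = pixels.shape[0]
    out = rescale(
        pixels, factor, channel_axis=-1, anti_aliasing=factor < 1.0, mode="reflect"
    ).astype(np.float32)
    side = out.shape[0]
    if side >= side_in:
        o = (side - side_in) // 2
        out = out[o : o + side_in, o : o + side_in]
    else:
        pad = side_in - side
        lo, hi = pad // 2, pad - pad // 2
        out = np.pad(out, ((lo, hi), (lo, hi), (0, 0)), mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _dihedral(pixels: np.ndarray, k: int, reflect: bool) -> np.ndarray:
    out = np.rot90(pixels, k, axes=(0, 1))
    if reflect:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment(patch: MPTPatch, config: AugmentConfig | None = None) -> list:
    """Enumerate the label-preserving variants of a patch.

    Rotations and the two reflections generate the dihedral group of the
    square (8 variants, identity included); each configured scale adds one
    more. Labels and provenance are copied unchanged.
    """
    cfg = config or AugmentConfig()
    ks = range(4) if cfg.rotation else (0,)
    reflects = [False] + ([True] if (cfg.h_reflect or cfg.v_reflect) else [])
    pixel_variants = [_dihedral(patch.pixels, k, r) for k in ks for r in reflects]
    pixel_variants += [_scale_pixels(patch.pixels, s) for s in cfg.scales]
    return [
        MPTPatch(
            pixels=px,
            subject_id=patch.subject_id,
            stack_id=patch.stack_id,
            frame_index=patch.frame_index,
            depth_um=patch.depth_um,
            patch_index=patch.patch_index,
            has_cells=patch.has_cells,
            diagnosis=patch.diagnosis,
            extra=dict(patch.extra, augmented=True),
        )
        for px in pixel_variants
    ]


def random_augment(pixels: np.ndarray, config: AugmentConfig, rng) -> np.ndarray:
    """Draw one random variant — used on the fly during training so the
    full augmented set never needs to be materialised."""
    k = int(rng.integers(4)) if config.rotation else 0
    reflect = (config.h_reflect or config.v_reflect) and bool(rng.integers(2))
    out = _dihedral(pixels, k, reflect)
    if config.scales and rng.random() < 0.2:
        out = _scale_pixels(out, float(rng.choice(config.scales)))
    if config.channel_jitter > 0:
        shift = rng.normal(0.0, config.channel_jitter, size=(1, 1, out.shape[2]))
        out = np.clip(out + shift.astype(np.float32), 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVRun:
    test_subject: str
    tune_subject: str
    train_subjects: tuple


@dataclass
class CVPlan:
    runs: list

    def validate(self) -> None:
        tests = [r.test_subject for r in self.runs]
        if len(set(tests)) != len(tests):
            raise ValueError("each subject must be tested exactly once")
        for r in self.runs:
            train = set(r.train_subjects)
            if not train:
                raise ValueError("train set must be non-empty")
            if r.test_subject in train or r.test_subject == r.tune_subject:
                raise ValueError(f"test subject {r.test_subject} leaks into train/tune")
            if r.tune_subject in train:
                raise ValueError(f"tune subject {r.tune_subject} leaks into train")


def make_cv_plan(subject_ids, seed: int = 0, diagnoses: dict | None = None) -> CVPlan:
    """Subject-wise leave-one-out plan: every subject is the test subject of
    exactly one run, a second (seeded) subject is held out for tuning, and
    the remainder train.

    When per-subject ``diagnoses`` are given, the tune draw avoids subjects
    whose removal would leave the training set without one of the classes
    (only relevant for very small cohorts)."""
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise ValueError("subject ids must be unique")
    if len(subjects) < 3:
        raise ValueError("subject-wise train/tune/test needs at least 3 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    runs = []
    for test in subjects:
        rest = [s for s in subjects if s != test]
        candidates = rest
        if diagnoses is not None:
            counts: dict = {}
            for s in rest:
                counts[diagnoses[s]] = counts.get(diagnoses[s], 0) + 1
            if len(counts) > 1:
                safe = [s for s in rest if counts[diagnoses[s]] > 1]
                candidates = safe or rest
        tune = candidates[int(rng.integers(len(candidates)))]
        train = tuple(s for s in rest if s != tune)
        runs.append(CVRun(test_subject=test, tune_subject=tune, train_subjects=train))
    plan = CVPlan(runs=runs)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyper-grid and optimisation settings shared by both stages."""

    hyper_grid: dict = field(
        default_factory=lambda: {
            "dropout_rate": [0.2, 0.5],
            "learning_rate": [1e-3],
            "momentum": [0.9],
        }
    )
    epochs_max: int = 60
    patience: int = 12
    min_epochs: int = 25  # early stopping arms only after this burn-in
    min_delta: float = 1e-3  # tune-loss improvement that resets patience
    optimizer: str = "adam"  # 'adam' (robust from random init) or 'sgd'
    max_restarts: int = 2  # extra random re-initializations on non-convergence
    restart_threshold: float = 0.45  # tune loss above this counts as unconverged
    batch_size: int = 16
    class_weights: str | None = "balanced"
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    augment_train: bool = True
    augment_mode: str = "materialize"  # 'materialize' (full set once) or 'online'
    seed: int = 0

    def validate(self) -> None:
        if not self.hyper_grid or any(len(v) == 0 for v in self.hyper_grid.values()):
            raise ValueError("hyper grid must be non-empty")
        if self.patience >= self.epochs_max:
            raise ValueError("patience must be smaller than epochs_max")

    def grid_points(self) -> list:
        keys = list(self.hyper_grid)
        points = [{}]
        for k in keys:
            points = [dict(p, **{k: v}) for p in points for v in self.hyper_grid[k]]
        return points


def patch_labels(patches, task: str) -> np.ndarray:
    if task == "cells":
        labels = [p.has_cells for p in patches]
    elif task == "ad":
        labels = [None if p.diagnosis is None else p.diagnosis == "AD" for p in patches]
    else:
        raise ValueError(f"unknown task {task!r}")
    if any(l is None for l in labels):
        raise ValueError(f"missing labels for task {task!r}")
    return np.array(labels, dtype=np.float32)


def _to_nchw(patches) -> np.ndarray:
    return np.stack([p.pixels.transpose(2, 0, 1) for p in patches]).astype(np.float32)


def class_weight_vector(y: np.ndarray, mode: str | None) -> np.ndarray:
    """Inverse-frequency weights: each class contributes the same summed
    weight, balancing the gradient of the objective."""
    if mode is None:
        return np.ones_like(y)
    n = y.size
    n_pos = float(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set must contain both classes")
    w_pos, w_neg = n / (2.0 * n_pos), n / (2.0 * n_neg)
    return np.where(y > 0.5, w_pos, w_neg).astype(np.float64)


def train(model: Sequential, train_patches, tune_patches, config: TrainConfig,
          task: str = "cells"):
    """Grid-searched, early-stopped training of one cascade stage.

    For every hyper-grid point the model is reset to its initial weights,
    trained with class-weighted BCE and on-the-fly augmentation of the
    training patches only, and early-stopped on the tuning loss; the
    grid-best weights (by tuning loss) are loaded into ``model``.

    Train and tune patches must come from disjoint subjects.
    """
    config.validate()
    train_subj = {p.subject_id for p in train_patches}
    tune_subj = {p.subject_id for p in tune_patches}
    if train_subj & tune_subj:
        raise ValueError(f"subject overlap between train and tune: {train_subj & tune_subj}")

    X = _to_nchw(train_patches)
    y = patch_labels(train_patches, task)
    Xt = _to_nchw(tune_patches)
    yt = patch_labels(tune_patches, task)
    w = class_weight_vector(y, config.class_weights)
    single_class_tune = not (0 < yt.sum() < yt.size)
    wt = None if single_class_tune else class_weight_vector(yt, config.class_weights)

    # The fixed input average-pool commutes with the dihedral augmentations,
    # so inputs are pooled once up front and training (including on-the-fly
    # augmentation) runs at the working resolution.
    net = model
    if isinstance(model.layers[0], AvgPool2D):
        X = model.layers[0].forward(X)
        Xt = model.layers[0].forward(Xt)
        net = Sequential(model.layers[1:])

    if config.augment_train and config.augment_mode == "materialize":
        # the full augmentation set (8 dihedral variants + the configured
        # scalings) is precomputed once; epochs then shuffle through it
        aug_x, aug_y, aug_w = [], [], []
        acfg = config.augmentation
        ks = range(4) if acfg.rotation else (0,)
        reflects = [False] + ([True] if (acfg.h_reflect or acfg.v_reflect) else [])
        for xi, yi, wi in zip(X, y, w):
            hwc = xi.transpose(1, 2, 0)
            variants = [_dihedral(hwc, k, r) for k in ks for r in reflects]
            variants += [_scale_pixels(hwc, sc) for sc in acfg.scales]
            for v in variants:
                aug_x.append(v.transpose(2, 0, 1))
                aug_y.append(yi)
                aug_w.append(wi)
        X = np.stack(aug_x)
        y = np.asarray(aug_y, dtype=np.float32)
        w = np.asarray(aug_w, dtype=np.float64)

    init_weights = model.get_weights()
    best = {"loss": np.inf, "weights": None, "point": None}
    history = []
    for gi, point in enumerate(config.grid_points()):
        # multi-start: SGD from a random initialization occasionally lands
        # in a degenerate optimum (constant output); a fresh draw recovers
        best_point_loss, best_point_weights = np.inf, None
        for attempt in range(config.max_restarts + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x7A, gi, attempt])
            )
            model.set_weights(init_weights)
            if attempt > 0:
                model.reinit(rng)
            model.set_dropout_rate(point.get("dropout_rate", 0.5))
            if config.optimizer == "adam":
                opt = Adam(model, lr=point.get("learning_rate", 1e-3))
            else:
                opt = SGD(model, lr=point.get("learning_rate", 0.01),
                          momentum=point.get("momentum", 0.9))
            attempt_loss, stall = np.inf, 0
            for epoch in range(config.epochs_max):
                order = rng.permutation(len(X))
                ep_loss = 0.0
                for start in range(0, len(X), config.batch_size):
                    idx = order[start : start + config.batch_size]
                    xb = X[idx]
                    if config.augment_train and config.augment_mode == "online":
                        xb = np.stack(
                            [
                                random_augment(x.transpose(1, 2, 0), config.augmentation, rng)
                                .transpose(2, 0, 1)
                                for x in xb
                            ]
                        )
                    logits = net.forward(xb, train=True, rng=rng)
                    loss, dlog = bce_with_logits(logits, y[idx], w[idx])
                    net.backward(dlog)
                    opt.step()
                    ep_loss += loss * len(idx)
                tune_logits = net.forward(Xt, train=False)
                tune_loss, _ = bce_with_logits(tune_logits, yt, wt)
                # a single-diagnosis tuning subject cannot expose a
                # constant-output model (always predicting its class gives
                # minimal tune loss), so the class-balanced training loss
                # joins the selection metric in that case
                sel_loss = tune_loss + ep_loss / len(X) if single_class_tune else tune_loss
                history.append(
                    dict(point, grid_index=gi, restart=attempt, epoch=epoch,
                         train_loss=ep_loss / len(X), tune_loss=tune_loss,
                         selection_loss=sel_loss)
                )
                if sel_loss < attempt_loss - config.min_delta:
                    attempt_loss, stall = sel_loss, 0
                    if sel_loss < best_point_loss:
                        best_point_loss, best_point_weights = sel_loss, model.get_weights()
                else:
                    stall += 1
                    if stall >= config.patience and epoch + 1 >= config.min_epochs:
                        break
            if best_point_loss <= config.restart_threshold:
                break
            log.info("grid point %s attempt %d unconverged (tune loss %.4f)",
                     point, attempt, best_point_loss)
        log.info("grid point %s: tune loss %.4f", point, best_point_loss)
        if best_point_loss < best["loss"]:
            best = {"loss": best_point_loss, "weights": best_point_weights, "point": point}
    model.set_weights(best["weights"])
    model.set_dropout_rate(best["point"].get("dropout_rate", 0.5))
    return model, pd.DataFrame(history), best["point"]


# ---------------------------------------------------------------------------
# cascaded prediction
# ---------------------------------------------------------------------------

@dataclass
class CascadePrediction:
    """Gated two-stage prediction with Monte-Carlo dropout uncertainty.

    ``p_ad``/``u_ad`` are present only when the cell gate fires
    (p_cells >= threshold; the threshold itself counts as positive)."""

    p_cells: float
    u_cells: float
    p_ad: float | None
    u_ad: float | None
    decision: str  # 'no_cells' | 'healthy' | 'AD'
    n_calls: int


def cascade_predict(cell_model, ad_model, patch, threshold: float = 0.5,
                    n_calls: int = 50, seed: int = 0) -> CascadePrediction:
    """Classify one patch through the cascade."""
    from .uncertainty import predict_with_dropout

    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    x = patch.pixels.transpose(2, 0, 1)[None] if isinstance(patch, MPTPatch) else patch[None]
    ens_c = predict_with_dropout(cell_model, x, n_calls=n_calls, seed=seed)
    p_cells, u_cells = float(ens_c.mean[0]), float(ens_c.std[0])
    if p_cells < threshold:
        return CascadePrediction(p_cells, u_cells, None, None, "no_cells", n_calls)
    ens_a = predict_with_dropout(ad_model, x, n_calls=n_calls, seed=seed + 1)
    p_ad, u_ad = float(ens_a.mean[0]), float(ens_a.std[0])
    decision = "AD" if p_ad >= 0.5 else "healthy"
    return CascadePrediction(p_cells, u_cells, p_ad, u_ad, decision, n_calls)


def run_loocv(patches, train_config: TrainConfig, arch_config: ArchConfig | None = None,
              n_calls: int = 50, gate_threshold: float = 0.5,
              train_config_ad: TrainConfig | None = None):
    """Full subject-wise leave-one-out evaluation of the cascade.

    For every cross-validation run, the cell gate is trained on all training
    patches and the AD stage on the expert-labelled living-cell subset; the
    held-out subject's patches are then pushed through the gated cascade
    with ``n_calls`` Monte-Carlo dropout passes.

    Returns (per-patch prediction table, per-call probability arrays keyed
    'cells' and 'ad', the CV plan). In the per-call arrays, patches never
    reaching stage 2 hold NaN in the 'ad' rows.
    """
    from .uncertainty import predict_with_dropout

    arch = arch_config or ArchConfig()
    config_ad = train_config_ad or train_config
    subjects = sorted({p.subject_id for p in patches})
    diagnoses = {p.subject_id: p.diagnosis for p in patches}
    plan = make_cv_plan(subjects, seed=train_config.seed, diagnoses=diagnoses)
    rows = []
    calls_cells = []
    calls_ad = []
    for fold, run in enumerate(plan.runs):
        tr = [p for p in patches if p.subject_id in run.train_subjects]
        tu = [p for p in patches if p.subject_id == run.tune_subject]
        te = [p for p in patches if p.subject_id == run.test_subject]
        log.info("fold %d: test %s, tune %s (%d train patches)",
                 fold, run.test_subject, run.tune_subject, len(tr))

        cell_model = build_model(arch)
        train(cell_model, tr, tu, train_config, task="cells")
        tr_cells = [p for p in tr if p.has_cells]
        tu_cells = [p for p in tu if p.has_cells] or tu
        ad_model = build_model(arch)
        train(ad_model, tr_cells, tu_cells, config_ad, task="ad")

        Xte = _to_nchw(te)
        ens_c = predict_with_dropout(cell_model, Xte, n_calls=n_calls,
                                     seed=train_config.seed + 1000 + fold)
        ens_a = predict_with_dropout(ad_model, Xte, n_calls=n_calls,
                                     seed=train_config.seed + 2000 + fold)
        gated = ens_c.mean >= gate_threshold
        for i, p in enumerate(te):
            p_ad = float(ens_a.mean[i]) if gated[i] else None
            rows.append(
                {
                    "fold": fold,
                    "subject_id": p.subject_id,
                    "stack_id": p.stack_id,
                    "frame_index": p.frame_index,
                    "patch_index": p.patch_index,
                    "depth_um": p.depth_um,
                    "has_cells": p.has_cells,
                    "diagnosis": p.diagnosis,
                    "p_cells": float(ens_c.mean[i]),
                    "u_cells": float(ens_c.std[i]),
                    "p_ad": p_ad,
                    "u_ad": float(ens_a.std[i]) if gated[i] else None,
                    "decision": (
                        "no_cells" if not gated[i] else ("AD" if p_ad >= 0.5 else "healthy")
                    ),
                }
            )
        calls_cells.append(ens_c.probabilities)
        ad_calls = ens_a.probabilities.copy()
        ad_calls[:, ~gated] = np.nan
        calls_ad.append(ad_calls)
    per_call = {
        "cells": np.concatenate(calls_cells, axis=1),
        "ad": np.concatenate(calls_ad, axis=1),
    }
    return pd.DataFrame(rows), per_call, plan
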