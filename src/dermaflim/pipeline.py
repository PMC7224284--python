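"""End-to-end pipeline orchestration: simulate -> fit -> patch -> train ->
predict -> explain -> evaluate, plus the depth-profile analysis.

Each stage writes its artifacts into ``<out>/<stage>/`` together with a
``manifest.json`` recording the stage name, the hash of the configuration
section it read, the seed, and its input/output files — so every artifact is
traceable and deterministic stages reproduce byte-identical outputs on
re-run. A stage whose upstream artifacts are missing fails with an error
naming the absent stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cascade as casc
from . import depth as depth_mod
from . import evaluation as ev
from . import flim as flim_mod
from . import synthetic as syn
from .patches import NormConfig, assemble_patches, MPTPatch

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "fit", "patch", "train", "predict", "explain", "evaluate"]


class PipelineError(RuntimeError):
    pass


class MissingStageError(PipelineError):
    """An upstream stage's outputs are absent; the message names it."""


@dataclass
class PipelineConfig:
    """Structured configuration for the full pipeline.

    Every stage reads only its own section plus the globals (seed, output
    directory, verbosity). Round-trips losslessly through YAML.
    """

    seed: int
    out_dir: str = "pipeline_out"
    verbosity: str = "INFO"
    cohort: dict = field(default_factory=dict)
    flim: dict = field(default_factory=dict)
    patching: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    uncertainty: dict = field(default_factory=dict)
    relevance: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise PipelineError("pipeline config must set a seed")
        return cls(**d)

    def cohort_config(self) -> syn.CohortConfig:
        d = dict(self.cohort)
        d.setdefault("seed", self.seed)
        if "effect_sizes" in d and not isinstance(d["effect_sizes"], syn.EffectSizes):
            d["effect_sizes"] = syn.EffectSizes(**d["effect_sizes"])
        if "stacks_per_subject" in d:
            d["stacks_per_subject"] = tuple(d["stacks_per_subject"])
        return syn.CohortConfig(**d)

    def section_hash(self, section: str) -> str:
        payload = {"seed": self.seed, section: getattr(self, section, {})}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(stage_dir: Path, stage: str, cfg_hash: str, seed: int,
                    inputs: list, outputs: list) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg_hash,
        "seed": seed,
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(out: Path, stage: str) -> Path:
    d = out / stage
    if not (d / "manifest.json").exists():
        raise MissingStageError(f"stage '{stage}' has not been run (missing {d})")
    return d


def _stage_dir(out: Path, stage: str) -> Path:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    d = _stage_dir(out, "simulate")
    ccfg = config.cohort_config()
    cohort = syn.generate_cohort(ccfg)
    manifest = syn.write_cohort(cohort, ccfg, d)
    gt = syn.ground_truth(cohort, ccfg)
    gt.to_csv(d / "ground_truth.csv", index=False)
    ccfg.to_yaml(d / "cohort_config.yml")
    outputs = [d / "manifest.csv", d / "ground_truth.csv", d / "cohort_config.yml"]
    outputs += sorted(d.glob("*.tif"))
    _write_manifest(d, "simulate", config.section_hash("cohort"), config.seed, [], outputs)
    log.info("simulate: %d subjects, %d frames", len(cohort), len(manifest))
    return d


def stage_fit(config: PipelineConfig) -> Path:
    """Demonstrate the TCSPC fitting path on a configurable subset of
    frames: sample decay cubes from the simulated ground truth, bin, fit,
    and store the per-pixel lifetime maps with their fit masks."""
    out = Path(config.out_dir)
    _require(out, "simulate")
    d = _stage_dir(out, "fit")
    sec = dict(config.flim)
    crop_px = int(sec.pop("crop_px", 24))
    max_frames = int(sec.pop("max_frames", 2))
    fit_cfg = flim_mod.FitConfig(**sec)
    ccfg = config.cohort_config()
    from dataclasses import replace

    small = replace(ccfg, field_px=crop_px,
                    field_um=ccfg.field_um * crop_px / ccfg.field_px)
    cohort = syn.generate_cohort(small)
    frames = [fr for s in cohort for st in s.stacks for fr in st.frames if fr.has_cells]
    frames = frames[:max_frames]
    cubes = [syn.render_decay_cube(fr, small) for fr in frames]
    maps = flim_mod.fit_stack(cubes, fit_cfg)
    outputs = []
    for fr, m in zip(frames, maps):
        path = d / f"{fr.stack_id}_f{fr.frame_index:03d}_flim.npz"
        np.savez(path, a1=m.a1, a2=m.a2, tau1=m.tau1, tau2=m.tau2, tau_m=m.tau_m,
                 ratio=m.ratio, intensity=m.intensity, fit_mask=m.fit_mask,
                 goodness=m.goodness)
        outputs.append(path)
    _write_manifest(d, "fit", config.section_hash("flim"), config.seed,
                    [out / "simulate" / "manifest.csv"], outputs)
    return d


def _load_patches(config: PipelineConfig) -> list:
    out = Path(config.out_dir)
    d = _require(out, "patch")
    data = np.load(d / "patches.npz", allow_pickle=False)
    meta = pd.read_csv(d / "patch_manifest.csv")
    pixels = data["pixels"]
    patches = []
    for i, row in meta.iterrows():
        patches.append(
            MPTPatch(
                pixels=pixels[i],
                subject_id=row.subject_id,
                stack_id=row.stack_id,
                frame_index=int(row.frame_index),
                depth_um=float(row.depth_um),
                patch_index=int(row.patch_index),
                has_cells=bool(row.has_cells),
                diagnosis=row.diagnosis,
            )
        )
    return patches


def stage_patch(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    _require(out, "simulate")
    d = _stage_dir(out, "patch")
    n = int(config.patching.get("grid", 3))
    norm = NormConfig(**config.patching.get("norm", {}))
    ccfg = config.cohort_config()
    cohort = syn.generate_cohort(ccfg)
    all_patches = []
    for s in cohort:
        for st in s.stacks:
            for fr in st.frames:
                img = syn.render_frame(fr, ccfg)
                all_patches += assemble_patches(
                    img.intensity, img.tau_m, img.ratio, norm=norm, n=n,
                    subject_id=s.subject_id, stack_id=st.stack_id,
                    frame_index=fr.frame_index, depth_um=fr.depth_um,
                    has_cells=fr.has_cells, diagnosis=s.diagnosis,
                )
    pixels = np.stack([p.pixels for p in all_patches])
    np.savez_compressed(d / "patches.npz", pixels=pixels)
    meta = pd.DataFrame([p.provenance() for p in all_patches])
    meta.to_csv(d / "patch_manifest.csv", index=False)
    _write_manifest(d, "patch", config.section_hash("patching"), config.seed,
                    [out / "simulate" / "manifest.csv"],
                    [d / "patches.npz", d / "patch_manifest.csv"])
    log.info("patch: %d patches", len(all_patches))
    return d


def _train_configs(config: PipelineConfig):
    sec = dict(config.training)
    arch = casc.ArchConfig(**sec.pop("arch", {}), seed=config.seed)
    ad_overrides = sec.pop("ad", {})
    if "augmentation" in sec:
        sec["augmentation"] = casc.AugmentConfig(**sec["augmentation"])
    base = casc.TrainConfig(**sec, seed=config.seed)
    tc_ad = None
    if ad_overrides:
        merged = {**sec, **ad_overrides}
        if "augmentation" in merged and not isinstance(merged["augmentation"], casc.AugmentConfig):
            merged["augmentation"] = casc.AugmentConfig(**merged["augmentation"])
        tc_ad = casc.TrainConfig(**merged, seed=config.seed)
    return base, tc_ad, arch


def stage_train(config: PipelineConfig) -> Path:
    """Train both cascade stages for every cross-validation run and store
    the per-fold model weights and training histories."""
    out = Path(config.out_dir)
    patches = _load_patches(config)
    d = _stage_dir(out, "train")
    tc, tc_ad, arch = _train_configs(config)
    tc_ad = tc_ad or tc
    subjects = sorted({p.subject_id for p in patches})
    diagnoses = {p.subject_id: p.diagnosis for p in patches}
    plan = casc.make_cv_plan(subjects, seed=config.seed, diagnoses=diagnoses)
    outputs = []
    histories = []
    for fold, run in enumerate(plan.runs):
        tr = [p for p in patches if p.subject_id in run.train_subjects]
        tu = [p for p in patches if p.subject_id == run.tune_subject]
        cell_model = casc.build_model(arch)
        _, h1, _ = casc.train(cell_model, tr, tu, tc, task="cells")
        tr_cells = [p for p in tr if p.has_cells]
        tu_cells = [p for p in tu if p.has_cells] or tu
        ad_model = casc.build_model(arch)
        _, h2, _ = casc.train(ad_model, tr_cells, tu_cells, tc_ad, task="ad")
        for name, model in (("cells", cell_model), ("ad", ad_model)):
            path = d / f"fold{fold:02d}_{name}.npz"
            model.save(path)
            outputs.append(path)
        h1["fold"], h1["stage"] = fold, "cells"
        h2["fold"], h2["stage"] = fold, "ad"
        histories += [h1, h2]
    pd.concat(histories, ignore_index=True).to_csv(d / "history.csv", index=False)
    with open(d / "cv_plan.json", "w") as fh:
        json.dump([asdict(r) for r in plan.runs], fh, indent=2)
    outputs += [d / "history.csv", d / "cv_plan.json"]
    _write_manifest(d, "train", config.section_hash("training"), config.seed,
                    [out / "patch" / "patches.npz"], outputs)
    return d


def stage_predict(config: PipelineConfig) -> Path:
    """Push every held-out subject's patches through its fold's cascade with
    Monte-Carlo dropout."""
    from .uncertainty import predict_with_dropout

    out = Path(config.out_dir)
    train_dir = _require(out, "train")
    patches = _load_patches(config)
    d = _stage_dir(out, "predict")
    _, _, arch = _train_configs(config)
    n_calls = int(config.uncertainty.get("n_calls", 50))
    threshold = float(config.uncertainty.get("gate_threshold", 0.5))
    with open(train_dir / "cv_plan.json") as fh:
        runs = json.load(fh)
    rows = []
    calls_cells, calls_ad = [], []
    for fold, run in enumerate(runs):
        te = [p for p in patches if p.subject_id == run["test_subject"]]
        cell_model = casc.build_model(arch)
        cell_model.load(train_dir / f"fold{fold:02d}_cells.npz")
        ad_model = casc.build_model(arch)
        ad_model.load(train_dir / f"fold{fold:02d}_ad.npz")
        X = np.stack([p.pixels.transpose(2, 0, 1) for p in te])
        ens_c = predict_with_dropout(cell_model, X, n_calls=n_calls,
                                     seed=config.seed + 1000 + fold)
        ens_a = predict_with_dropout(ad_model, X, n_calls=n_calls,
                                     seed=config.seed + 2000 + fold)
        gated = ens_c.mean >= threshold
        for i, p in enumerate(te):
            rows.append(
                {
                    "fold": fold, **p.provenance(),
                    "p_cells": float(ens_c.mean[i]),
                    "u_cells": float(ens_c.std[i]),
                    "p_ad": float(ens_a.mean[i]) if gated[i] else None,
                    "u_ad": float(ens_a.std[i]) if gated[i] else None,
                    "decision": ("no_cells" if not gated[i]
                                 else ("AD" if ens_a.mean[i] >= 0.5 else "healthy")),
                }
            )
        calls_cells.append(ens_c.probabilities)
        a = ens_a.probabilities.copy()
        a[:, ~gated] = np.nan
        calls_ad.append(a)
    pd.DataFrame(rows).to_csv(d / "predictions.csv", index=False)
    np.savez(d / "per_call.npz",
             cells=np.concatenate(calls_cells, axis=1),
             ad=np.concatenate(calls_ad, axis=1))
    _write_manifest(d, "predict", config.section_hash("uncertainty"), config.seed,
                    [train_dir / "cv_plan.json"],
                    [d / "predictions.csv", d / "per_call.npz"])
    return d


def stage_explain(config: PipelineConfig) -> Path:
    """Deep Taylor relevance maps for a few gated-positive test patches."""
    from .relevance import deep_taylor_relevance, modality_contributions, overlay_heatmap

    out = Path(config.out_dir)
    train_dir = _require(out, "train")
    pred_dir = _require(out, "predict")
    d = _stage_dir(out, "explain")
    n_examples = int(config.relevance.get("n_examples", 4))
    _, _, arch = _train_configs(config)
    preds = pd.read_csv(pred_dir / "predictions.csv")
    patches = _load_patches(config)
    key = lambda p: (p.subject_id, p.stack_id, p.frame_index, p.patch_index)
    by_key = {key(p): p for p in patches}
    gated = preds[preds.decision != "no_cells"].head(n_examples)
    outputs = []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for _, row in gated.iterrows():
        ad_model = casc.build_model(arch)
        ad_model.load(train_dir / f"fold{int(row.fold):02d}_ad.npz")
        patch = by_key[(row.subject_id, row.stack_id, row.frame_index, row.patch_index)]
        rmap = deep_taylor_relevance(ad_model, patch)
        stem = f"{row.subject_id}_{row.stack_id}_f{int(row.frame_index):03d}_p{int(row.patch_index)}"
        np.savez(d / f"{stem}_relevance.npz", per_pixel=rmap.per_pixel,
                 per_channel_total=rmap.per_channel_total,
                 output_score=rmap.output_score)
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        axes[0].imshow(patch.pixels[..., 0], cmap="gray")
        axes[0].set_title("AF intensity")
        axes[1].imshow(overlay_heatmap(patch, rmap))
        axes[1].set_title(f"relevance ({row.decision})")
        axes[2].imshow(modality_contributions(rmap))
        axes[2].set_title("modality contributions (RGB)")
        for ax in axes:
            ax.axis("off")
        fig.savefig(d / f"{stem}_heatmap.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
        outputs += [d / f"{stem}_relevance.npz", d / f"{stem}_heatmap.png"]
    _write_manifest(d, "explain", config.section_hash("relevance"), config.seed,
                    [pred_dir / "predictions.csv"], outputs)
    return d


def stage_evaluate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    pred_dir = _require(out, "predict")
    d = _stage_dir(out, "evaluate")
    preds = pd.read_csv(pred_dir / "predictions.csv")
    report: dict = {}

    cells_y = preds.has_cells.astype(bool).values
    cells_d = (preds.decision != "no_cells").values
    report["cells"] = ev.confusion_metrics(cells_y, cells_d).as_dict()
    report["cells_roc"] = {
        k: v for k, v in ev.roc_pr_curves(cells_y, preds.p_cells.values).items()
        if k in ("roc_auc", "pr_auc")
    }
    gated = preds[preds.decision != "no_cells"]
    if len(gated) and gated.diagnosis.nunique() == 2:
        ad_y = (gated.diagnosis == "AD").values
        ad_d = (gated.decision == "AD").values
        report["ad"] = ev.confusion_metrics(ad_y, ad_d).as_dict()
        report["ad_roc"] = {
            k: v for k, v in ev.roc_pr_curves(ad_y, gated.p_ad.values).items()
            if k in ("roc_auc", "pr_auc")
        }
    table = preds.assign(label=cells_y, pred=cells_d)
    try:
        report["inter_subject_accuracy_sd"] = ev.grouped_accuracy_sd(
            table, "subject_id", "label", "pred")
        report["inter_stack_accuracy_sd"] = ev.grouped_accuracy_sd(
            table, "stack_id", "label", "pred")
    except ValueError:
        pass
    with open(d / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(d, "evaluate", config.section_hash("evaluation"), config.seed,
                    [pred_dir / "predictions.csv"], [d / "metrics.json"])
    return d


def stage_depth_profile(config: PipelineConfig) -> Path:
    """Granulosum-aligned group profiles of tau_m and a1/a2 with per-depth
    Mann-Whitney comparisons."""
    out = Path(config.out_dir)
    _require(out, "simulate")
    d = _stage_dir(out, "depth_profile")
    ccfg = config.cohort_config()
    cohort = syn.generate_cohort(ccfg)
    tables, gidx, groups, subj = {}, {}, {}, {}
    for s in cohort:
        for st in s.stacks:
            tables[st.stack_id] = depth_mod.stack_depth_table(st, ccfg)
            gidx[st.stack_id] = st.granulosum_index
            groups[st.stack_id] = s.diagnosis
            subj[st.stack_id] = s.subject_id
    aligned = depth_mod.align_stacks(tables, gidx, groups, subj, ccfg.depth_step_um)
    profiles = depth_mod.depth_profiles(aligned)
    prof_df = pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True)
    prof_df.to_csv(d / "profiles.csv", index=False)
    alpha = float(config.evaluation.get("alpha", 0.05))
    tests = []
    common = sorted(
        set(profiles["AD"].aligned_depth_um) & set(profiles["healthy"].aligned_depth_um)
    ) if {"AD", "healthy"} <= set(profiles) else []
    for depth_um in common:
        a = depth_mod.group_samples_at_depth(aligned, "AD", depth_um)
        h = depth_mod.group_samples_at_depth(aligned, "healthy", depth_um)
        if a.size and h.size:
            u, p = depth_mod.compare_groups(a, h)
            tests.append({"aligned_depth_um": depth_um, "U": u, "p": p,
                          "significant": bool(p < alpha)})
    pd.DataFrame(tests).to_csv(d / "tau_m_tests.csv", index=False)
    _write_manifest(d, "depth_profile", config.section_hash("evaluation"), config.seed,
                    [], [d / "profiles.csv", d / "tau_m_tests.csv"])
    return d


_STAGE_FN = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "patch": stage_patch,
    "train": stage_train,
    "predict": stage_predict,
    "explain": stage_explain,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: PipelineConfig, stages: list | None = None) -> dict:
    """Run the requested stages in canonical order.

    ``stages`` defaults to all seven; unknown names raise, and a stage whose
    prerequisites were neither run in this call nor found on disk raises
    :class:`MissingStageError` naming the absent stage.
    """
    stages = list(stages) if stages is not None else list(STAGE_ORDER)
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    stages = sorted(set(stages), key=STAGE_ORDER.index)
    results = {}
    for s in stages:
        log.info("running stage %s", s)
        results[s] = _STAGE_FN[s](config)
    return results
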