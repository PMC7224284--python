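"""Synthetic multiphoton-tomography cohort generator with known ground truth.

Emulates the structure of an in-vivo forearm FLIM study: a cohort of
atopic-dermatitis (AD) patients and healthy volunteers, up to three z-stacks
per subject, en-face frames every 5 um down to ~100 um, and per-pixel
two-component NAD(P)H decay parameters from which raw TCSPC photon cubes can
be sampled.

The depth axis follows the epidermal layer sequence: stratum corneum (dead
corneocytes, no living cells), stratum granulosum, stratum spinosum, stratum
basale (melanin signature: mean-lifetime drop and a1/a2 rise), then dermis.
Disease effects, each with a tunable size:

* ``granulosum_tau_shift_ns`` — AD granulosum mean lifetime reduced.
* ``perinuclear_clustering_strength`` — fraction of each cell's
  mitochondrial puncta relocated from the cytoplasm into a perinuclear ring
  in AD living-cell layers.
* ``epidermal_thickening_um`` — AD spinosum thickened, pushing the basale
  melanin signature deeper than the healthy ~35 um.
* ``melanin_depth_um`` — depth at which the healthy basale is reached.

With all effect sizes zero the generated features are statistically
independent of the diagnosis label, which makes the generator usable as a
null model for calibration checks.

Every frame owns an integer render seed derived from the cohort seed, so
cohorts, rendered images, photon cubes and ground-truth tables are all
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .flim import PhotonDecayCube

__all__ = [
    "EffectSizes",
    "CohortConfig",
    "FrameSpec",
    "FrameImages",
    "ZStack",
    "SubjectRecord",
    "ConfigError",
    "generate_cohort",
    "render_frame",
    "render_decay_cube",
    "ground_truth",
    "write_cohort",
]

# mean lifetime (ns) per epidermal layer, before random effects
_LAYER_TAU = {
    "corneum": 1.60,
    "granulosum": 1.25,
    "spinosum": 1.15,
    "basale": 0.85,  # melanin: shorter tau_m, larger a1/a2
    "dermis": 1.45,
}
# relative AF intensity per layer (scales the photon budget)
_LAYER_INTENSITY = {
    "corneum": 0.75,
    "granulosum": 0.55,
    "spinosum": 0.50,
    "basale": 0.50,
    "dermis": 0.15,
}
_LIVING = ("granulosum", "spinosum", "basale")


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class EffectSizes:
    granulosum_tau_shift_ns: float = 0.15
    perinuclear_clustering_strength: float = 0.6
    epidermal_thickening_um: float = 10.0
    melanin_depth_um: float = 35.0

    @classmethod
    def null(cls) -> "EffectSizes":
        """All disease effects off: diagnosis independent of every feature."""
        return cls(0.0, 0.0, 0.0, 35.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: 6 AD + 4 healthy subjects, 21
    z-stacks in total (1-3 per subject), 21 frames from 0 to 100 um in 5 um
    steps, 160x160 um fields at 512 px.
    """

    seed: int
    n_ad_subjects: int = 6
    n_healthy_subjects: int = 4
    stacks_per_subject: tuple = (1, 3)
    total_stacks: int | None = 21
    frames_per_stack: int = 21
    depth_step_um: float = 5.0
    field_px: int = 512
    field_um: float = 160.0
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    photon_budget: float = 3000.0
    time_bins: int = 256
    period_ns: float = 12.5
    tau1_ns: float = 0.4  # free NAD(P)H
    tau2_ns: float = 2.5  # protein-bound NAD(P)H

    def validate(self) -> None:
        counts = (
            self.n_ad_subjects,
            self.n_healthy_subjects,
            self.frames_per_stack,
            self.field_px,
            self.time_bins,
        )
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        lo, hi = self.stacks_per_subject
        if not (1 <= lo <= hi):
            raise ConfigError("stacks_per_subject must be a range within [1, n]")
        n = self.n_ad_subjects + self.n_healthy_subjects
        if self.total_stacks is not None and not (n * lo <= self.total_stacks <= n * hi):
            raise ConfigError("total_stacks incompatible with per-subject range")
        if self.photon_budget <= 0:
            raise ConfigError("photon_budget must be positive")
        if self.tau1_ns <= 0 or self.tau2_ns <= 0:
            raise ConfigError("component lifetimes must be positive")
        es = self.effect_sizes
        if not all(np.isfinite(v) for v in asdict(es).values()):
            raise ConfigError("effect sizes must be finite")

    # -- plain-text config round-trip ------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stacks_per_subject"] = list(self.stacks_per_subject)
        with open(path, "w") as fh:
            yaml.safe_dump({"cohort": d}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)["cohort"]
        if "seed" not in d:
            raise ConfigError("cohort config must set a seed")
        d["effect_sizes"] = EffectSizes(**d.get("effect_sizes", {}))
        d["stacks_per_subject"] = tuple(d.get("stacks_per_subject", (1, 3)))
        return cls(**d)


@dataclass
class FrameSpec:
    """One en-face frame: its layer context and scalar ground truth."""

    subject_id: str
    diagnosis: str  # 'healthy' | 'AD'
    stack_id: str
    frame_index: int
    depth_um: float
    layer: str
    has_cells: bool
    tau_m_mean: float  # ground-truth mean lifetime of the frame, ns
    intensity_mean: float  # relative AF intensity in [0, 1]
    clustering: float  # perinuclear clustering strength applied (0 = uniform)
    render_seed: int

    def ratio_mean(self, tau1: float = 0.4, tau2: float = 2.5) -> float:
        a1 = (tau2 - self.tau_m_mean) / (tau2 - tau1)
        return a1 / (1.0 - a1)


@dataclass
class FrameImages:
    """Rendered per-pixel ground truth of one frame."""

    intensity: np.ndarray  # relative AF intensity, [0, 1]
    tau_m: np.ndarray  # ns
    a1: np.ndarray  # short-component amplitude, a2 = 1 - a1
    ratio: np.ndarray  # a1 / a2
    cell_mask: np.ndarray  # bool, living-cell pixels


@dataclass
class ZStack:
    stack_id: str
    frames: list
    granulosum_index: int


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: str
    stacks: list


def _stack_counts(rng, n_subjects: int, lo: int, hi: int, total: int | None):
    counts = rng.integers(lo, hi + 1, size=n_subjects)
    if total is not None:
        # nudge random subjects until the cohort total matches the design
        while counts.sum() > total:
            i = rng.integers(n_subjects)
            if counts[i] > lo:
                counts[i] -= 1
        while counts.sum() < total:
            i = rng.integers(n_subjects)
            if counts[i] < hi:
                counts[i] += 1
    return counts


def generate_cohort(config: CohortConfig) -> list:
    """Generate the subject/stack/frame skeleton with scalar ground truth.

    Pixel images and photon cubes are rendered lazily per frame (see
    :func:`render_frame` / :func:`render_decay_cube`); the returned records
    already carry every frame's layer, cell-presence label and true mean
    lifetime, which is all the depth-profile statistics need.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    es = config.effect_sizes

    n = config.n_ad_subjects + config.n_healthy_subjects
    diagnoses = ["AD"] * config.n_ad_subjects + ["healthy"] * config.n_healthy_subjects
    lo, hi = config.stacks_per_subject
    counts = _stack_counts(rng, n, lo, hi, config.total_stacks)

    cohort = []
    for si in range(n):
        subject_id = f"S{si + 1:02d}"
        diagnosis = diagnoses[si]
        subj_tau = rng.normal(0.0, 0.04)
        stacks = []
        for ki in range(int(counts[si])):
            stack_id = f"{subject_id}-Z{ki + 1}"
            stack_tau = rng.normal(0.0, 0.02)
            # granulosum starts 10-20 um below the surface
            g_um = float(rng.choice([10.0, 15.0, 20.0]))
            gran_thick = 10.0
            spin_thick = max(es.melanin_depth_um - g_um - gran_thick, 5.0)
            if diagnosis == "AD":
                spin_thick += es.epidermal_thickening_um
            basale_start = g_um + gran_thick + spin_thick
            basale_end = basale_start + 10.0
            frames = []
            for fi in range(config.frames_per_stack):
                d = fi * config.depth_step_um
                if d < g_um:
                    layer = "corneum"
                elif d < g_um + gran_thick:
                    layer = "granulosum"
                elif d < basale_start:
                    layer = "spinosum"
                elif d < basale_end:
                    layer = "basale"
                else:
                    layer = "dermis"
                tau = _LAYER_TAU[layer] + subj_tau + stack_tau + rng.normal(0.0, 0.02)
                if layer == "granulosum" and diagnosis == "AD":
                    tau -= es.granulosum_tau_shift_ns
                tau = float(np.clip(tau, 0.5, config.tau2_ns - 0.1))
                clustering = (
                    es.perinuclear_clustering_strength
                    if (diagnosis == "AD" and layer in _LIVING)
                    else 0.0
                )
                frames.append(
                    FrameSpec(
                        subject_id=subject_id,
                        diagnosis=diagnosis,
                        stack_id=stack_id,
                        frame_index=fi,
                        depth_um=d,
                        layer=layer,
                        has_cells=layer in _LIVING,
                        tau_m_mean=tau,
                        intensity_mean=_LAYER_INTENSITY[layer],
                        clustering=float(clustering),
                        render_seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
            gran_index = int(round(g_um / config.depth_step_um))
            stacks.append(ZStack(stack_id=stack_id, frames=frames, granulosum_index=gran_index))
        cohort.append(SubjectRecord(subject_id=subject_id, diagnosis=diagnosis, stacks=stacks))
    return cohort


def _voronoi_cells(rng, npx: int, um_per_px: float, pitch_um: float,
                   return_centers: bool = False):
    """Jittered-grid Voronoi tessellation; distances in um."""
    n_side = max(int(round(npx * um_per_px / pitch_um)), 1)
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    centers = np.column_stack([gy.ravel(), gx.ravel()]).astype(float)
    centers = (centers + 0.5) * (npx / n_side)
    centers += rng.uniform(-0.35, 0.35, centers.shape) * (npx / n_side)
    tree = cKDTree(centers)
    yy, xx = np.meshgrid(np.arange(npx), np.arange(npx), indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dists, _ = tree.query(pts, k=min(2, len(centers)))
    if dists.ndim == 1:
        dists = np.column_stack([dists, np.full_like(dists, np.inf)])
    d1 = dists[:, 0].reshape(npx, npx) * um_per_px
    gap = (dists[:, 1] - dists[:, 0]).reshape(npx, npx) * um_per_px
    if return_centers:
        return d1, gap, centers
    return d1, gap


def _speckle(rng, npx: int, sigma_px: float) -> np.ndarray:
    """Smoothed positive noise field in [0, 1] — the mitochondrial texture."""
    f = gaussian_filter(rng.standard_normal((npx, npx)), sigma_px)
    f -= f.mean()
    s = f.std()
    if s > 0:
        f /= s
    return np.clip(f, 0.0, None) / 2.5  # keep within ~[0, 1]


def render_frame(frame: FrameSpec, config: CohortConfig) -> FrameImages:
    """Render one frame's per-pixel ground-truth images.

    Living-cell layers are drawn as a Voronoi tessellation of cells with
    dark nuclei and bright mitochondrial puncta in the cytoplasm; with
    nonzero clustering a corresponding fraction of each cell's puncta moves
    into a perinuclear ring. The stratum corneum shows large anuclear
    corneocytes, the dermis a dim unstructured background.
    """
    rng = np.random.default_rng(np.random.SeedSequence(frame.render_seed))
    npx = config.field_px
    um_per_px = config.field_um / config.field_px
    tau_lo, tau_hi = 0.45, config.tau2_ns - 0.05

    tau = np.full((npx, npx), frame.tau_m_mean)
    cell_mask = np.zeros((npx, npx), dtype=bool)

    if frame.layer in _LIVING:
        d1, gap, centers = _voronoi_cells(rng, npx, um_per_px, pitch_um=20.0, return_centers=True)
        r_nuc = 5.0
        nucleus = d1 < r_nuc
        border = gap < 1.2
        # mitochondria as discrete bright puncta: uniformly spread through
        # the cytoplasm in healthy cells, concentrated in a perinuclear ring
        # (fraction = clustering strength) in AD cells
        mito = np.zeros((npx, npx))
        r_cell = 10.0  # typical cytoplasm extent, um
        for cy, cx in centers:
            n_mito = rng.poisson(28)
            clustered = rng.random(n_mito) < frame.clustering
            radius = np.where(
                clustered,
                rng.normal(r_nuc + 1.5, 0.8, n_mito),
                np.sqrt(rng.uniform(r_nuc**2, r_cell**2, n_mito)),
            )
            theta = rng.uniform(0, 2 * np.pi, n_mito)
            py = np.clip(np.round(cy + radius * np.sin(theta) / um_per_px), 0, npx - 1)
            px_ = np.clip(np.round(cx + radius * np.cos(theta) / um_per_px), 0, npx - 1)
            np.add.at(mito, (py.astype(int), px_.astype(int)), 1.0)
        mito = gaussian_filter(mito, 0.6 / um_per_px)
        if mito.max() > 0:
            mito /= np.percentile(mito[mito > 0], 98)
        mito = np.clip(mito, 0.0, 1.3)
        mito[nucleus | border] = 0.0
        intensity = np.full((npx, npx), 0.28)
        intensity += 0.75 * mito
        intensity[nucleus] = 0.15
        intensity[border] = 0.22
        # mitochondria-rich pixels sit slightly lower in tau_m (more bound
        # NAD(P)H engaged in respiration)
        tau = tau + 0.20 * nucleus - 0.10 * np.clip(mito, 0, 1.0)
        cell_mask = ~border
    elif frame.layer == "corneum":
        _, gap = _voronoi_cells(rng, npx, um_per_px, pitch_um=32.0)
        border = gap < 1.5
        intensity = np.where(border, 0.3, 1.0)
    else:  # dermis
        intensity = 0.4 + 0.6 * _speckle(rng, npx, sigma_px=3.0 / um_per_px)

    intensity = intensity * frame.intensity_mean / max(_LAYER_INTENSITY[frame.layer], 1e-6)
    intensity *= np.exp(rng.normal(0.0, 0.10, intensity.shape))  # shot-to-shot gain
    intensity = np.clip(intensity + 0.02, 0.0, 1.0)

    tau = tau + gaussian_filter(rng.standard_normal(tau.shape), 2.0) * 0.05
    tau = np.clip(tau, tau_lo, tau_hi)
    a1 = (config.tau2_ns - tau) / (config.tau2_ns - config.tau1_ns)
    a1 = np.clip(a1, 0.01, 0.99)
    ratio = a1 / (1.0 - a1)
    return FrameImages(
        intensity=intensity.astype(np.float32),
        tau_m=tau.astype(np.float32),
        a1=a1.astype(np.float32),
        ratio=ratio.astype(np.float32),
        cell_mask=cell_mask,
    )


def render_decay_cube(
    frame: FrameSpec,
    config: CohortConfig,
    images: FrameImages | None = None,
) -> PhotonDecayCube:
    """Sample a raw TCSPC photon cube from a frame's ground-truth maps.

    Per pixel, the expected photon count is ``photon_budget * intensity`` and
    arrival times follow the two-component exponential mixture of the
    ground-truth (a1, tau1, a2, tau2), truncated at the laser period and
    discretised into ``time_bins`` uniform bins; counts are Poisson.
    """
    if config.tau1_ns <= 0 or config.tau2_ns <= 0:
        raise ValueError("component lifetimes must be positive")
    img = images if images is not None else render_frame(frame, config)
    if np.any(img.a1 < 0) or np.any(img.intensity < 0):
        raise ValueError("amplitudes and intensities must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([frame.render_seed, 0xC0DE]))
    nt = config.time_bins
    dt = config.period_ns / nt
    t = (np.arange(nt) + 0.5) * dt
    lam = config.photon_budget * img.intensity.astype(np.float64)

    decay1 = np.exp(-t / config.tau1_ns)
    decay2 = np.exp(-t / config.tau2_ns)
    npx = img.intensity.shape[0]
    counts = np.empty((npx, npx, nt), dtype=np.int32)
    for row in range(npx):  # chunked to bound memory at large fields
        a1 = img.a1[row].astype(np.float64)[:, None]
        shape = a1 * decay1[None, :] + (1.0 - a1) * decay2[None, :]
        shape /= shape.sum(axis=1, keepdims=True)
        counts[row] = rng.poisson(lam[row][:, None] * shape)
    meta = {
        "subject_id": frame.subject_id,
        "stack_id": frame.stack_id,
        "frame_index": frame.frame_index,
        "depth_um": frame.depth_um,
        "field_um": config.field_um,
    }
    return PhotonDecayCube(counts=counts, t_ns=t, meta=meta)


def ground_truth(cohort: list, config: CohortConfig) -> pd.DataFrame:
    """Flat per-patch ground-truth table (one row per 3x3-grid patch).

    Columns round-trip losslessly through CSV.
    """
    from .patches import PATCH_SIDE, patch_grid  # local import to avoid a cycle

    starts = patch_grid(config.field_px, patch=min(config.field_px, PATCH_SIDE))
    n_patches = len(starts) ** 2
    rows = []
    for subj in cohort:
        for stack in subj.stacks:
            for fr in stack.frames:
                for p in range(n_patches):
                    rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "diagnosis": subj.diagnosis,
                            "stack_id": stack.stack_id,
                            "frame_index": fr.frame_index,
                            "depth_um": fr.depth_um,
                            "patch_index": p,
                            "layer": fr.layer,
                            "has_cells": bool(fr.has_cells),
                            "granulosum_index": stack.granulosum_index,
                            "tau_m_true": round(fr.tau_m_mean, 6),
                            "ratio_true": round(
                                fr.ratio_mean(config.tau1_ns, config.tau2_ns), 6
                            ),
                            "render_seed": fr.render_seed,
                        }
                    )
    columns = [
        "subject_id", "diagnosis", "stack_id", "frame_index", "depth_um",
        "patch_index", "layer", "has_cells", "granulosum_index",
        "tau_m_true", "ratio_true", "render_seed",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: list, config: CohortConfig, outdir, decay_cubes: bool = False):
    """Write a cohort to disk: per-stack multi-page TIFFs, optional HDF5
    photon cubes, and a CSV manifest."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for subj in cohort:
        for stack in subj.stacks:
            pages = []
            for fr in stack.frames:
                img = render_frame(fr, config)
                pages.append(np.stack([img.intensity, img.tau_m, img.ratio], axis=-1))
                manifest.append(
                    {
                        "subject_id": subj.subject_id,
                        "diagnosis": subj.diagnosis,
                        "stack_id": stack.stack_id,
                        "frame_index": fr.frame_index,
                        "depth_um": fr.depth_um,
                        "has_cells": bool(fr.has_cells),
                    }
                )
                if decay_cubes:
                    import h5py

                    cube = render_decay_cube(fr, config, img)
                    with h5py.File(outdir / f"{stack.stack_id}.h5", "a") as fh:
                        g = fh.create_group(f"frame_{fr.frame_index:03d}")
                        g.create_dataset("counts", data=cube.counts, compression="gzip")
                        g.create_dataset("t_ns", data=cube.t_ns)
            tifffile.imwrite(outdir / f"{stack.stack_id}.tif", np.asarray(pages), photometric="minisblack")
    df = pd.DataFrame(manifest)
    df.to_csv(outdir / "manifest.csv", index=False)
    return df
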