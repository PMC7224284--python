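"""Patch extraction, channel assembly/normalization and cohort manifests.

A classifier input patch is a 200x200 px, 3-channel image: AF intensity,
mean lifetime tau_m, and the a1/a2 amplitude ratio, each clipped to a fixed
physical range and scaled to [0, 1]. Each frame yields a 3x3 grid of such
patches (overlapping when the frame side is below 600 px), indexed row-major
0-8, with subject/stack/frame provenance carried along.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PATCH_SIDE",
    "NormConfig",
    "MPTPatch",
    "ManifestError",
    "patch_grid",
    "crop_patches",
    "assemble_frame_channels",
    "assemble_patches",
    "write_patch_tiff",
    "read_patch_tiff",
    "read_manifest",
    "write_manifest",
]

PATCH_SIDE = 200

MANIFEST_COLUMNS = [
    "subject_id",
    "diagnosis",
    "stack_id",
    "frame_index",
    "depth_um",
    "has_cells",
]


class ManifestError(ValueError):
    """Manifest fails schema validation; message names the offender."""


@dataclass(frozen=True)
class NormConfig:
    """Per-channel physical ranges mapped linearly onto [0, 1].

    Intensity is normalized per frame by percentiles (robust to hot pixels);
    tau_m and a1/a2 are clipped to fixed physiological ranges so the channel
    scale is comparable across frames and subjects.
    """

    intensity_percentiles: tuple = (1.0, 99.0)
    tau_range_ns: tuple = (0.0, 5.0)
    ratio_range: tuple = (0.0, 20.0)


@dataclass
class MPTPatch:
    """A 200x200x3 normalized patch with provenance and labels."""

    pixels: np.ndarray  # (200, 200, 3) float32 in [0, 1]
    subject_id: str = "?"
    stack_id: str = "?"
    frame_index: int = -1
    depth_um: float = float("nan")
    patch_index: int = 0
    has_cells: bool | None = None  # tri-state: True / False / unknown
    diagnosis: str | None = None  # 'healthy' / 'AD' / unknown
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.shape != (PATCH_SIDE, PATCH_SIDE, 3):
            raise ValueError(f"patch must be {PATCH_SIDE}x{PATCH_SIDE}x3, got {px.shape}")
        if not (0 <= self.patch_index <= 8):
            raise ValueError("patch_index must lie in [0, 8]")
        self.pixels = px

    def provenance(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "stack_id": self.stack_id,
            "frame_index": self.frame_index,
            "depth_um": self.depth_um,
            "patch_index": self.patch_index,
            "has_cells": self.has_cells,
            "diagnosis": self.diagnosis,
        }


def patch_grid(side: int, patch: int = PATCH_SIDE, n: int = 3) -> list:
    """Start offsets of an n x n symmetric patch grid along one axis.

    The stride is floor((side - patch) / (n - 1)); patches overlap whenever
    side < n * patch. A side equal to the patch size degenerates to a single
    patch.
    """
    if side < patch:
        raise ValueError(f"frame side {side} smaller than patch size {patch}")
    if side == patch or n == 1:
        return [0]
    stride = (side - patch) // (n - 1)
    return [i * stride for i in range(n - 1)] + [side - patch]


def crop_patches(frame: np.ndarray, n: int = 3, patch: int = PATCH_SIDE):
    """Crop a frame (2-D or H x W x C) into the n x n patch grid.

    Returns a list of (patch_index, y0, x0, view) in row-major order.
    """
    h, w = frame.shape[:2]
    ys = patch_grid(h, patch, n)
    xs = patch_grid(w, patch, n)
    out = []
    idx = 0
    for y0 in ys:
        for x0 in xs:
            out.append((idx, y0, x0, frame[y0 : y0 + patch, x0 : x0 + patch]))
            idx += 1
    return out


def _normalize(channel: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise ValueError("normalization range must be increasing")
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def assemble_frame_channels(
    intensity: np.ndarray,
    tau_m: np.ndarray,
    ratio: np.ndarray,
    norm: NormConfig | None = None,
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate and normalize the three modality maps of one frame.

    Channel order is (AF intensity, tau_m, a1/a2). Pixels excluded by
    ``fit_mask`` (below the photon threshold) are set to 0 in the lifetime
    channels after normalization.
    """
    norm = norm or NormConfig()
    if not (intensity.shape == tau_m.shape == ratio.shape):
        raise ValueError("modality maps must share a shape")
    p_lo, p_hi = np.nanpercentile(intensity, norm.intensity_percentiles)
    if p_hi <= p_lo:
        p_hi = p_lo + 1.0
    chans = np.stack(
        [
            _normalize(intensity, p_lo, p_hi),
            _normalize(np.nan_to_num(tau_m), *norm.tau_range_ns),
            _normalize(np.nan_to_num(ratio), *norm.ratio_range),
        ],
        axis=-1,
    ).astype(np.float32)
    if fit_mask is not None:
        chans[~fit_mask, 1] = 0.0
        chans[~fit_mask, 2] = 0.0
    return chans


def assemble_patches(
    intensity: np.ndarray,
    tau_m: np.ndarray,
    ratio: np.ndarray,
    *,
    norm: NormConfig | None = None,
    fit_mask: np.ndarray | None = None,
    n: int = 3,
    **provenance,
) -> list:
    """Normalize a frame's channels and cut it into MPTPatch objects."""
    chans = assemble_frame_channels(intensity, tau_m, ratio, norm, fit_mask)
    patches = []
    for idx, y0, x0, view in crop_patches(chans, n=n):
        patches.append(
            MPTPatch(
                pixels=np.ascontiguousarray(view),
                patch_index=idx,
                extra={"y0": y0, "x0": x0},
                **provenance,
            )
        )
    return patches


def write_patch_tiff(patch: MPTPatch, path) -> None:
    """Write a patch as a 3-page TIFF (one page per channel) with its
    provenance JSON-encoded in the image description tag."""
    desc = json.dumps(patch.provenance())
    tifffile.imwrite(path, np.moveaxis(patch.pixels, -1, 0), description=desc, photometric="minisblack")


def read_patch_tiff(path) -> MPTPatch:
    with tifffile.TiffFile(path) as tf:
        pixels = np.moveaxis(tf.asarray(), 0, -1)
        desc = tf.pages[0].description
    prov = json.loads(desc) if desc else {}
    prov.pop("y0", None)
    return MPTPatch(pixels=pixels, **{k: v for k, v in prov.items() if v is not None})


def write_manifest(table: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    table.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Raises :class:`ManifestError` naming the offending column or rows on
    schema violations (missing columns, duplicated frame keys, inconsistent
    per-subject diagnosis).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    key = ["subject_id", "stack_id", "frame_index"]
    if "patch_index" in df.columns:
        key.append("patch_index")
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ManifestError(f"duplicate manifest key at row(s) {list(df.index[dup])[:5]}")
    bad = df.groupby("subject_id")["diagnosis"].nunique()
    bad = bad[bad > 1]
    if len(bad):
        raise ManifestError(f"inconsistent diagnosis for subject(s): {list(bad.index)}")
    return df
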