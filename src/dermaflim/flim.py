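"""Per-pixel fluorescence-lifetime (FLIM) analysis of TCSPC photon decays.

The tissue autofluorescence decay is modelled as a two-component exponential

    F(t) = a1 * exp(-t / tau1) + a2 * exp(-t / tau2),    a1 + a2 = 1,

where the short component (tau1, typically ~0.4 ns) is attributed to free
NAD(P)H and the long component (tau2, ~2.5 ns) to its protein-bound form.
The amplitude-weighted mean lifetime

    tau_m = a1 * tau1 + a2 * tau2

and the amplitude ratio a1/a2 summarise the free/bound balance, an indirect
readout of cellular metabolic activity.

Fitting is weighted nonlinear least squares on the decay tail (from the
histogram maximum onward), with Poisson weights max(count, 1), the a1+a2=1
constraint built into the parameterisation, and box bounds on the lifetimes.
Pixels below a photon threshold are masked rather than fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = [
    "PhotonDecayCube",
    "FlimMaps",
    "FitConfig",
    "FitResult",
    "BelowThresholdError",
    "FitError",
    "bin_pixels",
    "fit_biexponential",
    "mean_lifetime",
    "component_ratio",
    "fit_map",
    "fit_stack",
]


class BelowThresholdError(ValueError):
    """Histogram carries too few photons for a reliable bi-exponential fit."""


class FitError(RuntimeError):
    """The optimiser failed to converge after all restarts."""


@dataclass
class PhotonDecayCube:
    """Per-pixel TCSPC arrival-time histograms for one en-face frame.

    Attributes
    ----------
    counts : (H, W, T) array
        Non-negative photon counts per pixel and time bin.
    t_ns : (T,) array
        Bin centers in nanoseconds, strictly increasing and uniformly spaced.
    meta : dict
        Free-form provenance (field size, depth, subject/stack ids ...).
    """

    counts: np.ndarray
    t_ns: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.t_ns = np.asarray(self.t_ns, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (H, W, T) array")
        if self.counts.shape[-1] != self.t_ns.shape[0]:
            raise ValueError("time axis length mismatch between counts and t_ns")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        dt = np.diff(self.t_ns)
        if not np.all(dt > 0):
            raise ValueError("t_ns must be strictly increasing")
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("t_ns must be uniformly spaced")

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def total_counts(self) -> np.ndarray:
        """Per-pixel photon totals (the AF intensity image)."""
        return self.counts.sum(axis=-1)


@dataclass
class FlimMaps:
    """Per-pixel bi-exponential fit results for one frame.

    On ``fit_mask`` pixels: a1 + a2 == 1, tau1 <= tau2 and
    tau_m = a1*tau1 + a2*tau2 lies between the two component lifetimes.
    Masked (unfit) pixels hold NaN in the parameter maps.
    """

    a1: np.ndarray
    a2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    ratio: np.ndarray
    intensity: np.ndarray
    fit_mask: np.ndarray
    goodness: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.a1.shape


@dataclass(frozen=True)
class FitConfig:
    """Batch-wide fitting parameters, fixed once per batch.

    bin_radius       square pixel-binning radius (0 = no binning)
    photon_threshold minimum photons in a (binned) histogram to attempt a fit
    init             starting point (a1, tau1_ns, tau2_ns)
    tau_bounds       box bounds on both lifetimes, ns
    ratio_cap        saturation value reported for a1/a2 when a2 == 0
    max_starts       extra optimiser restarts on non-convergence
    """

    bin_radius: int = 1
    photon_threshold: float = 300.0
    init: tuple = (0.7, 0.4, 2.5)
    tau_bounds: tuple = (0.05, 10.0)
    ratio_cap: float = 1e3
    max_starts: int = 3


@dataclass(frozen=True)
class FitResult:
    a1: float
    tau1: float
    a2: float
    tau2: float
    tau_m: float
    goodness: float
    n_photons: float


def bin_pixels(cube: PhotonDecayCube, radius: int) -> PhotonDecayCube:
    """Sum each pixel's histogram over its (2*radius+1)^2 square neighborhood.

    Binning trades lateral resolution for photon statistics so that the
    bi-exponential fit is well conditioned. The neighborhood is clipped at
    the frame edge; output dimensions equal input dimensions, and radius 0
    is the identity.
    """
    if radius < 0:
        raise ValueError(f"binning radius must be >= 0, got {radius}")
    if radius == 0:
        return replace(cube, counts=cube.counts.copy(), meta=dict(cube.meta))
    h, w, _ = cube.counts.shape
    # 2-D summed-area table per time bin; exact for integer counts.
    sat = np.zeros((h + 1, w + 1) + cube.counts.shape[2:], dtype=np.int64)
    sat[1:, 1:] = cube.counts.cumsum(axis=0).cumsum(axis=1)
    y0 = np.clip(np.arange(h) - radius, 0, h)
    y1 = np.clip(np.arange(h) + radius + 1, 0, h)
    x0 = np.clip(np.arange(w) - radius, 0, w)
    x1 = np.clip(np.arange(w) + radius + 1, 0, w)
    out = (
        sat[y1[:, None], x1[None, :]]
        - sat[y0[:, None], x1[None, :]]
        - sat[y1[:, None], x0[None, :]]
        + sat[y0[:, None], x0[None, :]]
    )
    meta = dict(cube.meta)
    meta["bin_radius"] = meta.get("bin_radius", 0) + radius
    return replace(cube, counts=out, meta=meta)


def _biexp_model(t: np.ndarray, scale: float, a1: float, tau1: float, tau2: float) -> np.ndarray:
    return scale * (a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2))


def fit_biexponential(
    histogram: np.ndarray,
    t_ns: np.ndarray,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one decay histogram to the two-component model.

    The tail from the histogram maximum onward is fitted (no instrument
    response deconvolution); the overall photon scale is a free nuisance
    parameter while a1 is fitted directly so a1 + a2 = 1 holds by
    construction. Components are reported ordered tau1 <= tau2.

    Raises
    ------
    BelowThresholdError
        If total counts fall below ``config.photon_threshold``.
    FitError
        If the optimiser fails for every restart.
    """
    cfg = config or FitConfig()
    histogram = np.asarray(histogram, dtype=float)
    t_ns = np.asarray(t_ns, dtype=float)
    total = float(histogram.sum())
    if total < cfg.photon_threshold:
        raise BelowThresholdError(
            f"{total:.0f} photons < threshold {cfg.photon_threshold:.0f}"
        )

    # Tail fit from the histogram maximum onward, on the absolute time axis:
    # amplitudes are then referenced to t = 0, matching the generating model
    # exactly on noise-free decays.
    i0 = int(np.argmax(histogram))
    t = t_ns[i0:]
    y = histogram[i0:]
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))  # Poisson weights

    lo_t, hi_t = cfg.tau_bounds
    lower = np.array([1e-12, 0.0, lo_t, lo_t])
    upper = np.array([np.inf, 1.0, hi_t, hi_t])

    def residuals(p):
        return (_biexp_model(t, *p) - y) * w

    a1_0, t1_0, t2_0 = cfg.init
    starts = [(max(y[0], 1.0), a1_0, t1_0, t2_0)]
    # restarts bracket the component split and lifetimes differently
    starts += [
        (max(y[0], 1.0), 0.3, 0.5 * t1_0, 2.0 * t2_0),
        (max(y[0], 1.0), 0.9, 2.0 * t1_0, 0.5 * t2_0),
    ][: max(cfg.max_starts - 1, 0)]

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(residuals, p0, bounds=(lower, upper), method="trf")
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and best is res:
            break
    if best is None:
        raise FitError("bi-exponential fit failed for all starts")

    scale, a1, tau1, tau2 = best.x
    a2 = 1.0 - a1
    if tau1 > tau2:  # enforce the short-component-first convention
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
    if (tau2 - tau1) / tau2 < 0.02:
        # the two components collapsed: the split is unidentifiable, so the
        # fit is reported as effectively mono-exponential
        tau1 = tau2 = a1 * tau1 + a2 * tau2
        a1, a2 = 1.0, 0.0
    dof = max(t.size - 4, 1)
    chi2 = float(2.0 * best.cost / dof)
    return FitResult(
        a1=float(a1),
        tau1=float(tau1),
        a2=float(a2),
        tau2=float(tau2),
        tau_m=float(a1 * tau1 + a2 * tau2),
        goodness=chi2,
        n_photons=total,
    )


def mean_lifetime(a1, tau1, a2, tau2, *, atol: float = 1e-6):
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + a2*tau2.

    Requires a1 + a2 = 1 within ``atol`` and positive lifetimes. Accepts
    scalars or broadcastable arrays.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    tau1 = np.asarray(tau1, dtype=float)
    tau2 = np.asarray(tau2, dtype=float)
    if np.any(np.abs(a1 + a2 - 1.0) > atol):
        raise ValueError("relative amplitudes must satisfy a1 + a2 = 1")
    if np.any(tau1 <= 0) or np.any(tau2 <= 0):
        raise ValueError("lifetimes must be positive")
    out = a1 * tau1 + a2 * tau2
    return float(out) if out.ndim == 0 else out


def component_ratio(a1, a2, *, cap: float = 1e3):
    """Short-to-long amplitude ratio a1/a2.

    When a2 == 0 the ratio saturates at ``cap`` (a documented sentinel, not
    infinity) so downstream image channels stay finite. If both amplitudes
    are zero the ratio is undefined and reported as NaN.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if np.any(a2 < 0):
        raise ValueError("a2 must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a2 > 0, a1 / np.maximum(a2, 1e-300), cap)
    out = np.where((a1 == 0) & (a2 == 0), np.nan, out)
    out = np.minimum(out, cap)
    return float(out) if out.ndim == 0 else out


def fit_map(cube: PhotonDecayCube, config: FitConfig | None = None) -> FlimMaps:
    """Fit every pixel of a decay cube, producing per-pixel parameter maps.

    Pixel binning is applied first (``config.bin_radius``); pixels whose
    binned histogram stays below the photon threshold are masked out of the
    maps (NaN), never zero-filled.
    """
    cfg = config or FitConfig()
    binned = bin_pixels(cube, cfg.bin_radius)
    h, w, _ = binned.counts.shape
    shape = (h, w)
    nan = np.full(shape, np.nan)
    maps = FlimMaps(
        a1=nan.copy(),
        a2=nan.copy(),
        tau1=nan.copy(),
        tau2=nan.copy(),
        tau_m=nan.copy(),
        ratio=nan.copy(),
        intensity=cube.total_counts().astype(float),
        fit_mask=np.zeros(shape, dtype=bool),
        goodness=nan.copy(),
        meta=dict(cube.meta),
    )
    totals = binned.total_counts()
    for iy in range(h):
        for ix in range(w):
            if totals[iy, ix] < cfg.photon_threshold:
                continue
            try:
                r = fit_biexponential(binned.counts[iy, ix], binned.t_ns, cfg)
            except (BelowThresholdError, FitError) as exc:
                log.debug("pixel (%d, %d) unfit: %s", iy, ix, exc)
                continue
            maps.a1[iy, ix] = r.a1
            maps.a2[iy, ix] = r.a2
            maps.tau1[iy, ix] = r.tau1
            maps.tau2[iy, ix] = r.tau2
            maps.tau_m[iy, ix] = r.tau_m
            maps.ratio[iy, ix] = component_ratio(r.a1, r.a2, cap=cfg.ratio_cap)
            maps.goodness[iy, ix] = r.goodness
            maps.fit_mask[iy, ix] = True
    return maps


def fit_stack(cubes, config: FitConfig | None = None) -> list:
    """Batch-process a sequence of decay cubes with identical parameters.

    Mirrors unattended batch analysis: one FitConfig for the whole stack,
    per-pixel failures are masked and logged, and only structural errors
    (malformed cubes) abort the run.
    """
    cfg = config or FitConfig()
    out = []
    for i, cube in enumerate(cubes):
        log.info("fitting frame %d/%d", i + 1, len(cubes))
        out.append(fit_map(cube, cfg))
    return out
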