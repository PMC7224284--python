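# Methods

## The decay model and its fit

Per-pixel TCSPC histograms are modelled as a two-component exponential
mixture, F(t) = a1·e^(−t/τ1) + a2·e^(−t/τ2) with a1 + a2 = 1. The fit is
weighted nonlinear least squares (trust-region reflective with box bounds,
via `scipy.optimize.least_squares`) on the decay tail from the histogram
maximum onward, with Poisson weights 1/√max(count, 1). Three choices matter:

* **a1 + a2 = 1 is enforced inside the parameterisation** (only a1 is a free
  parameter, plus an overall photon scale), so the normalization invariant
  holds by construction rather than by post-hoc renormalisation.
* **The time axis is absolute**, not re-zeroed at the tail start. Shifting
  the origin rescales the two amplitudes by e^(−t0/τi) and would bias a1 by
  ~1.5% per time bin; on the absolute axis a noise-free decay is recovered
  to four significant digits.
* **Degenerate fits collapse**: when the two lifetimes converge to within
  2% the split between them is unidentifiable, and the result is reported
  as mono-exponential (a1 = 1, τ1 = τ2 = τm).

Initialization is (a1, τ1, τ2) = (0.7, 0.4 ns, 2.5 ns) with lifetimes
bounded to [0.05, 10] ns; on non-convergence two further starts bracket the
component split from either side. There is no instrument-response
deconvolution and no incomplete-decay (periodic excitation) correction: the
synthetic decays are truncated at the 12.5 ns laser period (80 MHz), which
keeps the simulation an exact oracle for the fitter. Pixels with fewer than
300 photons after binning are masked, never zero-filled. Pixel binning sums
the (2r+1)² neighborhood, edge-clipped, via a summed-area table (exact for
integer counts).

Measured recovery envelope (200 random pixels per level, seeded): median
relative τm error ≈ 0.6% at 10⁵ photons and ≈ 4% at 10⁴ photons — well
inside the 5% / 15% envelopes the test suite enforces.

## The synthetic cohort

The generator emulates the *structure* of a 10-subject forearm MPT study
(6 AD / 4 healthy, up to three 160×160 µm z-stacks per subject, 5 µm steps
to 100 µm), not any real subject's data. Depth follows the epidermal
sequence; each layer sets a mean lifetime (corneum 1.6 ns, granulosum
1.25 ns, spinosum 1.15 ns, basale 0.85 ns, dermis 1.45 ns) and an intensity
level. Subject (σ = 0.04 ns), stack (0.02 ns) and frame (0.02 ns) random
effects are added on top, so observations within a subject are correlated —
which is why group statistics treat the *subject* as the exchangeable unit.

A single per-pixel field, the short-component amplitude a1, drives both
image channels: τm = a1τ1 + (1−a1)τ2 and ratio = a1/(1−a1). Intensity is
rendered from a Voronoi cell mosaic (jittered-grid seeds, ~20 µm pitch)
with dark 5 µm-radius nuclei, dim cell borders, and mitochondria drawn as
discrete bright puncta (Poisson ~28 per cell, Gaussian-splatted at 0.6 µm).

Disease effects:

* **Perinuclear clustering** (strength c ∈ [0, 1]): a fraction c of each
  cell's puncta is relocated from the uniform cytoplasm distribution to a
  ring at the nuclear boundary. The published phenotype is a visually
  evident accumulation, so the default c = 0.6 makes the ring apparent but
  leaves 40% of puncta dispersed. Applied to all nucleated layers of AD
  subjects.
* **Granulosum τm reduction** (default 0.15 ns) in AD.
* **Epidermal thickening** (default 10 µm) widens the AD spinosum, pushing
  the basale below the imaged healthy-basale depth.
* **Melanin signature**: the basale's low τm / high a1/a2 (melanin is a
  short-lifetime emitter) appears near 35 µm in healthy skin and
  correspondingly deeper in AD.

With all effect sizes zero, nothing in the generative path reads the
diagnosis label, so the null cohort is exchangeable by construction; this
is what the Mann-Whitney calibration check exercises.

Raw data are sampled on demand: expected photons per pixel equal
`photon_budget × intensity` (budget 3000 by default — a realistic binned-
pixel count), arrival times follow the pixel's mixture over 256 bins (a
common TCSPC depth; the bin count is configurable), and counts are Poisson.
Cube sampling is chunked by image row to bound memory at large fields.

## Patching and normalization

Frames are cut into a symmetric 3×3 grid of 200×200 px patches with stride
⌊(side−200)/2⌋ — nine patches of 62.5 µm side cannot tile a 160 µm field
disjointly, so overlap is unavoidable; the symmetric layout was chosen for
even coverage. Channels are normalized to [0, 1]: intensity by the frame's
1st-99th percentiles (robust to hot pixels), τm clipped to [0, 5] ns, a1/a2
clipped to [0, 20]. Unfit pixels are zeroed in the lifetime channels with
the mask retained in provenance.

## The classifier and its training

The backbone is a small densely-connected CNN: a fixed 4×4 average-pool
brings the 200 px patch to a 50 px working resolution, then four dense
blocks (3×3 convolution → batch-norm → ReLU, output concatenated onto the
block input, growth 8) with 2×2 max-pool transitions, global average
pooling, a 16-unit fully connected layer, dropout, and a single sigmoid
unit. Everything — forward, backward, SGD with momentum, Adam, batch-norm,
dropout — is implemented in numpy inside `dermaflim.nn`; batch-norm is what
lets plain SGD train the convolutions from random initialization (without
it the conv-layer gradients are orders of magnitude smaller than the
head's).

Training details:

* class-weighted binary cross-entropy (inverse class frequency, so each
  class contributes equal summed weight), minimised with Adam (lr 10⁻³) by
  default — training from random initialization with plain SGD proved
  unreliable (some cross-validation folds never left the initial loss
  plateau); SGD with momentum remains available for the fine-tuning regime
  the head-replacement workflow was designed for;
* augmentation of the training set only, at the working resolution —
  block-average pooling commutes with the dihedral group, so inputs are
  pooled once and augmented after, an exact equivalence for the dihedral
  ops and a 16× cost reduction. Two modes: the full augmentation set
  (8 dihedral variants, plus any configured re-scalings) materialised once
  and shuffled through every epoch — the default, and what makes the
  texture filters learn reliably from ~100 training patches — or one
  random variant per sample per epoch for cheap tasks like the cell gate;
* grid search over dropout rate, learning rate and momentum, selected by
  tuning loss; early stopping with patience 12, armed only after a burn-in
  (the randomly initialized network sits on a loss plateau before the
  texture filters differentiate). A tuning subject necessarily carries a
  single diagnosis, and a binary cross-entropy evaluated on one class alone
  is minimised by a constant always-that-class predictor — so whenever the
  tuning set is single-class the selection metric adds the class-balanced
  training loss, which a degenerate constant model cannot minimise;
* multi-start: if a grid point's best tuning loss stays above 0.45 the
  optimiser is considered stuck in a degenerate (constant-output) optimum
  and is retried from a fresh seeded initialization, up to twice — the same
  philosophy as the lifetime fitter's restarts.

Cross-validation is strictly subject-wise: each subject tests exactly once,
a second subject is held out for tuning, the rest train. For very small
cohorts the tune draw avoids removing the last subject of a diagnosis from
the training set (with 10 subjects the constraint never binds). The AD
stage trains on expert-labelled living-cell patches; at inference the
stage-1 gate (threshold 0.5, ties gate through) decides which patches reach
it — the cascade's deployment semantics, also used when computing the AD
metrics.

## Uncertainty and relevance

Monte-Carlo dropout keeps the dropout mask stochastic at inference: 50
calls by default, mean = prediction, sample SD (n−1) = uncertainty, all
seeded. Metric confidence intervals re-evaluate each metric once per call
and report mean ± SD plus the 2.5-97.5 percentile interval.

Deep Taylor decomposition explains the pre-sigmoid logit of the predicted
class (the sigmoid is not conserved under propagation; for a negative
prediction the head's sign is flipped so the explained evidence is
positive). Hidden layers use the z⁺ rule, the first parametric layer the
z^B rule with the known [0, 1] input bounds; max-pooling routes relevance
to the winning input, average pooling proportionally to its (non-negative)
inputs; batch-norm is folded into the adjacent convolution's weights before
applying the rule; dropout is disabled. On bias-free ReLU networks the
propagation is conservative to < 10⁻⁴ relative; biases absorb relevance,
and that leakage is logged rather than renormalised away. Renderings:
relevance overlay with alpha proportional to magnitude on the AF-intensity
base, and a per-modality composite (red = τm, green = a1/a2, blue =
intensity) smoothed by a 5 px Gaussian for display only.

## Statistics

Depth profiles are aligned at the stratum granulosum (0 µm); corneum frames
are excluded as dead tissue. Group comparisons use the two-sided
Mann-Whitney U test — exact enumeration when both samples have ≤ 8
observations and no ties, the tie-corrected normal approximation otherwise
(`scipy.stats.mannwhitneyu`). The significance threshold defaults to
α = 0.05 and is configurable. Comparisons aggregate to one observation per
subject, because subject random effects make within-subject frames
correlated; at stack level the test would be anti-conservative.

Confusion metrics follow the standard definitions with the F-score as the
harmonic mean of PPV and sensitivity; metrics with empty denominators are
reported as explicit nulls, never as zero. ROC curves use a threshold sweep
with trapezoidal AUC (equal to the concordant-pair probability, which the
test suite verifies by brute force); PR AUC uses the step-wise
average-precision rule, since trapezoids over PR curves are biased.

## Problem sizes

The end-to-end benchmark evaluates the cascade on a cohort of 10 subjects
(6 AD / 4 healthy) with two stacks each, twelve depths (0-55 µm, covering
every layer for both groups), and frames rendered directly at the patch
geometry (200 px = 62.5 µm, one patch per frame; 240 patches total). These
sizes keep the 20 CNN trainings of the subject-wise LOOCV on one CPU at
about fifteen minutes while preserving the subject/stack/depth structure.
Unit tests use 64 px fields and 4-subject cohorts; the decay-cube fitting
path is exercised on cropped fields (the per-pixel optimiser, not the
renderer, is the expensive part).

## What the synthetic results do and do not show

Passing tests demonstrate that the pipeline is correct and self-consistent:
the fitter recovers known decays, the cascade learns the generator's
disease effects under leakage-free cross-validation, uncertainty and
relevance obey their contracts. They do not certify clinical performance —
the synthetic cohort has idealised morphology (convex cells, isotropic
puncta, no motion artefacts, no SHG/collagen channel, no optical PSF), its
disease effects are homogeneous across subjects, and the private study
cohort's headline metrics are not reproducible from it. The generator's
stack-count jitter, layer depths and photon budgets emulate the study
design, not its images.

## Known limitations

* No instrument response function and no incomplete-decay correction; real
  TCSPC data with a wide IRF would need both.
* The pretrained-backbone option of the published workflow is not
  implemented; the small backbone trains from random initialization.
* Granulosum localization in real data must be operator-supplied in the
  manifest; the package does not auto-detect it.
* The printed significance threshold in the source study ("p < 0.5") is
  treated as a typo for α = 0.05; α is configurable.
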