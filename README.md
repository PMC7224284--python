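# dermaflim

Automatic analysis of multiphoton tomography (MPT) fluorescence-lifetime
imaging of human skin, aimed at the diagnosis of atopic dermatitis (AD) —
the most common chronic inflammatory skin disease — without operator
intervention.

MPT with time-correlated single photon counting (TCSPC) records, for every
pixel of an en-face skin image, a histogram of photon arrival times. The
NAD(P)H autofluorescence decay is modelled as a two-component exponential

```
F(t) = a1 · exp(-t/τ1) + a2 · exp(-t/τ2),     a1 + a2 = 1,
```

where the short component (τ1 ≈ 0.4 ns, free NAD(P)H) and long component
(τ2 ≈ 2.5 ns, protein-bound NAD(P)H) split the signal between metabolic
states. The amplitude-weighted mean lifetime **τm = a1·τ1 + a2·τ2** and the
amplitude ratio **a1/a2** are the standard metabolic readouts. Each imaged
frame is summarised into 200×200 px patches with three channels — AF
intensity, τm, a1/a2 — which feed a two-stage convolutional cascade:

1. **cell gate** — does the patch show living epidermal cells?
2. **diagnosis** — if so, is the skin AD-affected or healthy?

Training is subject-wise leave-one-out cross-validation (one subject held
out for testing, another for tuning; grid search with early stopping;
class-weighted binary cross-entropy; dihedral + scaling augmentation of the
training set only; Adam by default for from-scratch training, SGD with
momentum available for fine-tuning). Prediction keeps dropout active and aggregates 50
stochastic forward passes: the mean is the predicted probability, the
standard deviation its uncertainty. Deep Taylor decomposition propagates
the decision logit back to the input pixels (z⁺ rule in hidden layers, z^B
at the bounded input), yielding per-pixel, per-modality relevance heatmaps.

Because clinical MPT cohorts are private, the package ships a synthetic
cohort generator with full ground truth: epidermal layers by depth (stratum
corneum → granulosum → spinosum → basale → dermis), Voronoi cell morphology
with dark nuclei and mitochondrial puncta, raw per-pixel TCSPC photon
cubes, and tunable disease effects (perinuclear mitochondrial clustering,
granulosum τm reduction, epidermal thickening, the healthy-only melanin
signature near 35 µm). All randomness is seeded; every stage is exactly
reproducible.

## Worked example

```python
import numpy as np
from dermaflim import flim, synthetic

# a bi-exponential pixel at 10^5 photons
nt = 256; t = (np.arange(nt) + 0.5) * (12.5 / nt)
shape = 0.7 * np.exp(-t / 0.4) + 0.3 * np.exp(-t / 2.5)
hist = np.random.default_rng(0).poisson(1e5 * shape / shape.sum())
fit = flim.fit_biexponential(hist, t)
print(f"a1={fit.a1:.3f} tau1={fit.tau1:.3f} tau2={fit.tau2:.3f} tau_m={fit.tau_m:.3f}")
# a1=0.685 tau1=0.396 tau2=2.483 tau_m=1.054
```

The generating truth is τm = 0.7·0.4 + 0.3·2.5 = 1.03 ns; the fit recovers
it within ~2% at this photon budget. On noise-free decays the fit
reproduces the generating parameters to four significant digits.

The full pipeline runs from a YAML config:

```bash
dermaflim run --config examples/pipeline.yml --seed 1 --out out/
```

which simulates a cohort, demonstrates per-pixel lifetime fitting on raw
photon cubes, cuts and normalizes patches, trains the cascade per
cross-validation fold, predicts with Monte-Carlo dropout, renders deep
Taylor heatmaps, and writes a metrics report (accuracy, balanced accuracy,
sensitivity, specificity, PPV, NPV, F-score, ROC/PR AUCs, inter-stack and
inter-subject accuracy SD). Each stage directory carries a `manifest.json`
with the config hash and seed for provenance.

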