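# Methods

This note records the models implemented in `sersml`, the assumptions behind
the synthetic data, the numerical choices, and what the test results do and
do not establish about real measurements.

## Synthetic SERS spectra

Real input to this kind of analysis is a set of SERS spectra of
extracellular-vesicle (EV) samples on a gold-nanoparticle colloid. The
generator emulates the statistical structure such data presents to the
analysis chain; it is not a physical electromagnetic model.

Each spectrum on the default axis (400–3200 cm⁻¹ at 2 cm⁻¹ dispersion, 1401
points) is

```
x(ν) = poly(ν) + g · [ hump(ν) + Σ_b L(ν; c_b, w_b, A_b) ] + ε(ν) + spikes
```

* **Bands** `L` are Lorentzians (the natural Raman line shape) at the eight
  wavenumbers assigned to lipid/protein vibrations (493, 741, 1011, 1078,
  1221, 1349, 1437, 2913 cm⁻¹), FWHM 12 cm⁻¹. Mean amplitudes are scaled so
  the strongest band (C–H stretching at 2913 cm⁻¹) has signal-to-noise ≈ 10;
  each drawn amplitude has a 5% coefficient of variation (sample-to-sample
  chemical variability).
* **Class contrasts.** The cancer-like preset sits 30% above the common mean
  at 1349/1437 cm⁻¹ (collagen/adenine-related and lipid CH₂ bands) and 30%
  below at 1078/1221 cm⁻¹; the normal-like preset mirrors it. The three
  interference presets (kidney-, cervix-, liver-like) carry stronger
  (±40–50%) four-band signatures: EVs from different tissue origins differ
  more than the same-tissue cancer/normal pair, which is why the five-class
  task ends up easier than the binary one.
* **Enhancement variability** `g` is a per-spectrum lognormal factor (mean 1,
  sd 0.25) multiplying every band and the citrate hump. It models
  hotspot-to-hotspot enhancement differences between samples and is the
  dominant variance component, making PC1 the common-intensity axis — the
  structure the PCA step presumes.
* **Baseline** is a gentle cubic drift (~20 counts over the axis) plus a
  broad Gaussian hump at 1598 cm⁻¹ (σ = 150 cm⁻¹, height 40), mimicking the
  citrate background of AuNP colloids.
* **Noise and spikes**: i.i.d. Gaussian noise (sd 10 counts) and Poisson
  cosmic-ray spikes (rate 0.1 per spectrum, single-point, 400–1200 counts).

Every output is a pure function of (inputs, seed): each spectrum consumes
independent child streams for amplitudes, noise, and spikes, so a mixture at
fraction 1 reproduces the pure simulation bit for bit.

**What the generator does not emulate:** wavenumber calibration drift,
detector etaloning, correlated (1/f) noise, band-shape changes, peak shifts,
or any concentration–intensity calibration. Passing recovery tests on this
generator shows the pipeline correctly extracts band-amplitude structure
buried under baseline, noise and enhancement variability; it does not show
that real EV classes are separable at these accuracies.

## Preprocessing

Order: despike → MPLS baseline removal → DFT smoothing (matching the
measurement-cleanup order the models assume). No intensity normalization by
default; `normalize=True` adds per-spectrum max-normalization.

* **Despike** (cosmic-ray removal; the method is our choice): Hampel-style
  windowed modified z-score, window 5 points, threshold 8. The local MAD of a
  5-point window is itself very noisy, so it is floored at the global median
  window-MAD — without this, ordinary noise occasionally exceeds any
  threshold. Flagged points are replaced by the median of unflagged window
  values, which makes the filter idempotent in practice. Boundaries use
  reflect padding so an edge spike does not vote for itself.
* **MPLS**: the background contour is a grey-scale morphological opening with
  a flat 75-point structuring element, refined by a weighted Whittaker
  smoother (penalty λ = 10, first differences). Weights are 1 where the
  opening tracks the spectrum (|residual| ≤ 3 robust sigma), 0.001 over peak
  regions, and forced to 1 on the first/last ⌈n/2000⌉ points. Two numerical
  refinements: the opening is computed on a 9-point median-presmoothed copy
  (otherwise it rides the lower noise envelope and injects spectrum-to-
  spectrum low-frequency variance), and the signal is extended by linear
  extrapolation over one structuring-element width at each end (otherwise the
  flat element clips sloped baselines at the boundaries). `corrected` is
  exactly `input − baseline`.
* **DFT smoothing**: multiply the spectrum's DFT by a low-pass window — unity
  up to (cutoff − rolloff)·Nyquist, raised-cosine taper to zero at
  cutoff·Nyquist (defaults 0.15 and 0.05) — and invert. The Tukey taper
  avoids ringing; DC is always in the passband, so the spectrum mean is
  preserved exactly. Equivalent to circular convolution with the window's
  impulse response (the oracle used in tests).

## PCA

Centering only, no variance scaling (standard for intensity matrices). Fitted
by SVD; loading signs are fixed so each component's largest-magnitude element
is positive. Defaults: k = 2 ahead of the binary SVM, full spectra for the
CNN.

## SVM

Dual soft-margin SVM solved by SMO with second-order working-set selection
(the most-violating "up" index paired with the maximal-gain "low" index),
implemented as a numba-compiled loop. Stopping: KKT gap below
1e-7 · max(1, C · max|K|) in score units, or 10⁴ passes (n pair updates
each). The bias is the mean of `y − f` over free support vectors. Kernel
scale s divides features before inner products (gaussian kernel
`exp(−‖x−z‖²/s²)`); multiclass is one-vs-one with majority voting, ties going
to the smallest class index.

Bayesian hyperparameter search minimises the 5-fold CVloss over
log₁₀C, log₁₀s ∈ [−3, 6]²: 5 seeded uniform starts, then a squared-
exponential Gaussian-process surrogate (small white-noise jitter,
normalised outputs) with plain expected-improvement acquisition maximised
over 1024 seeded candidates per iteration, 30 evaluations total. Plain EI is
used rather than any time-penalised variant because wall-clock terms are
hardware-dependent and irrelevant to correctness. Platt calibration maps
scores to posteriors by regularised maximum likelihood with the standard
(N₊+1)/(N₊+2), 1/(N₋+2) target smoothing.

## CNN

Layers: conv1d(8 filters, width 9) → ReLU → maxpool(4) → conv1d(16, 9) →
ReLU → maxpool(4) → fully-connected(d) → softmax, trained with Adam (β₁ 0.9,
β₂ 0.999), initial learning rate 0.01, batch 16, fixed 60 epochs, no early
stopping. The layer sizes are our design: at 2 cm⁻¹ dispersion a 12 cm⁻¹
band spans ~6 grid points, so the signal is heavily oversampled and pooling
width 4 matches the information density while keeping desk-scale training
fast; wider stacks gave no accuracy benefit on the synthetic presets. Input
spectra are per-spectrum max-normalized (which also cancels the enhancement
factor g). Weight initialisation is He-scaled and, with shuffling, fully
seeded — identical seeds give identical weights. Gradients are hand-derived
and verified against central finite differences.

## Evaluation

The pooled set (not each class) is shuffled and split 60/10/30; train and
validation sizes are `round(n·f)` and the test set absorbs the remainder, so
2700 spectra give 1620/270/810. Percentages are rounded half-up to one
decimal for reporting; raw fractions are kept alongside and used in any
further computation. ROC is swept over all thresholds with trapezoidal AUC,
which equals Mann–Whitney concordance with ties counted one half; multiclass
ROC is one-vs-rest. A class absent from the truth gets recall `None`
(undefined), never 0.

## Interpretation

Shapley values use the interventional convention: a feature absent from a
coalition is imputed from background rows (a seeded subsample of ≤ 100
training spectra). Exact enumeration is limited to 12 features; beyond that a
permutation-sampling estimator is used, which also reports per-feature
Monte-Carlo standard errors. For a PCA+SVM model the explained function is
the decision score as a function of wavenumber intensities (mapping through
the PCA projection), so rankings are reported in cm⁻¹. PDP curves average the
model over the data with one feature clamped to a grid; grids outside the
observed feature range trigger a warning.

## Problem sizes and expected numbers

The synthetic study uses the class sizes of the study design: 135 spectra
per class, 60/10/30 split. On these conditions the PCA(2) + Bayes-optimized
SVM typically reaches 95–100% two-class test accuracy and the CNN 95–99%
five-class accuracy; multi-seed recovery checks in the test suite require
≥ 95% on at least 8 of 10 seeds. The four-ratio mixture task
(99:1/90:10/75:25/50:50) lands near 50–60% accuracy: adjacent ratios differ
only by fractions of the pure-class contrast, which at the generator's SNR is
close to the noise floor — a known desk-scale limitation of the synthetic
analogue, not of the code path.

## Known limitations

* The SMO tolerance is scaled by C·max|K|; at extreme C (≥ 10⁶) with large
  feature magnitudes the solver may stop on the pass cap and the returned
  dual is only approximately optimal (CVloss-guided search steers away from
  such corners).
* Exact Shapley cost grows as 2^p · |background|; at the 12-feature cap with
  100 background rows this is ~4·10⁵ model evaluations per query.
* The CNN is CPU/numpy; it is deterministic and fast at spectrum scale but
  not meant for large images or GPU workloads.
* The generator's lognormal enhancement factor is independent across spectra;
  real substrates can drift systematically within a session, which no test
  here covers.
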