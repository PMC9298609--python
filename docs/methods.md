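# Methods

`nircal` implements the complete analysis chain used to calibrate a portable
Vis/NIR spectrometer against soluble solids content (SSC, °Brix) in fruit:
instrument transform and cropping, spectral pretreatment, sample-set
partitioning, three calibration model families, wavelength selection, model
evaluation, and a resampling stability protocol. This note records the models,
their assumptions, the defaults and why they were chosen, and what the
synthetic test bed does and does not establish.

## Spectral model and instrument transform

The device records a raw reflectance spectrum `R`, a dark reference `D`
(source off) and a white reference `W` (source on, no sample); all modelling
uses the relative spectrum `Rc = (R − D) / (W − D)`, channel-wise on a fixed
grid. Both spectral ends are noisy on hardware of this class, so the working
range is a closed-interval crop (default 550–1,000 nm). Cropping and the
transform commute, which the tests assert.

## Pretreatment

Six pipelines are supported: `none`, `sg`, `sg-msc`, `sg-snv`, `d1-sg-msc`,
`d2-sg-msc`. Savitzky-Golay (SG) filtering uses window 11 and polynomial
order 2 by default — a standard choice at 2 nm channel spacing, wide enough to
suppress white noise without flattening the ~30 nm-wide overtone bands; both
are configurable. Derivatives come from the SG polynomial itself (never finite
differences) and are scaled by the channel spacing, so first-derivative units
are per nm. SNV centres each spectrum and scales it to unit sample (n−1)
standard deviation. MSC regresses each spectrum on a reference (the mean
*calibration* spectrum after any upstream steps), then inverts the fitted
slope and offset; the reference is learned from calibration rows only, so
held-out samples never leak into the fitted state. `sg-msc` is the package
default for downstream stages, as the pretreatment-comparison stage selects it
on the synthetic population.

## Partitioning

Kennard-Stone (KS) selects calibration samples by max–min Euclidean distance:
the first two picks are the farthest pair, each later pick maximises the
minimum distance to the selected set. Ties break toward the lowest sample
index, making the split fully deterministic (duplicate rows are legal). The
study workflow computes one KS split (default 90/30 on 120 samples) and
freezes it for every model comparison; only the stability protocol re-draws
random 3:1 splits. KS distances are computed on whatever representation the
caller passes — the workflow uses the cropped raw spectra.

## Calibration models

**PLS** (univariate y) is NIPALS with X- and y-deflation: X = T Pᵀ + E,
y = U qᵀ + F, regression through the R-weights so the coefficient vector maps
centred X to centred y. X and y are mean-centred, never autoscaled (standard
for spectra, where channels share units). The latent-variable count is chosen
by leave-one-out cross-validation (default cap 15, matching the largest LV
counts such studies report); ties go to the smaller count. A compiled kernel
(`_pls_fast`, numba) implements the same recursion for the cross-validation
hot paths; a test pins the two routes together at 1e-8.

**LS-SVM** solves the dual system `[[0, 1ᵀ], [1, K + I/γ]] [b; α] = [0; y]`
with RBF kernel `K(x, x') = exp(−‖x − x'‖²/(2σ²))`. (γ, σ²) come from an
exhaustive cross-validated grid search, by default 13×13 log-spaced over
γ ∈ 10⁰…10⁷ and σ² ∈ 10⁰…10⁶ with 10-fold CV — a range bracketing the
10³–10⁵ magnitudes typical of tuned LS-SVM spectral calibrations. Ties break
toward smaller γ, then smaller σ² (less interpolation, smoother kernel). The
solution's relative KKT residual is checked (≤ 1e-6 to accept, ≤ 1e-8
asserted in tests on healthy problems).

**MLR** is OLS with intercept and requires more (independent) samples than
variables — which is why it only ever runs after wavelength selection.

## Wavelength selection

**BOSS** (bootstrapping soft shrinkage). Weights over all p channels start
uniform. Each iteration: (i) draw `n_submodels` (default 1000) variable
multisets by weighted bootstrap sampling — draw count equals the currently
retained (nonzero-weight) variable count, duplicates collapse to the unique
set; (ii) fit a PLS sub-model per subset, LV count by internal 5-fold CV
capped at `max_lv` (default 10); (iii) keep the best `best_fraction` (default
0.1) of sub-models by RMSECV and set each variable's new weight to the
normalised sum of its absolute regression coefficients across the kept
sub-models — variables absent from all kept sub-models get weight 0 and are
never sampled again (soft shrinkage, no explicit elimination); (iv) score the
iteration by the cross-validated RMSECV of a PLS model on the retained set.
That score traces the characteristic U-curve — high with all channels, falling
as noise channels drop out, rising once informative channels start to go — and
the retained set of the lowest-RMSECV iteration is returned. Sub-model count
and best fraction follow the original soft-shrinkage literature; 5-fold CV
(not LOOCV) keeps 10³ sub-models per iteration tractable.

*Termination safeguard.* The retained set is the union of the kept
sub-models' variables, and that union can reach a fixed point above one
variable (every kept sub-model contains the same few strong channels). After
`stall_patience` (default 5) iterations without shrinkage, the lowest-weight
5% (at least one variable) is shed per stalled iteration, so the iteration
count stays finite and the variable count still reaches 1. The safeguard
engages only after the RMSECV minimum in practice, so it does not affect the
returned subset; it exists to terminate, not to select.

**SPA** (successive projections algorithm) is deterministic forward selection
minimising collinearity: from every candidate start, grow a chain by
projecting all unselected columns onto the orthogonal complement of the
selected span and taking the largest residual norm (chains truncate, never
fail, when the residual space is numerically exhausted). Every (start, prefix)
subset is scored by MLR RMSEP on a validation block; the arg-min wins, ties
toward fewer variables then the lower start index. `max_vars` defaults to 30 —
it must stay below the calibration sample count for MLR, and selections in
this problem class run ~15–40 wavelengths. Scoring subsets on the final
prediction set would leak test information into selection, so the workflow
validates on a KS-internal 80/20 split of the calibration block by default;
an explicit external validation block is supported for studies that use one.

**BOSS-SPA** runs SPA restricted to the BOSS-retained columns, so its
selection is a subset of BOSS's and the three-stage reduction
|full| > |BOSS| ≥ |BOSS-SPA| holds by construction.

## Evaluation and stability

The headline score is `r = 1 − SSE/SST` — an R²-form quantity: 1 for perfect
prediction, 0 for predicting the calibration mean, negative for worse. The
field's tables often label this a correlation coefficient, so the Pearson
correlation is also computed, under its own name; nothing is guessed about
which one a given published table used. RMSEC/RMSEP are plain root mean
square errors in °Brix on the calibration and prediction blocks respectively,
which the split construction keeps disjoint.

The stability protocol re-divides all samples 3:1 at random `n_repeats` = 20
times (seeds `base_seed + r`), optionally re-runs a selector per repeat
(shared by all model families), fits every family on the calibration block
and scores the held-out block. The summary reports mean ± sample standard
deviation per metric — the error bars of the usual stability figure. A failing
repeat is recorded, warned about and excluded rather than aborting a 20×
protocol. In the orchestrated study the per-repeat BOSS stage runs with 200
sub-models (`stability_submodels`) — the protocol repeats selection 20 times,
and the scaled sub-model count keeps the whole stage proportionate while
leaving the per-iteration mechanics unchanged.

## Synthetic test bed

No public dataset accompanies this problem setting, so the generator is a
first-class module with known ground truth. It emulates: ~120 fruit with SSC
drawn from a truncated normal (mean 12.6, S.D. 0.8, range 11.0–14.5 °Brix;
rejection sampling — the simplest way to respect both the moments and the
range); spectra on the 550–1,000 nm × 2 nm grid built as a smooth polynomial
baseline plus Gaussian absorption bands at 680 nm (chlorophyll,
*not* SSC-informative), 750 nm (4th overtone C–H) and 950 nm (2nd overtone
O–H), the latter two with amplitudes affine in the sample's SSC (a
Beer–Lambert-like limit); then per-sample multiplicative slope and additive
offset (the distortion MSC/SNV are built to remove) and i.i.d. Gaussian noise
last. Ground truth records exactly the channels where an informative band
exceeds half its peak height — an unambiguous recovery criterion for
selection tests. Amplitudes are arbitrary absorbance-like units; the hardware
defines none.

Noise and scatter defaults (noise S.D. 0.06, slope S.D. 0.12, offset S.D.
0.06) put the emulated study at the operating point portable-device SSC
studies actually report — full-spectrum PLS RMSEP ≈ 0.2–0.3 °Brix, r ≈
0.8–0.9 — and make scatter strong enough that pretreatment measurably helps.
`planted_config` is a sparse variant for selection benchmarks: two narrow
SSC-informative bands whose half-maximum support is exactly 8 of 226
channels, flat baseline and mild scatter. Hidden *inside* each band's support
sits a narrower interfering band, centred slightly off the band centre, whose
amplitude varies randomly from sample to sample but carries no SSC
information — the synthetic analogue of a varying non-sugar constituent
(bands can carry per-sample amplitude noise via `band_amplitude_sds`;
informative bands keep it at 0 so their coefficients stay exactly affine in
SSC). Because the interferent is observable only through the planted channels
themselves, cancelling it requires combining several channels of the band:
each planted channel carries genuinely unique predictive content, and a
selection method is rewarded for keeping the planted set rather than
collapsing each band to one representative channel. The interferent is mild,
so every planted channel also remains individually informative — the property
the soft-shrinkage weights respond to.

What the generator does **not** emulate: radiative transfer or probe
geometry, wavelength-dependent scatter, correlated (pink) instrument noise,
temperature effects, or interfering constituents beyond the global scatter
terms. Consequently, passing tests show the algorithms recover known
structure under realistic noise — not that any particular fruit cultivar is
predictable at a given accuracy.

## Numerical choices

- NIPALS stops (and `fit` raises) when the residual weight norm falls below
  1e-12 — the requested LV count exceeds the effective rank.
- SNV uses the n−1 standard deviation; tests are exact against that choice.
- SPA's residual-exhaustion threshold is 1e-10 relative to the largest
  original column norm.
- KS and SPA tie-breaks are index-based and deterministic; BOSS is
  deterministic given its seed (a single `numpy` Generator drives SSC
  sampling, bootstrap draws and fold assignment).
- `random_split` sizes the calibration block as `round(n · fraction)`;
  120 × 0.75 → 90/30.
- Serialized models store arrays row-major with explicit shapes in JSON; a
  round-trip reproduces predictions bit-for-bit.

## Problem sizes used in the checks

The acceptance checks run at the study's own scale — n = 120, p = 226, KS
90/30, 10 seeds for the stochastic properties, 20 stability resamples — with
two package-level choices for proportionality: the stability stage reuses one
frozen BOSS-SPA selection for all three model families (the protocol's
purpose is model-stability comparison on a common variable set), and its
LS-SVM grid is 8×7 rather than 13×13.

## Known limitations

- BOSS's iteration count (hence runtime) depends on how quickly weights
  concentrate; adversarially flat problems lean on the termination safeguard.
- The LS-SVM grid search refits the full kernel system per fold and grid
  point; for n in the thousands a low-rank or warm-started solver would be
  needed.
- SPA evaluates every (start, prefix) candidate; cost grows as
  p × max_vars × MLR. Fine at p ≤ a few hundred, the intended regime.
- `r = 1 − SSE/SST` is reported exactly as defined; comparing it against
  published tables requires knowing whether those printed this quantity or
  Pearson's r — both are provided.
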