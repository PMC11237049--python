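# Methods

## Problem and model

`ramancnn` classifies 1-D Raman spectra of articular cartilage into clinical
categories — osteoarthritic (OA) vs healthy donors, and superficial vs deep
cartilage layer — with a convolutional network that receives *several
differently pre-processed versions of the same spectrum* as its input
channels. Fluorescence background dominates raw Raman measurements, and the
choice of baseline-correction algorithm is usually a manual, dataset-specific
decision; the multi-channel design sidesteps that choice by letting the
network weight eight variants of each spectrum: the raw signal (channel 0)
plus the signal minus seven different baseline estimates (penalised-spline
asPLS, morphological JBCD, iterative-smoothing RIA, signal-free-region FABC,
adaptive min-max polynomial, Goldindec asymmetric polynomial, and BEADS-style
low-pass).

The classifier is a pre-activation 1-D residual network: an initial
convolution, `n_blocks` residual blocks (BN–ReLU–conv–BN–ReLU–conv with an
identity shortcut; blocks after the first downsample by stride 2 through a
1×1 projection), then BN–ReLU, global average pooling and a linear 2-class
head. The default geometry (6 blocks, 100 filters, kernel 5) follows the
published single-channel Raman ResNet this design adapts; transfer from
single-channel weights duplicates the first-layer kernel across the 8 input
channels verbatim (a `--scale-duplicated`-style option divides by the channel
count instead) and re-initialises the head when the class count changes.
Because every conv feeding a batch-norm carries no bias, an input whose
channels are all equal produces exactly `C ×` the single-channel first-layer
pre-activation — an identity the tests check to round-off.

The network, its backpropagation (including gradients with respect to the
input), the Adam optimizer and Integrated Gradients are implemented directly
on NumPy; convolutions use im2col matrix multiplication in float64. The seven
baseline estimators are native implementations of their published algorithm
families (each documented in `baselines.py` with its fixed defaults), built
on a banded-solver Whittaker smoother, SciPy morphology/Savitzky–Golay
filters, and iterative polynomial clipping. They aim for the qualitative
behaviour of each family — a smooth background lying under the peaks — not
for bit-compatibility with any particular library release.

## Training and evaluation protocol

All evaluation is patient-grouped, class-stratified 6-fold cross-validation:
patients (never spectra) are partitioned into six test groups with per-class
counts within ±1 of `n_class/6`; the remaining patients are split 80/20 into
train/validation, again per class at patient level. No spectrum of a test
patient influences any fitted quantity: standardisation statistics
(per-channel-per-wavenumber mean and sd, population convention, sd floored at
1e-8) are fitted on the training fold only, and the code asserts the fitted
count excludes validation and test spectra.

Training follows a two-phase epoch-selection protocol: phase 1 trains for the
full epoch budget (default 100) recording validation F1 each epoch; the
selected epoch `e*` is the earliest argmax; phase 2 re-instantiates the model
from the same initialisation and trains on train+validation for exactly `e*`
epochs before a single test evaluation. Optimisation uses Adam with learning
rate 1e-4 and betas (0.5, 0.999), cross-entropy loss, batch size 4 (1 for
validation/test scoring). An optional shortcut stops phase 1 once validation
F1 reaches 1.0 — no later epoch can beat a perfect score and ties resolve to
the earliest epoch, so the selected epoch and the returned model are
unchanged. The binary F1 of the configured positive class (OA for disease
tasks, deep for layer tasks) is the reported metric, averaged over the six
test folds.

## Integrated Gradients and feature ranking

Attributions are path integrals of the target-class logit's input gradient
from a reference `x'` to the input `x`. The reference is the all-zero input
in standardised space — the per-feature training mean in raw units, the least
informative reference available. The integral is approximated on `m+1`
equispaced path points with **trapezoidal** weights (default `m = 50`; the
right-Riemann rule is available but carries an `O(1/m)` systematic error of
roughly `(g(1) − g(0))/2m` that the trapezoid cancels; at 300 steps the
measured median relative completeness residual is ~1.5e-4 for the trapezoid
versus ~2.7e-3 for right-Riemann). The completeness residual
`|Σᵢ IGᵢ − (F(x) − F(x'))|` is recorded on every map and a warning is logged
when the median relative residual of a batch exceeds 1%.

Per-wavenumber importance sums `|IG|` over channels, test samples and folds;
the ranking sorts descending with ties broken toward the lower wavenumber.
Attribution targets each test sample's true label and includes misclassified
samples by default (`correct_only` excludes them). Reduced-feature
experiments feed the top-k ranked wavenumbers of the manually pre-processed
single spectrum (5th-order iterative-exclusion polynomial subtraction,
rubberband lower-convex-hull subtraction, symlet-4 level-3 soft-universal
wavelet denoising, vector normalisation) to an ANN (two hidden layers of 22
rectified units, 20% dropout, same epoch-selection protocol), a decision
tree and an RBF SVM with frozen library defaults (`SVC(C=1, gamma='scale')`,
Gini, unlimited depth).

## Synthetic cohorts

The generator emulates the study population: 45 OA and 19 healthy donors,
15–20 spectra per donor per cartilage layer, 1015-point grids over 614–1722
cm⁻¹ (region A) or 2495–3264 cm⁻¹ (region B). Each spectrum is a sum of
Gaussian peaks, a random 5th-order polynomial fluorescence background
(coefficients drawn per spectrum, scale 2 a.u., kept non-negative), iid
Gaussian noise (sd 0.02 a.u.) and Poisson-rate cosmic-ray spikes (0.05 per
spectrum, ~5 a.u.). Peak amplitudes carry a log-normal per-patient random
effect (sd 0.1 on the log scale), which induces the within-donor correlation
the patient-grouped CV must respect; peaks flagged with a class effect are
amplified multiplicatively in OA donors. Default region-A peaks sit at 718
(lipids), 830 (proline/hydroxyproline, OA-raised ×1.4), 1004 (phenylalanine),
1330 (collagen CH₂ wagging/twisting, OA-raised ×1.5) and 1450 cm⁻¹ (CH₂
deformation) — the bands reported as cartilage OA biomarkers. `ground_truth_
bands` exposes the ±2σ grid intervals of the class-discriminative peaks.

What the generator does **not** model: physical lineshapes (Voigt/Lorentzian
tails), detector response, wavelength-calibration error, water/substrate
bands, and any layer-dependent signal (the layer label is carried but not
discriminative by default). Passing tests on these cohorts therefore
demonstrate the correctness and internal consistency of the pipeline, not
clinical performance on real cartilage spectra.

## Validation scenarios and their design

Four named scenarios (in `simulate.scenario_config`) fix the conditions of
the self-validation suite:

- **default** — the realistic cohort above, spikes included.
- **strong** — class effects raised to ×2.0 at 830 and 1330 cm⁻¹, noise sd
  0.01, cosmic rays off: a cleanly separable disease task for checking that
  the full multichannel protocol reaches near-perfect F1.
- **null** — all class effects 1.0, cosmic rays off: the no-signal control;
  its mean F1 is compared against a permutation band obtained by shuffling
  predictions against truths within each fold (2000 permutations, 99% band).
- **single_band / two_band** — planted-truth cohorts for attribution
  validation: one (or the two) discriminative peak(s) on a *featureless*
  background (no fluorescence, no spikes, noise sd 0.02).

The planted-truth design needs justification, because two genuine pipeline
behaviours otherwise make "top-k must lie in the planted band" ill-posed:

1. **Cosmic-ray spikes are real attribution targets.** A spike is a massive
   outlier in standardised units (~10² sd); any faithful attribution method
   assigns it weight, and at desk-scale sample counts a handful of spikes
   dominates the aggregated ranking. Spikes are therefore disabled in the
   named validation scenarios (they remain in the default cohort).
2. **Global baseline estimates leak class signal.** Estimators that respond
   to overall peak amplitude (the imodpoly noise-offset term, Goldindec's
   residual threshold, RIA's smoothing window) shift their baseline by a few
   percent of the discriminative peaks' amplitude *across the whole grid*.
   After per-feature standardisation these low-noise offsets become usable
   class evidence anywhere in the spectrum — measured on a fluorescent
   strong-effect cohort, the CNN can reach F1 0.99 while its top-50 IG
   wavenumbers all sit outside the planted bands. The model is right and the
   attribution is honest; the *experiment* is only well-posed when the
   planted bands are the sole class signal, hence the featureless background
   in the planted scenarios. The leak amplitude measured on a noise-free
   planted cohort is ≤ 0.056 a.u. (dominated by RIA); the scenarios' noise
   floor and band-free background keep it below usable levels. Raising the
   noise floor far above the leak (to 0.1 a.u.) is not an alternative: the
   many signal-free wavenumbers then become unit-variance inputs whose sheer
   number dilutes the aggregate |IG| mass and the top ranks degenerate into
   a lottery over noise features.

These interactions are intrinsic to the multichannel design and worth
knowing about when interpreting feature rankings on real data: wavenumbers
ranked important by the network need not correspond to discriminative
*bands* — they may be artefacts (spikes) or globally redundant encodings of
band amplitudes created by the correction algorithms themselves.

## Desk-scale problem sizes

The validation suite and the acceptance script run on one CPU, so they use
the smallest sizes at which each behaviour is cleanly measurable, fixed in
`experiments.py`: strong/null runs keep the 45+19-patient split with 3–4
spectra per patient on the superficial layer; planted-truth runs use 8+8
patients with 12–14 (single-band) or 8–10 (two-band) spectra each — the
single-band recovery experiment needs the larger per-patient sample because
the aggregated |IG| ranking only follows per-index signal strength once
enough test spectra average out the magnitude noise of individual inputs.
The network is the 2-block/16-filter desk-scale spec; epoch budgets are 20
(strong), 8 (null) and 40 (planted scenarios), with the perfect-validation
shortcut enabled; rankings use 16 trapezoid steps at desk scale while
completeness is always measured at 300. Optimiser settings are never
scaled. The full-scale defaults (6 blocks / 100 filters / 100 epochs)
remain the library defaults used by the CLI.

## Numerical choices and degenerate inputs

- Whittaker smoothing solves the pentadiagonal system with a banded Cholesky
  factorisation; tiny systems (n < 5) fall back to a dense solve.
- The iterative-exclusion polynomial fit stops when its support set
  stabilises, at 50 iterations, or when the support would fall below
  `order + 1` points; a plain least-squares variant is available.
- The rubberband baseline is the lower convex hull via Andrew's monotone
  chain; output is clamped at hull vertices to exactly zero.
- Wavelet denoising uses symlet-4, level 3, soft universal threshold
  `σ√(2 ln W)` with σ from the MAD of the finest detail coefficients — the
  source publication names no wavelet, so the default is fixed here.
- Vector normalisation raises a degenerate-input error on the zero vector;
  fitting a standardizer requires ≥ 2 spectra; sd is floored at 1e-8.
- A baseline method returning non-finite values is logged and its channel
  falls back to the raw spectrum rather than poisoning the stack.
- Epoch-selection ties resolve to the earliest epoch; per-fold seeds derive
  from the run seed through `SeedSequence.spawn`, so every reported number
  is reproducible from one integer.

## Known limitations

- The seven baseline algorithms use fixed desk-scale defaults; cited
  publications leave several free parameters unstated and no attempt is made
  to match any reference implementation numerically.
- Binary F1 for a fixed positive class is the headline metric (as in the
  protocol this package follows); macro-averaged scores can be derived from
  the stored confusion counts.
- Region B's shorter pre-processed grids are handled by the shared-grid
  invariant of the dataset container (channels are stacked on the common
  grid); no cross-region model is provided.
- Planted-band recovery validates the attribution pipeline's mechanics, not
  the biological interpretability of rankings on real spectra — see the
  leak discussion above.
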