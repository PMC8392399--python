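# Methods

## Problem and scope

The package models a binary tissue-classification task: given Raman
spectra acquired at many points of fresh glioma biopsies (one biopsy
per patient), decide whether the tumour is IDH-mutant or IDH-wild-type.
The clinical quantity of interest is patient-level, but spectra are the
unit of acquisition, so evaluation is pooled at spectrum level with a
leave-one-patient-out (LOPO) outer loop to prevent patient leakage; an
optional majority-vote aggregation to patient level is provided but not
default.

## Synthetic cohort model

Each noise-free spectrum is a sum of Lorentzian bands

S(ν) = Σₖ Aₖ · m · wₖ² / ((ν − cₖ)² + wₖ²),

with centers cₖ from the tissue shift catalogue, half-width-at-half-
maximum wₖ (4–8 cm⁻¹, typical for tissue bands), base amplitudes Aₖ
scaled to the visual prominence of tissue spectra, and a multiplier m
that combines the class effect (bands reported as IDH-MUT-elevated
carry `mut_factor` > 1, default 1.25; all others 1) and a per-patient
log-normal intensity effect (`patient_effect_sd`, default 0.15 on the
log scale). The Lorentzian is the standard Raman line shape; a
pseudo-Voigt option exists per band. The patient effect is a single
multiplicative scalar — the simplest hierarchy that makes LOPO differ
from spectrum-level cross-validation.

Per-spectrum artefacts, in order:

* a fluorescence baseline: a random polynomial of degree
  `baseline_order` (default 4) with coefficients ~ N(0,
  `baseline_coeff_scale`), shifted so its minimum is a small positive
  pedestal — the shift keeps it an exact polynomial of the same degree
  while guaranteeing non-negativity, which clipping would not;
* an affine scatter distortion y → (1+b)y + a, b ~ N(0, 0.15),
  a ~ N(0, 2);
* additive Gaussian noise (default sd 1);
* Poisson(0.05)-many single-bin cosmic-ray spikes of magnitude ≈ 500
  (uniform ±20%). Multi-bin spikes are out of scope.

Defaults mirror the acquisition structure of an ex-vivo study: 10
patients per class, 35–66 spectra per patient (uniform), axis 350–1800
cm⁻¹ at 1 cm⁻¹ so that truncation to 400–1750 is a real operation. The
within/between-patient variance ratio of real cohorts is not published;
the defaults here are plausible, not estimated — conclusions from
synthetic runs transfer to the *machinery*, not to clinical effect
sizes.

Everything is drawn from one `numpy` generator seeded from the config,
so equal configs give bit-identical cohorts.

## Preprocessing conventions

The conditioning chain leaves several choices open in common usage;
the ones fixed here, so results are reproducible:

* **Despiking** (placed first so spikes cannot poison the outlier or
  scatter statistics): bins implicated by a modified z-score of the
  first difference (robust scale 1.4826·MAD) above 8 are replaced by
  the mean of the nearest clean neighbours.
* **IQR outlier gate**: the per-spectrum statistic is total integrated
  intensity (trapezoid), sensitive to both dropouts and saturation;
  fences Q1 − k·IQR, Q3 + k·IQR with k = 1.5.
* **MSC**: ordinary least squares of each spectrum on the point-wise
  mean of the whole set (per-sample references available), output
  (y − a)/b.
* **S2N gate**: S2N = (P − B)/σ with P the maximum within 1004 ± 10
  cm⁻¹, B a linear baseline between the window endpoints evaluated at
  the peak, and σ = median|Δ|/(0.6745·√2) over the quiet 1700–1750 cm⁻¹
  window (successive differences cancel smooth structure; the constants
  make the estimator consistent for white Gaussian noise). σ = 0 maps
  to S2N = +∞: a noiseless spectrum always passes.
* **VRA baseline**: iterative modified polynomial fit (degree 5,
  tol 1e-4 on the relative change of the residual SD, ≤ 100
  iterations). The working signal is clamped at fit + DEV each round,
  peeling peaks off the fluorescence estimate; a final re-fit on
  non-peak bins (within 2 DEV of the iterated fit) removes the upward
  bias that clustered band wings otherwise leave. Non-convergence
  returns the last iterate with a flag.
* **Savitzky–Golay**: 3rd order, 9-point window; edge bins use the
  polynomial-interpolation boundary rule so that any signal of degree
  ≤ 3 is reproduced exactly over the whole axis (mirror padding would
  break this invariant at the edges).
* **Min–max**: *global* scope by default — one (min, max) over the
  whole retained set, preserving between-spectrum intensity relations
  (needed for median-with-IQR plots); per-spectrum scope available.

The published step listing is ambiguous about whether the S2N gate
runs before or after background subtraction (two steps share one
number); the default order follows the listing as printed and the step
order is fully configurable, so both variants are runnable.

## Featurization

Feature = intensity at the axis point nearest each catalogued shift
(ties toward the lower wavenumber); a local-max mode with a ±2 cm⁻¹
window exists. The built-in catalogue covers the 52 assigned tissue
shifts; the ~50 additional screened shifts of the original study were
never printed and cannot be reconstructed, so extended catalogues are
user-supplied rather than invented.

## Per-shift statistics

Group 1 is IDH-WT (n₁), group 2 IDH-MUT (n₂). U = R₁ − n₁(n₁+1)/2 with
midranks; p is exact (full enumeration, via the exact null
distribution) when n₁·n₂ ≤ 400 and the pooled sample is tie-free,
otherwise a tie-corrected normal approximation with continuity
correction. All-identical input returns the convention U = n₁n₂/2,
p = 1. Both U and n₁n₂ − U are reported because published tables often
leave the group convention implicit. Primary p-values are unadjusted,
matching common practice in this literature; a Benjamini–Hochberg
column is emitted alongside, clearly marked as an extension, because
52 simultaneous tests invite misreading. The Shapiro–Wilk screen is
reported per class but never gates the rank test.

## Classification and evaluation

Per outer LOPO fold: (a) two-group ANOVA-F scores on the training
spectra only, top-k selection (k = 52 by default, ties toward the
lower wavenumber); (b) stratified 5-fold grid search on the training
spectra — C ∈ {0.01, 0.1, 1, 10, 100, 1000} for the RBF-SVM
(kernel width γ = 1/(n_features · feature variance)); eta ∈
{0.01, 0.05, 0.1, 0.2, 0.3}, max_depth ∈ {5, 8, 10, 12, 15}, gamma ∈
{0.1, 0.2, 0.3, 0.4} for the boosted trees (hist method, binary
logistic, 100 rounds); (c) refit on the whole training fold and
prediction of the held-out patient with continuous scores (signed
margin for the SVM, positive-class probability for the trees). Inner
folds are stratified by class at spectrum level — patient-level inner
grouping is impossible when a training fold holds few patients.

Inner model selection maximizes **balanced accuracy** for the SVM and
minimizes binary log-loss for the trees. Balanced rather than raw
accuracy because the LOPO outer split makes every training fold
imbalanced against the held-out class; raw-accuracy selection then
prefers a degenerate majority-class model whenever the signal is weak
(its inner score is the majority rate, which beats chance-level
candidates), and that degenerate model misclassifies *every* held-out
spectrum. Balanced accuracy scores the degenerate model at exactly 1/2
and coincides with accuracy selection when a real signal is present.

IDH-MUT is the positive class throughout. Metrics come from pooled
confusion counts: per-class precision/recall/F1, accuracy, and
unweighted (macro) averages; a class never predicted gets precision 0
and an explicit flag. The ROC is a threshold sweep with tied scores
grouped; AUC by trapezoid, which equals U/(n₁n₂) on the scores — this
identity is asserted in tests against the independent rank-statistic
implementation.

## Benchmark study designs

`ramanidh.benchmarks` fixes two synthetic designs used by the tests,
the analysis drivers and the acceptance script.

**Planted design** (pipeline plant-and-recover): 10 + 10 patients, 12
spectra each; 20 well-separated bands (≥ 60 cm⁻¹ apart, amplitude 30,
width 5), ten carrying `mut_factor` 2; six strong class-shared bands
(amplitude 150) plus the 1004 cm⁻¹ anchor; moderate artefacts. The
shared mass is not decoration: MSC regresses each spectrum on the
cohort mean, and when class-specific bands dominate the total spectral
mass the fitted slope absorbs part of the class effect and smears it
with opposite sign onto neutral bands — which can make neutral bands
*more* selectable than planted ones. Tissue spectra are dominated by
class-shared structure, so the fixture is built the same way.

**Exchangeable null design** (permutation calibration): 25 + 25
patients, 4 spectra each, no patient-level intensity effect. Labels
are permuted at patient level and pooled LOPO accuracy should sit near
1/2. Two structural facts shape this design:

* with a class-balanced cohort, the training fold of every LOPO split
  leans against the held-out patient's class, and a soft-margin SVM on
  inseparable (label-permuted) features is a majority-class predictor
  for *any* C — so its null accuracy collapses toward 0, the
  well-known pessimistic bias of block-balanced permutation nulls.
  The calibration check therefore uses the boosted-tree family, whose
  per-spectrum noise-driven predictions do not collapse;
* with patient-level intensity effects, fold outcomes are nearly
  all-or-nothing per patient, inflating the null accuracy variance by
  the block size; removing the patient effect makes spectra
  exchangeable so pooled accuracy concentrates.

## Problem sizes

The test suite and acceptance script run the planted design at 20
patients × 12 spectra (≈ 240 spectra), selection recovery over 20
seeds, the null design at 50 patients × 4 spectra with 50
permutations, and the boosted-tree grid at 2×2×2 (eta {0.05, 0.3},
max_depth {5, 10}, gamma {0.1, 0.3}); the SVM grid is always searched
in full. These sizes were chosen so a complete run finishes in minutes
on one CPU while leaving all qualitative conclusions unchanged; the
analysis drivers default to the larger 35–66 spectra-per-patient
acquisition range.

## Known limitations

* The generator emulates the statistical structure of tissue spectra,
  not their biochemistry: band ratios, fluorescence shape and the
  within/between-patient variance split are plausible choices, not
  estimates. Passing tests demonstrate that the machinery is correct
  and leak-free, not that clinical accuracy would reach any particular
  level.
* Cosmic rays are single-bin; detector artefacts wider than one bin
  are not modelled and the despiker is not designed for them.
* The VRA baseline is polynomial; fluorescence with sharper curvature
  than degree 5 will leak into the corrected signal.
* Wavenumber calibration, instrument response and vendor binary
  formats are out of scope; I/O is plain text.
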