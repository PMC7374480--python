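# Methods

This note documents the models, the synthetic-data generator, and the
numerical conventions behind `ramanotype`. Everything stated here is
computed by the test suite or the pipeline itself; nothing is quoted from
external data.

## The problem

Carotenoid profiling of intact tomato fruit from surface Raman scans, posed
as two tasks on the same spectra:

1. **Classification** into seven carotenoid-profile classes — high
   all-*trans*-lycopene, lycopene + β-carotene, lycopene + γ-carotene,
   β-carotene (low lycopene), β-carotene + anthocyanin,
   tetra-*cis*-lycopene, and low-carotenoid fruit. The diagnostic feature
   is the ν1 C=C stretch near 1520 cm⁻¹, whose position encodes the
   dominant pigment (1519 / 1523 / 1528 cm⁻¹ for all-*trans*-lycopene /
   tetra-*cis*-lycopene / β-carotene).
2. **Quantification** of all-*trans*-lycopene (reference range
   1.8–21.5 mg/100 g) and β-carotene (1.6–9.5 mg/100 g) against UV-Vis
   reference values obtained via Beer–Lambert with extinction coefficients
   172 and 139 mM⁻¹cm⁻¹.

## Synthetic spectra

No instrument dataset ships with the package; the generator emulates the
statistical structure the analysis assumes.

* **Axis.** 512 equally spaced points, 200–2500 cm⁻¹ (≈4.5 cm⁻¹ spacing).
  Real detectors need not be wavenumber-linear — the axis is a modeling
  choice, and region point counts (74 points in 1370–1700 cm⁻¹, 62-point
  windows) follow from it rather than from any instrument.
* **Bands.** Lorentzian lines; each carotenoid contributes 1007 cm⁻¹
  (relative amplitude 0.5, FWHM 10), 1158 cm⁻¹ (0.75, FWHM 10) and its ν1
  line (1.0, FWHM 12). FWHM 12 makes the 1519/1523 classes overlap enough
  to be nontrivial yet separable. Band amplitude is *linear in
  concentration with unit slope*, so regression models can be validated by
  exact parameter recovery. γ-carotene's ν1 is placed at 1516 cm⁻¹ and
  anthocyanin contributes a broad 1600 cm⁻¹ feature (FWHM 60) — simulator
  conventions, not literature assignments.
* **Class recipes.** Minor pigments are ratio-tied to the dominant one
  (β-carotene at 40–80 % of lycopene in the mixed class, γ-carotene at
  50–100 %, trace lycopene at 5–25 % of β-carotene). A mixed profile is
  only a *class* when its second pigment is appreciable; independent draws
  would blur neighbouring classes into a continuum. Mixed red classes draw
  lycopene from 6–21.5 mg/100 g (visibly red fruit).
* **Nuisance model.** Each replicate scan gets (i) a smooth random
  nonnegative quadratic baseline with scale 2.0 counts (1064 nm excitation
  keeps fluorescence low), (ii) a multiplicative scatter factor
  ~ N(1, 0.15), and (iii) additive Gaussian noise with sd equal to 1 % of
  that spectrum's peak band signal (shot noise scales with signal), floored
  at 0.02 counts of detector noise; the noise rides inside the scatter
  factor, as photon noise does. Three replicates per sample share
  concentrations but not nuisance draws and are averaged before modeling.
* **What it does not model.** Resonance-Raman cross sections, fluorescence
  physics, skin/flesh optics, pixel-correlated detector noise, instrument
  drift. Passing tests therefore demonstrate correctness of the chain and
  attainable performance *under this noise model*, not field performance.

## Preprocessing

SNV (per-spectrum standardization, sample sd with n−1), Savitzky-Golay
filtering (order-2 local polynomials; derivative taken w.r.t. pixel index;
scipy's polynomial-interpolation edge handling keeps the point count
constant), closed-interval region selection, and column mean centering with
frozen training means. Classification uses SNV → SG(25-pt, 2nd derivative)
→ 1370–1700 cm⁻¹ → center; calibration uses SG(15-pt, 2nd derivative with
smoothing) → center; the MLPs see mean-centered raw spectra only. All
fitted statistics come from training rows; cross-validation refits the
preprocessing inside every fold.

## SIMCA

One PCA submodel per class on the preprocessed training spectra of that
class. Conventions, several of which are genuinely open in commercial
implementations:

* **Components per class** by leave-one-out residual variance
  PRESS(k)/(p−k), accepting k+1 only on a ≥5 % improvement (raw PRESS
  decreases monotonically because every component absorbs part of the
  held-out vector); capped at min(n_c−2, 10).
* **Residual scale** s0: the documented resubstitution formula
  s0² = Σ‖r‖²/((n_c−k−1)(p−k)) is available (`s0_method="train"`), but the
  classifier defaults to the leave-one-out estimate
  s0² = PRESS(k)/(n_c (p−k)), which reflects prediction rather than
  training error — at n_c ≈ 6–22 and p = 74 the resubstitution value is
  several-fold too small and the F-test rejects genuine class members.
* **Admission.** Residual F-ratio s_i²/s0² compared against a per-class
  cutoff. The default cutoff is the conformal (1−α) quantile of the
  class's own leave-one-out F-ratios (finite-sample valid with no
  distributional assumption); the parametric alternative uses the F
  distribution at the Satterthwaite effective dof of the residual
  covariance — after 25-point smoothing, neighbouring pixels are strongly
  correlated and the nominal p−k dof would give an absurdly tight critical
  value. A score-space gate (Mahalanobis within the χ²(0.999, k) radius)
  excludes samples lying *along* a class's components but far outside its
  score range. α defaults to 0.05.
* **Assignment.** Nearest admitted class by the combined statistic
  g = F + d²/k (residual F-ratio plus per-component score Mahalanobis),
  both ≈1 for genuine members. Ranking by F alone lets a diffuse class
  claim alien samples: a featureless spectrum sits inside every pigmented
  class's component span with a deceptively small residual. A sample may
  be admitted to one class, several, or none; accuracy counts a prediction
  correct only when the true class is the nearest admitted one.
* **Interclass distance.** D(a,b) = sqrt((s_ab²+s_ba²)/(s_aa²+s_bb²)) − 1
  from cross-fitted pooled residual variances s_xy² = Σ‖r‖²/(n_x (p−k_y));
  the −1 pins the self-distance at exactly 0. D > 3 indicates
  well-separated classes.
* **Discriminating power.** The per-wavenumber version of the same ratio,
  with the denominator floored at 1e-12. The pipeline reports it on
  SNV-only (underivatized) spectra: the second-derivative filter relocates
  shape mismatch into Lorentzian side lobes, while on intensity-shaped data
  the maximum falls on the ν1 band itself (1528 cm⁻¹ for the
  lycopene-vs-β-carotene pair).

## PLS1

NIPALS with X and y deflation; regression vector b = W(PᵀW)⁻¹q; prediction
ŷ = (x−x̄)·b + ȳ. Latent variables are chosen by leave-one-out
cross-validation as the global SECV minimum (smaller a on ties; the default
benchmark selects 1, consistent with the single-analyte simulation). SECV
and SEP are divisor-n root-mean-square errors; a bias-corrected variant is
available. Calibration/validation is a seeded 80/20 split stratified by
concentration quartile. Outlier screening flags |standardized residual| > 3.

## MLP

Pure-numpy feedforward network, 1–2 ReLU hidden layers, He-uniform
initialization, full-batch ADAM (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8),
inverted dropout on hidden activations, early stopping on validation loss
with best-weight restoration (estimator default patience 50; the pipeline
budget is max 2000 epochs, patience 100 — selected networks typically stop
between ~400 and ~1700 epochs). Classification head: softmax with
categorical cross-entropy (probabilities clipped at 1e-12); regression
head: ReLU with MSE, so predicted concentrations are nonnegative.
Gradient correctness is verified against central finite differences — the
load-bearing test for the module.

Input variables are chosen by a 62-point sliding window stepped 2 points
across the axis (226 candidates on the 512-point axis); each window is
scored by a small fixed MLP's validation error rate with cross-entropy as
tie-break, lowest error (leftmost on ties) wins. Hyperparameters are
sampled uniformly (dropout 0–0.9, 1–2 hidden layers, 2–250 neurons per
layer) for 50 trials in the classification benchmark; the regression
benchmark tunes 12 sampled configurations by validation loss. Dropout
rate 1 is rejected (it would drop every unit under inverted scaling).
Splits are seeded, largest-remainder rounded, stratified by class (or
concentration quartile): 80/10/10 for classification, 60/20/20 for
regression.

## Benchmarks and their limits

The default configuration simulates 106 fruit for classification
(28/13/10/14/7/17/17 across the seven classes) and 58 lycopene-dominant
fruit for quantification. At the default seed and three alternates the
pipeline reaches SIMCA held-out accuracy ≥ 95 %, MLP test accuracy 100 %,
all 21 pairwise ICDs > 3.4, PLS1 external r ≈ 0.98 with SEP ≈ 1.1–1.4
mg/100 g, and MLP-regression r ≈ 0.94–0.96.

One bound is not attainable under this noise model: the replicate-averaged
multiplicative scatter (sd 0.15/√3 ≈ 0.087) imposes an irreducible error
floor of ≈ 0.087·√E[c²] ≈ 1.1 mg/100 g on any intensity-based predictor of
a concentration uniform on 1.8–21.5. PLS1 sits essentially on that floor;
the 34-training-sample MLP regressor lands at ≈ 1.7–2.5 mg/100 g, so a
test asserting MLP RMSE ≤ 1.14 mg/100 g fails and is left failing rather
than weakened. β-carotene calibration is supported
(`ramanotype run-quantification --analyte bcarotene`) but flagged small-n:
17 samples leave 3–4 for validation, so its metrics are unstable by
construction.

## Degenerate inputs and tie-breaks

Zero-variance spectra are rejected by SNV; constant classes are rejected by
the class-model fit; classes fitted with k equal to their exact rank have
s0 = 0 and admit their training samples; k = 0 models use the residual
criterion only. Ties in latent-variable selection go to fewer components,
in window selection to the leftmost window, and hyperparameter tables rank
by (accuracy desc, test loss asc) without dropping trials. All stage seeds
derive from one experiment seed via `SeedSequence`; reports are
bit-reproducible on a fixed platform.
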