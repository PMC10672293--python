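# Methods

This note records what the package computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Spectra live on a uniform, strictly descending wavenumber axis; the default
instrument grid is 1798 points spanning 4000–650 cm⁻¹ (≈1.86 cm⁻¹ per
step). Each measurement row carries a sample id, an optional replicate id,
and a class label from `{positive, control, unknown}` ("positive" is the
disease class; the same binary machinery serves the lung and prostate
endpoints). Three replicate spectra per swab are averaged on the raw
absorbance scale before any preprocessing, following the acquisition
protocol's "measure three, then average" order.

## Preprocessing chain

Fixed order: fingerprint truncation → Savitzky–Golay 2nd derivative →
unit-vector normalisation → (train-fitted) mean centring.

* **Truncation** to the closed interval 1800–900 cm⁻¹ happens *before* the
  derivative, so the normalisation norm is computed over the analysed
  region only. (Whether the original analysis normalised over the full
  range is unstated; this choice is self-consistent and documented.)
* **SG derivative**: window 9 points, polynomial order 2, derivative
  order 2, scaled by the grid spacing so the output has units
  absorbance·cm². A 2nd derivative annihilates constant and linear
  baselines; the embedded least-squares smoothing tempers the noise
  amplification. The (window−1)/2 = 4 edge points per side are dropped
  rather than extrapolated; within the truncated fingerprint region no
  marker band is lost.
* **Vector normalisation** divides each row by its Euclidean norm,
  removing multiplicative effects (film thickness, scatter,
  concentration). Rows of exactly zero norm are an error, not a silent 0/0.
* **Mean centring** statistics are learned on training rows only and
  applied unchanged to test rows. The source protocol is silent here, but
  anything else would leak test statistics into the model and invalidate
  the external validation.
* The chain refuses to run twice on the same dataset (a state flag):
  differentiating an already-differentiated spectrum is never intended.

## Outlier rejection

A PCA model (enough PCs for 95% explained variance) yields per-sample
Hotelling T² (distance within the model subspace, F-distribution control
limit with K and n−K degrees of freedom) and Q residuals (squared distance
off the subspace, Jackson–Mudholkar limit from the residual eigenvalue
tail), both at a configurable confidence (default 95%). A sample is
removed only when it exceeds **both** limits — the conservative reading of
the joint T²-vs-Q criterion; a sample extreme in a single statistic is
retained. The confidence level and flagging rule are not stated in the
source study (whose removed-outlier counts are not reproducible without
the raw spectra), so both are explicit parameters.

## Kennard–Stone split

Within each class: start from the two mutually most distant samples
(Euclidean distance on preprocessed spectra), then repeatedly add the
sample maximising its minimum distance to the already-selected set, until
round(0.70 × class size) samples are selected; these form the training
set. Ties break toward the smallest sample id, making the split invariant
to input row order. Applying the rule per class reproduces the published
per-class training counts (22/664 for a 31/948 cohort, 12/399 for 17/570).

## Classifiers

* **LDA/QDA**: Mahalanobis discriminant d_c(x) = (x−μ_c)ᵀΣ_c⁻¹(x−μ_c) +
  ln|Σ_c| − 2 ln π_c (pooled Σ and no log-determinant term for LDA).
  Priors default to *equal*: with a ~30:1 imbalance, proportional priors
  would silence the minority class, contradicting the screening intent.
  Covariances get an escalating ridge (starting at 1e-8·trace/dim, ×10
  until Cholesky succeeds) — a 22-sample class in 8 PCs is near-singular.
  Exact discriminant ties go to "control": a call-back requires a strictly
  better positive fit. The decision score d_control − d_positive makes
  ROC/AUC computable from any discriminant model.
* **PLS-DA**: PLS latent variables against 0/1 class membership
  (scikit-learn backend), then an LDA on the LV scores; LV count by
  stratified 10-fold CV when unset.
* **SVM** (linear / 2nd-order polynomial / RBF kernels) and **KNN**
  (Euclidean majority vote, odd k) are comparison methods on scikit-learn
  backends behind the same output contract; cost, RBF width (median-
  distance heuristic × {0.25…4}) and k ∈ {1,3,…,15} tuned by the same CV.
* **GA wavenumber selection**: binary masks over wavenumbers; tournament
  selection (size 2), single-point crossover (p=0.60), per-bit mutation
  (p=0.01), elitism of one; fitness is the stratified CV misclassification
  of an inner LDA on the masked variables, with folds fixed per run so
  fitnesses are comparable across generations. Defaults: 100 generations ×
  200 chromosomes. Everything is driven by one integer seed.
* The PC count for PCA models defaults to the smallest K within one
  standard error of the best stratified 10-fold CV accuracy (the original
  analysis reports only the chosen counts, not the criterion); an
  explained-variance-threshold strategy is also provided.

## Validation metrics

AC, SENS, SPEC, F = 2·SENS·SPEC/(SENS+SPEC), G = √(SENS·SPEC); zero
denominators yield "undefined", never 0. AUC is the rank statistic of the
decision scores (ties half-credited). Exact values are kept internally.
**Display convention**: the publication-style table (`as_printed`) rounds
SENS and SPEC half-up to 2 d.p. first and computes F and G from the
*rounded* values. This chained rounding is the only convention consistent
with every published table cell (one training row prints F = G = 0.98
where the exact values round to 0.99), and it is confined to display.

## Marker extraction

The preprocessed-domain DBM spectrum (mean positive − mean control) says
*where* classes differ; the train-fitted PCA loadings say where the model
looks. Markers are local maxima of the summed absolute loading
Σₖ|loadingₖ| whose |DBM| lies in the top decile (evaluated over a ±2-point
neighbourhood of the peak — the two extrema of one band can sit a grid
point apart), thinned so no two markers are closer than 8 cm⁻¹ (stronger
peak wins) and capped at 20. The summed-absolute surface rather than the
signed "TOTAL" trace is used for peak picking because signed loading lobes
cancel at resampling-dependent positions; the signed trace is still
provided for plotting. Direction arrows come from the **raw**-domain DBM —
the 2nd derivative inverts peak signs, so derivative-domain signs would
not describe absorbance — read as the band's ±2-point centre minus a
surrounding annulus (offsets ~11–22 cm⁻¹), so broad baseline offsets in
the raw DBM cannot flip a narrow band's direction. Assignments attach the
nearest packaged band-table entry within 4 cm⁻¹ (≈2 grid steps).

## Synthetic cohorts: what they emulate, and what they do not

The generator produces the *statistical structure* the analysis depends
on, not physically realistic radiometry:

* class imbalance and replicate structure (defaults 31/948 lung, 17/570
  prostate; 3 replicates per sample);
* Gaussian absorbance bands at the published discriminating wavenumbers,
  with signed class offsets following the published direction arrows, on
  top of class-neutral amide/phosphate scaffolding and a constant
  rayon-swab background;
* per-sample band-amplitude jitter (shared across a sample's replicates)
  whose standard deviation is halved for the positive class — the
  "narrower, less spread" cancer profile that motivates QDA — plus
  per-measurement gain (1 ± 2%), a random degree-2 baseline, and white
  noise.

Free parameters the source study does not quantify were calibrated once
and frozen: band σ 4.2 cm⁻¹ for bands with a neighbour within 13 cm⁻¹ else
5.5 (three overrides in the lung table keep crowded triplets resolvable),
band amplitude 0.030, |class offset| 0.006, jitter 10%, so that the
default PCA-QDA pipeline lands at-or-above the published performance
regime. Two consequences are worth stating plainly. First, the default
cohort is *more* separable than the clinical data (test SENS = SPEC = 1.00
rather than SPEC ≈ 0.91): with only 9 test positives, a single miss drops
SENS to 0.889, so any calibration that reproduces SPEC ≈ 0.9 overlap also
makes SENS flicker below 1.0 — the clinical result (SENS exactly 1.0)
sits in a corner the synthetic world can only reach from the separable
side. Second, a green planted-recovery test establishes that the
*algorithms* behave as specified on data with the assumed structure; it
says nothing about spectra whose class differences are not band-shaped.
The 9-point SG window cannot resolve same-sign bands closer than
~13 cm⁻¹, capping noise-free marker recovery at 15 of the 18 published
lung wavenumbers (83%).

## Numerical choices

* PCA by SVD of the centred matrix (not NIPALS): numerically robust,
  identical subspace. Eigenvalues are score variances with ddof = 1.
* Rounding for display: half-up (`floor(x·100 + 0.5)/100`), matching the
  published tables; Python's banker's rounding is never used on metrics.
* Kennard–Stone and GA tie-breaks are deterministic (smallest id / first
  maximiser), so every stochastic stage is reproducible from one seed.
* Degenerate inputs fail loudly: zero-norm rows, empty truncation regions,
  single-sample classes, K beyond matrix rank, unknown labels.

## Limitations

* Binary endpoints only; no multi-class support, no probability
  calibration, no confidence intervals on metrics.
* The published outlier counts (19 and 15 removed) are not reproducible
  without the raw clinical spectra; the outlier stage is validated by
  statistical calibration on null data instead.
* The synthetic generator does not model ATR penetration depth, water
  vapour/CO₂ artefacts, or detector drift; the swab background is a
  constant, not a variable contaminant.
* JCAMP-DX and vendor binary formats are out of scope (wide CSV only).
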