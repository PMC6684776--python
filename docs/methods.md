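# Methods

This note documents the models and numerical choices behind crpkit: what
each stage assumes, which defaults matter and why, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## Signals and matrices

A fingerprint is a full-profile signal on a strictly increasing axis (m/z in
Da for MALDI-TOF spectra, retention time in minutes for chromatograms).
Intensities are kept verbatim at I/O time — instrument exports can be
negative after baseline handling, and clamping would silently bias SNV and
centering. All samples are brought onto one axis by linear interpolation
(the minimal assumption when the acquisition grid is not documented; the
grid is configurable). Replicate acquisitions (three per sample by default)
are averaged point-wise before matrix assembly; the averaging sums in a
canonical replicate order so the result is independent of input order at
the last-ulp level.

## Correlation optimized warping

COW corrects peak-position drift between samples (calibration drift in
MALDI, retention-time drift in LC). Both query and reference are cut into
`floor((n-1)/m)` segments of nominal length `m` grid points (the last
segment absorbs the remainder, endpoints fixed). Each interior boundary of
the query may shift by an integer in `[-t, +t]` (slack). A candidate warp
re-stretches each query segment onto the reference segment's length by
linear interpolation; its score is the sum over segments of the Pearson
correlation with the reference segment — the canonical COW benefit. The
optimum over all boundary placements is found exactly by dynamic
programming over (boundary, shift) states; the test suite checks the DP
against exhaustive enumeration on all instances small enough to enumerate.

Numerical choices:

* zero-variance segments contribute correlation 0, not NaN, so flat
  baseline regions cannot poison the DP total;
* ties between warp paths resolve toward the smallest absolute boundary
  shift, so aligning a signal to itself returns it unchanged;
* `m >= t + 3` is required, which guarantees warped boundaries stay ordered.

Defaults are segment 150 and slack 5 grid points — appropriate for
~30000-point mass-spectral profiles where drift is a few points. The
optional tuner scores each (segment, slack) pair on the aligned,
row-normalised matrix by *simplicity* (Σσ⁴/(Σσ²)² over singular values —
higher when aligned rows are closer to rank one) plus a *peak factor*
(1 − mean relative change in total area, capping each row's contribution at
1), and breaks ties toward the smaller segment, then smaller slack. The
exact constants of this score are our choice; the score rewards alignment
without rewarding area distortion, which is the failure mode of aggressive
warping.

The reference signal is the row with the largest summed Pearson correlation
to all other rows (constant rows excluded; ties to the lowest index). When
classes drift independently one can align each class to its own reference
first and then align class references to each other; the pipeline aligns
everything to one global reference by default, which is the simpler
behaviour and adequate when drift is not class-structured.

## Row/column preprocessing

SNV standardises each row with the sample (n−1) standard deviation,
removing multiplicative/slope variation. Sum-normalisation divides a row by
Σ|x|. Mean centering removes each column's mean — **fitted on calibration
rows only** and re-applied to validation rows, so no validation information
leaks into the model space. Recipes are ordered step lists; `mean_center`
may appear at most once and must be last (any row operation after centering
would destroy the fitted column means). The shipped default recipe is SNV
followed by mean centering, the combination that gives the most parsimonious
PLS-DA fit in the bundled preprocessing-comparison table.

## PCA, T²/Q screening, HCA

PCA is a centered SVD with a deterministic sign convention (largest-|loading|
element positive). For screening, each sample gets two distances:
T²= Σₖ t²ₖ/λₖ (within-model, λ the calibration score variances) and
Q = squared reconstruction residual (off-model). Limits at confidence 1−α
(default 95%) use the standard F scaling k(n−1)/(n−k)·F(k, n−k) for T² and
the Jackson–Mudholkar approximation for Q, computed from the residual
eigenvalues of the calibration SVD. A sample is an outlier only when
**both** statistics exceed their limits: high T² alone is an extreme but
model-consistent sample, high Q alone an ill-modelled but central one.

One screening pass is the default. A caveat the tests encode: if a single
extreme sample is included in the PCA fit, the first component can absorb
its entire (rank-one) deviation and drive its Q toward zero; the
planted-outlier fixture therefore fits the model on the in-control samples
and scores the suspect against it, which is also the recommended usage.

HCA is agglomerative Ward linkage; merge heights are reported on the
squared-Euclidean scale (the variance-increase convention), and are
guaranteed non-decreasing. Flat clusters come from a cluster-count or
height cut; dendrograms export as Newick for external plotting.

## Kennard-Stone splitting

Within each class: seed with the two mutually farthest samples, then
repeatedly add the sample with the largest minimum distance to the selected
set, stopping at ⌈fraction·n⌉ (default fraction 0.6). This puts the most
extreme, space-spanning samples into calibration and leaves interior
samples for validation. The per-class ceiling rule gives 23 + 30 = 53
calibration and 15 + 19 = 34 validation samples for class sizes 38 and 49.

## The five classifiers

All models share `fit(X, y)`/`predict(X)` with string labels; prediction is
deterministic and side-effect free. Binary discriminants code the classes
0/1 in sorted label order unless a `class_order` is given.

* **PLS-DA** — PLS regression (NIPALS, via scikit-learn) of the 0/1 code;
  2 latent variables by default for mass-spectral matrices (1 is typical
  for chromatographic ones); label 1 when the predicted response ≥ 0.5, the
  symmetric threshold between the codes. With as many latent variables as
  the rank, PLS prediction coincides with least squares (tested).
* **KNN** — Euclidean majority vote, K = 3 default, K selectable by
  leave-one-out accuracy (ties → smallest K). Implemented by hand (~20
  lines) so neighbour ties (stable sort by distance, then label) and vote
  ties (nearest neighbour wins) are explicit and row-permutation invariant.
* **SIMCA** — one PCA per class on class-centered data (5 components per
  class by default for mass-spectral data, 1 for chromatographic). A
  query's residual variance s² = ‖r‖²/(p−k) is compared with the pooled
  calibration residual variance s₀² = Σ‖rᵢ‖²/((n−k−1)(p−k)) via F = s²/s₀²
  against the 1−α critical value with (p−k, (n−k−1)(p−k)) degrees of
  freedom. Sole accepting class wins; both accept → smaller F; both reject
  → `"unassigned"`. A class whose calibration residual is numerically zero
  (e.g. exactly collinear training points) accepts only queries inside its
  subspace.
* **CART** — Gini decision tree grown to purity without pruning (two-class
  problems don't need size selection), via scikit-learn with a fixed
  random state; split ties follow the library's internal order.
* **SVM-DA** — soft-margin SVM, linear kernel and C = 1 by default, via
  scikit-learn; probability estimates optional.

## Evaluation

Venetian-blinds cross-validation assigns sample i to fold i mod B (B = 10
default). Confusion metrics take a positive class and tolerate
`"unassigned"` predictions with this rule: an unassigned positive is a
false negative (sensitivity = recovered positives / all positives), while
an unassigned negative is excluded from specificity (it was not falsely
called positive). ER is the misclassification rate (FP + FN)/n over all
samples and NER = 1 − ER; this counting reproduces the published two-class
authentication tables from their raw prediction counts, which the macro
mean (sensitivity + specificity)/2 does not once unassigned samples exist —
the macro mean is still exposed as `balanced_ner`. Rates are exact
fractions internally and rounded only in reports (2 decimals for rates, 4
for RMSE-type values).

Calibration curves are ordinary least squares; σ is the residual standard
deviation √(SSE/(n−2)); LOD = 3.3σ/slope and LOQ = 10σ/slope (the
conventional 10/3.3 ratio — a reported LOQ equal to the LOD formula is a
known typographical trap, and the published LOD/LOQ value pairs have ratio
≈ 3, consistent with 10σ/slope). RSD% uses the sample (n−1) standard
deviation, verified cell-by-cell against the bundled QC table.

## Peptide-marker analytics

Cysteine motifs are the ordered inter-cysteine gap counts, rendered
`C-Xn-…-C` with `X` for a gap of one and `C-C` for adjacent cysteines; the
renderer and parser round-trip. Pairwise identity is ungapped and
positional (both published marker pairs are equal length); unequal lengths
are an explicit error pointing to external aligners rather than a silently
different statistic. Masses come from the standard residue tables
(pyteomics): free-thiol by default; `disulfide(n)` removes 2 H per bridge;
`alkylated` adds carbamidomethyl (+57.0215 mono) per cysteine. The
diagnostic reduction-plus-alkylation experiment shifts a fully
disulfide-bonded peptide by H + CH₂CONH₂ = 58.03 Da per cysteine (nominally
58), which is how CRP peaks are recognised in screening.

Digestion uses the Keil rules: trypsin cuts C-terminal to K/R,
chymotrypsin (high specificity) C-terminal to F/W/Y (a low-specificity
F/W/Y/L/M variant is available); neither cuts before proline. Fragments
with up to the requested number of missed cleavages carry 1-based inclusive
spans and both mass kinds; the zero-missed fragments tile the parent, and
fragment masses satisfy hydrolysis conservation (Σ masses − (n−1)·H₂O =
parent mass), both fuzz-tested.

## Synthetic data: what it does and does not emulate

The generator draws class fingerprints as sums of Gaussian marker peaks on
a 2000–6000 Da grid of 30935 points (the matrix width of the motivating
study), with the four published marker masses as the two default class
templates (RH: 3944.3/4780.1; RA: 3811.8/4724.4). Per replicate it applies
a multiplicative amplitude error per marker (CV 0.1), additive white noise
(sd 0.02 on unit-amplitude peaks), a constant baseline (0.05), a rigid m/z
shift (sd 1 Da ≈ 8 grid points) and a smooth 5-knot warp (sd 0.5 Da) —
magnitudes chosen once as plausible for reflector-mode MALDI peptide
profiles and triplicate spotting. One integer seed drives
counter-derived substreams per (class, sample, replicate), so datasets are
reproducible and order-independent. The default benchmark is 38 + 49
samples in triplicate.

Not emulated: isotope envelopes and adducts, detector saturation,
mass-dependent resolution, chemical noise, correlated baseline structure,
and matrix/suppression effects. Consequently, passing benchmarks shows the
algorithms behave correctly on signals with the stated distortion model —
it does not certify accuracy figures on real deposited spectra, which carry
richer structure.

A consequence worth naming: SIMCA's residual F-test with (p−k, …) degrees
of freedom assumes residuals spread over ~p independent channels. Real and
simulated profile residuals are dominated by a few structured directions
(shift/warp misfit), so the test is sharply conservative and can unassign
many warped in-class samples — visible in the benchmark report, and the
reason class modelling is the weakest of the five models there. This is a
faithful property of the method, not a defect of the implementation;
relaxing α or modelling more components per class softens it.

## Problem sizes and determinism

The shipped tests run the full pipeline at the study-scale matrix
(87 × 30935) once and use reduced grids (hundreds to thousands of points)
elsewhere; both complete in seconds to a couple of minutes on one CPU.
Every stochastic component flows from a single integer seed; re-running any
stage with the same config and seed reproduces reports bit-identically
(runtimes are deliberately kept out of report files).
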