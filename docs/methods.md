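# Methods

This note documents the models and procedures implemented in
`tractmvpa`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical decisions that
affect results.

## Synthetic tract and cohort

**Skeleton geometry.** `make_skeleton` grows a connected tube of integer
1-mm voxels along a smooth random cubic-spline curve between two
end-regions, labelled `frontal` (arc position t = 0) and `temporal`
(t = 1) after the uncinate-fasciculus anatomy the generator emulates.
Voxels are accepted only if 26-adjacent to the tube grown so far, so the
skeleton is a single connected component by construction and carries an
exact voxel count.  Default sizes are 940 voxels (right) and 832 (left),
matching the descriptive scale of a skeletonized uncinate; `end_fraction`
(default 0.1) fixes the share of voxels per end region.

**DTI metrics.** Everything derives from per-voxel tensor eigenvalues
with λ₂ = λ₃: AD = λ₁, RD = (λ₂+λ₃)/2, MD = (AD+2·RD)/3, and FA by the
standard tensor formula
FA = √(3/2)·‖λ−λ̄‖/‖λ‖.  Because the metrics are computed *from* the
eigenvalues after admissibility is enforced (λ₁ ≥ λ₂ = λ₃ ≥ 0), the
identities hold to machine precision for every generated voxel.
Baselines are conventional healthy white-matter skeleton magnitudes,
AD = 1.2×10⁻³ and RD = 0.55×10⁻³ mm²/s (hence MD ≈ 0.77×10⁻³); they are
textbook values, not fitted to any dataset.

**Noise model.** Between-subject variability has three components, all
in mm²/s: a per-subject global offset (SD 2.5×10⁻⁵) shared by all
voxels, a spatially smooth per-subject field (SD 2.5×10⁻⁵) drawn from a
Gaussian random field with exponential covariance exp(−d/ℓ) over voxel
Euclidean distance (decay length ℓ = 5 voxels, sampled by Cholesky
factorization), and unsmoothed i.i.d. noise (SD 5×10⁻⁶).  The implied
per-voxel between-subject SD is √(Σ SD²) ≈ 3.6×10⁻⁵ mm²/s, roughly 5 %
of the MD baseline — a realistic order for skeletonized DTI.  No
deposited data informs these values; they are the package's fixed study
conditions.

**Group effect.** The implanted athlete-minus-control difference on a
chosen metric is `amplitude · w(t)` with
w(t) = exp(−(t/τ)²) − exp(−((1−t)/τ)²) (taper τ = 0.2): +amplitude at
the frontal-end centre, −amplitude at the temporal-end centre, zero
mid-tract.  An MD effect shifts all three eigenvalues equally; AD/RD
effects shift only the corresponding eigenvalues.  The default amplitude
is 3× the per-voxel noise SD, the condition used throughout the tests;
parameters that would drive any diffusivity negative are rejected.

**Behaviour.** Each subject's go/no-go performance is simulated from the
scheduled task (9 digits × 25 repetitions, 250 ms stimulus + 900 ms ISI,
no-go on digit 3): commission errors are Bernoulli per no-go trial with
a subject-level logit-normal probability (athletes centre 0.55,
controls 0.30), reaction times Gaussian over correct go trials (athlete
mean 340 ms vs control 400 ms, between-subject SD 35 ms, trial SD
60 ms).  Questionnaire scores are T-score-like Gaussians (athletes
58 ± 7 aggression / 56 ± 7 mania, controls 48 ± 7 / 47 ± 7), optionally
regenerated by a linear-Gaussian model whose population correlation with
a named tract summary (default: mean AD within athletes) equals a
requested target (default −0.543 for aggression).  Effect sizes
(d ≈ 1.4–1.7) were chosen once so a 19-vs-17 comparison detects the
implanted directions at p < 0.05 with high power; they are plausible for
a strongly selected clinical contrast but are not calibrated to any
dataset.

**What the generator does not emulate.** No raw diffusion signal, tensor
fitting, tractography, registration error, scanner/site effects,
age–metric dependence, or non-Gaussian outliers.  Passing tests
therefore demonstrate the *pipeline's* statistical behaviour
(calibration, recovery, no leakage) under a clean generative model, not
robustness to real-data artefacts.

**Reproducibility.** One global seed fans out through
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stream, subject))`,
so each subject's data is a counter-based independent stream:
regenerating any dataset from its stored seed is bit-identical, and a
subject's data does not depend on cohort size.

## Tract-map preparation

Visitation counts are divided by the waytotal (counts/waytotal ∈ [0,1]).
Thresholding retains voxels with value ≥ fraction × P95, where P95 is
the 95th percentile, by linear interpolation between order statistics,
of the *strictly positive* within-tract values — background zeros are
not part of the tract's intensity distribution.  Ties at the threshold
are retained (closed threshold).  Retained-voxel counts depend on the
percentile convention, which is why it is fixed and documented.
Defaults: fraction 0.20 (uncinate), 0.40 (SLF control tract).
Averaging subject maps into a group map is available both before and
after thresholding behind a switch; neither order is asserted as
canonical.

## Feature selection

Per-voxel two-class F-score
F(v) = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s⁺² + s⁻²) with n−1 sample variances;
a voxel constant in both classes scores 0 when the means agree and +∞
when they differ.  The top ceil(fraction·V) voxels are retained (ceil so
a positive fraction never retains zero voxels), ties broken toward the
lower voxel index.  Selection is always computed inside the training
fold.

## Classifiers

**Kernel SVM.** Soft-margin C-SVC solved by an in-package SMO dual
solver with second-order (maximal-gain) working-set selection, jitted
with numba.  This solver exists for throughput: a permutation test
re-runs LOOCV with grid search for every relabelling, which at the
package's cohort sizes means millions of fits of ~20-subject problems;
the in-package solver fits one in ~20 µs.  It is cross-checked against
libsvm (via scikit-learn) on random instances in the test suite, both in
decision values and dual objective.  `gamma="scale"` follows the
1/(n_features · Var) convention; the polynomial kernel is
(γ·x·x′ + 1)³ by default.

**ElasticNet logistic regression.**
min (1/n)Σ log(1+exp(−yᵢ(xᵢ′β+b))) + λ₁[α‖β‖₁ + (1−α)/2‖β‖₂²],
intercept unpenalized, solved by FISTA with a constant 1/L step
(L = ‖[X,1]‖²/(4n); the ridge term lives in the proximal operator).
Convergence requires both a flat objective (relative change < 10⁻¹²
over 10 iterations) and a small proximal-gradient mapping
(< 10⁻⁸·(1+‖w‖)); the stationarity condition matters because on flat
problems the objective plateaus while coefficients are still moving.
λ₁ = 0 on separable data is unbounded by design; the iteration cap
triggers a convergence warning and returns the last iterate.

**Total-variation logistic regression.**
min (1/n)Σ log(1+exp(−yᵢ(xᵢ′β+b))) + λ₁‖β‖₁ + λ_TV‖Dβ‖₁, where D is
the ±1 edge-difference operator of the skeleton's 26-neighbour adjacency
(anisotropic TV, which keeps the ADMM subproblems separable; the
isotropic variant is a known alternative).  ADMM with splitting
z₁ = β, z₂ = Dβ: the (β,b) update is a Newton solve of the smooth
logistic-plus-quadratic subproblem, both z updates are soft-thresholds,
and ρ follows the standard residual-balancing rule (×2 / ÷2 when one
residual exceeds 10× the other).  Stopping tolerances are
abs 10⁻⁸ / rel 10⁻⁶ on the primal and dual residuals with a 5000
iteration cap; these are tight because the package asserts coefficient
level agreement with the λ_TV = 0 lasso limit.  ADMM is not a descent
method, so the objective trace need not be monotone; the solver records
the trace and returns the best iterate encountered.  Reported
coefficients come from the sparsified consensus block (z₁), which
carries exact zeros.

**Standardization.** All families z-score each voxel with training-fold
mean/SD (population SD, zero-variance columns left unscaled) and apply
the same parameters to test subjects; this is standard for penalized
models and is switchable off.  Decision scores are oriented so larger
means more "+1-like"; a score of exactly 0 predicts +1.

## Evaluation protocol

**LOOCV + grid search.** For every fold the F-scores, the voxel
selection and the standardization are computed from the n−1 training
subjects only.  The default (non-nested) mode picks the grid point
maximizing LOOCV accuracy and reports that point's held-out predictions
— the optimistic placement implied by a single-loop design.  This
optimism is deliberate and safe *for the permutation p*, because the
null repeats the identical procedure, grid search included, for every
relabelling; a fully nested inner/outer mode is available when an
unbiased accuracy itself is wanted.  Grid combinations are enumerated
deterministically (fraction-major) and accuracy ties resolve to the
earliest combination.  The default full grids are
fractions {0.01,…,1}, C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2³} (log₂ steps of 2);
`GridSearchSpec.desk_scale()` (fractions {0.2, 1}, C {1, 100},
γ "scale") is the documented reduced grid used in the examples,
calibration studies and CLI defaults.

**A note on LOOCV under the null.** LOOCV accuracy on exchangeable data
is *pessimistically* biased (≈0.35 at 10 vs 10): removing a subject
tilts the training class balance against its own class.  The suite
asserts the absence of optimistic bias rather than a mean of 0.5, and
the permutation p-values remain calibrated because the null ensemble
carries the same bias.

**ROC / AUC.** One curve from the pooled held-out decision scores
(with a single held-out subject per fold there is no per-fold curve to
average), swept from +∞ to −∞; AUC by trapezoid equals the Mann–Whitney
pair statistic with ties counting ½, asserted against an enumeration
oracle.

**Permutation test.** Permutations are uniform random relabelings
(class sizes preserved automatically), seeded.  p is the raw fraction of
null statistics ≥ the observed one — ties count, and p = 0 is possible —
with the never-zero estimator (b+1)/(m+1) reported alongside.  The
statistic is accuracy by default, AUC selectable.  Study-scale runs use
10,000 permutations; the desk-scale default is 500.  Null-ROC contours
interpolate every null curve onto a common FPR grid and take the
pointwise (1−p) order-statistic quantile, so contours are nested and the
level has the counting interpretation.

## Interpretation maps

The covariance map is the per-voxel sample covariance (n−1 denominator)
between feature and the ±1 group coding; its sign says which group has
the larger mean, and it is exactly antisymmetric under label flip.  TFCE
uses E = 0.5, H = 2, dh = max/100 — the established convention for
skeletonized data — with 26-connectivity cluster extent, a closed
(≥ h) threshold, and two-sided handling by enhancing the positive and
negated maps separately and re-signing.  FWE inference permutes labels,
takes the max |TFCE| per permutation, includes the unpermuted labelling
in the ensemble (so p ∈ [1/n_perm, 1]), and reports per-voxel
p = fraction of null maxima ≥ |TFCE(v)|.

Bootstrap coefficient maps resample subjects with replacement at *fixed*
hyperparameters (the full-data optimum): re-optimizing the grid inside
10,000 resamples would be computationally disproportionate and would
change the estimand from "the coefficients of this model" to "the
coefficients of a moving model".  Resamples missing a class are redrawn
and counted.  Diagnostics (sign agreement, Pearson r) compare the mean
coefficient map to the covariance map over the non-zero support only.

## Univariate statistics

Pooled-variance (Student) t-test, two-tailed, matching the plain
two-sample design; Welch is available as an option.  Pearson p-values
use t = r√((n−2)/(1−r²)).  The age-partialled correlation uses the
first-order formula, verified against the residual-regression route to
10⁻¹⁰.  Fisher z = arctanh r; |r| = 1 maps to a signed infinity with a
warning.  The exploratory correlation battery applies no multiple-testing
correction to its decisions, but the tidy output table carries
Benjamini–Hochberg adjusted p-values alongside for transparency.

## Problem sizes used in tests and the acceptance script

Calibration: 200 replicate null datasets (10 vs 10 × 50 voxels), 200
permutations each.  Signal recovery: 20 replicates of 19 vs 17 on 900
voxels, 500 permutations each.  Covariance recovery: 200 per group.
TFCE permutation checks: 150–300 voxels, 50–200 permutations.
Bootstrap maps: 40–200 resamples in tests (10,000 is the study-scale
setting).  These sizes were fixed once as desk-scale analogues of the
study-scale settings.

## Known limitations

- The generator's noise amplitudes and behavioural effect sizes are
  package choices, not estimates from data; absolute accuracies on the
  synthetic cohort say nothing about accuracies on real cohorts.
- Anisotropic TV differs from the isotropic variant of the cited
  literature by the norm over edge differences; coefficient maps can be
  axis-aligned blocky.
- The SMO solver targets small cohorts (tens of subjects); it makes no
  attempt at shrinking/caching and is unsuitable for n ≫ 100.
- LOOCV accuracy is a high-variance estimator; at n = 36 its
  permutation p is meaningful but the accuracy itself has a wide
  sampling band.
- Lasso-type solutions are not always unique; coefficient-level
  comparisons (e.g. the λ_TV → 0 limit) are asserted on well-conditioned
  instances and can degrade on near-separable data.
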