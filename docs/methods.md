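# Methods

This note documents the models, numerical choices and known limitations of
the package. It is written for someone who wants to know exactly what is
computed and what passing the test suite does and does not establish.

## Synthetic cohort model

No raw data from the clinical study this pipeline emulates are available,
so the generator is an explicit stand-in, built to reproduce the *study
design* (four groups of tens of subjects, 240 volumes at TR = 2 s, one
shared gray-matter mask in a common space, low head motion, clinical
scores per group) rather than the biophysics of BOLD.

**Signal model.** Each gray-matter voxel's series is a weighted sum of
band-limited latent signals plus i.i.d. Gaussian noise (default
SD 1):

```
x_v(t) = g · s0(t) + Σ_k λ_k,i(group, v) · s_k(t) + ε_v(t) + baseline + drift
```

* `s0` is a global latent shared by all GM voxels with loading `g = 0.3`,
  giving weak widespread correlation (r ≈ 0.08) the way real gray matter
  shares global signal.
* Each `EffectSpec` plants one latent `s_k` shared by the voxels of one
  region; the loading depends on the subject's group, so groups differ in
  within-region correlation and hence in GBC. Latents are synthesized in
  the frequency domain with support restricted to 0.01–0.08 Hz, so planted
  structure survives the band-pass exactly.
* Per subject, the group loading is jittered multiplicatively
  (relative SD 0.15 by default). For the target group the depression score
  is `hdrs17 = intercept + slope · λ_i + noise` (defaults 11, 8, SD 4),
  planting a connectivity–severity correlation.
* White matter and CSF compartments carry their own weak common latents so
  the nuisance mean regressors are non-trivial; a baseline of 100 and
  per-voxel linear drift give the detrending something to remove.
* Motion traces are smoothed Gaussian random walks, zero at the first
  volume; translation increments have SD `motion_level` (default 0.02 mm)
  and rotation increments `motion_level/50` rad so both contribute equally
  to FD on a 50 mm sphere. The default yields mean FD ≈ 0.1 mm, matching
  a well-behaved clinical cohort.
* Masks are concentric ellipsoids (WM core, GM shell — always the largest
  compartment — CSF rim) on the requested grid; one shared mask per
  cohort, since the emulated analysis normalizes all subjects to one
  template.
* Reproducibility: a master `SeedSequence` spawns one independent stream
  per subject, so identical config + seed reproduces every array bit for
  bit.

**What the generator does not emulate:** scanner physics, spatial
registration error, physiological (cardiac/respiratory) noise, anatomy,
spatial autocorrelation of the noise floor. Passing tests therefore show
the *pipeline arithmetic* is correct and calibrated, not that the method
would behave identically on real scans.

## Preprocessing and motion QC

In-scope stages operate on images already in a common space: volume
discard (default 10), joint nuisance regression, detrending and band-pass.
Out of scope (the synthetic space makes them moot): slice timing,
realignment estimation, segmentation/normalization.

The nuisance/detrend/filter step is implemented as a single orthogonal
projection: the ideal rectangular band-pass (an exact projection in the
DFT basis) is applied to the data *and* to the regressor matrix
(constant, polynomial trend, 6 motion parameters, global/WM/CSF means),
and the filtered data are residualized on the filtered regressors by least
squares. Consequences, all tested: residuals are exactly orthogonal to
every raw regressor; a pure trend maps to zero; in-band sinusoids pass
with gain 1 and out-of-band with gain 0; and the whole operation is
idempotent. Whether the original analysis regressed nuisance before or
jointly with detrending is not documented anywhere we could rely on; the
joint projection was chosen because it is order-free. Columns annihilated
by the filter are dropped; a rank-deficient remainder triggers a warning
and a pseudoinverse fit (short series make the filtered regressors
linearly dependent by construction).

FD uses the Power convention (sum of absolute parameter differences,
rotations converted to arc length on a 50 mm sphere), with motion-file
rotations assumed in radians (a degrees flag is provided, since
realignment dialects differ). QC is count-only: volumes with FD > 0.3 mm
(strict) are counted, never removed; a subject passes when mean FD
< 0.3 mm and the flagged count < half the series (both strict, matching
the quoted inequalities; for 230 volumes the bound is 115).

## GBC mapping

The weighted-z variant (default) sums Fisher-z transformed correlations
over edges with r ≥ 0.25; the binary variant counts them. The threshold is
one-sided — negative correlations never contribute. Correlations are
clamped at 1 − 1e−7 before `atanh` so duplicated series cannot produce
infinities; zero-variance voxels get GBC 0 with a warning. The voxel×voxel
matrix is never materialized: rows are processed in blocks (default 512),
with results identical to the brute-force double loop (property-tested up
to 50 voxels, and at block sizes that force multiple blocks).

Map order is fixed: compute → standardize → smooth. Standardization is
across the mask (mean 0, SD 1 — the "zGBC" scale); the alternative
across-subject standardization (per voxel over the cohort) is available as
`standardize_across_subjects`, since which of the two the original
toolchain meant by its second "Z transformation" is not decidable from the
text. Smoothing is a separable Gaussian with σ = FWHM/(2√(2 ln 2)),
renormalized by the smoothed mask so values outside the mask never leak in
and a constant map is unchanged.

A consequence of across-mask standardization worth knowing: when a planted
region dominates the map's variance (small synthetic masks, strong
loadings), dividing by the map SD cancels much of the *between-subject*
loading variation, attenuating planted GBC–severity correlations. At
moderate loadings the correlation survives (the recovery test operates
there); the demo in `analysis/` shows the attenuated, marginal case.

## Classification

Features are the mask voxels of each subject's zGBC map. The kernel is
linear on features mean-centered with the *training-fold* means only —
centering inside the fold is the leakage-safe reading, and a sentinel test
verifies that corrupting a held-out subject cannot change that fold's
model. Per-fold centered kernels are derived from the raw Gram matrix by
the centering identity, so the feature matrix is touched once.

* **SVM**: soft-margin dual on the precomputed kernel (libsvm via
  scikit-learn), cost fixed at 1 (exposed in config); the decision value
  is the reported score.
* **GPC**: our own Laplace-approximate Gaussian-process classifier on the
  precomputed kernel — linear covariance plus a unit bias term, logistic
  likelihood, stabilized Newton mode finding, MacKay approximation for the
  predictive probability. It is cross-checked against an independent
  Laplace GPC implementation (scikit-learn with a DotProduct kernel):
  latent modes agree to 1e−6, predictive probabilities to 0.03 (the two
  use different approximations of the predictive integral).
* **Multiclass GPC** is one-vs-rest with normalized probabilities — a
  documented deviation from a joint multinomial Laplace GP, whose exact
  formulation in the original toolchain is not described. Probability ties
  break by sorted class order.

LOSOCV requires ≥ 2 subjects per class. Balanced accuracy is the
unweighted mean of per-class recalls (= (sens+spec)/2 for two classes);
per-class metrics in the multiclass case are one-vs-rest. The binary ROC
pools the n held-out scores into one curve. On pure-noise features the
LOSOCV balanced accuracy is slightly pessimistic (the familiar
leave-one-out anti-correlation), but stays within the 95% binomial band
around chance in the calibration tests (binary and four-class).

## Permutation inference

One unrestricted label shuffle per repetition drives both the performance
test and the weight-map test (a single permutation scheme; kernels don't
depend on labels, so only the fits are redone). p = count(null ≥
observed)/n_perm exactly — ties count, p = 0 is reported as "< 1/n_perm",
and an optional (count+1)/(n_perm+1) estimator is off by default.

Voxel weights are reconstructed from the dual coefficients
(w = Σ αᵢ xᵢ, verified against a primal solver to 1e−6) and averaged over
folds (whole-sample refit available). Before the voxel-wise two-sided
comparison, every weight map — observed and null alike — is scaled to unit
Euclidean norm. This is essential, not cosmetic: a soft-margin fit on
shuffled labels is non-separable and accumulates far more dual mass than
the separable observed fit, so raw null |w| stochastically dominates the
observed map everywhere and no voxel can ever reach small p. Normalization
makes the test one of *relative* voxel contribution and preserves
exchangeability under the null (measured voxel false-positive rate at
p ≤ 0.001 is 0.002 ≈ 2/1001, the exact discrete expectation). The sign of
the observed weight labels voxels positive/negative discriminative;
clusters are connected components (26-neighbour default; 6/18 available)
of p < threshold voxels, split by sign, kept when size > 30 (strict — a
30-voxel blob dies, a 31-voxel blob survives), and verified against a
flood-fill oracle.

Two initial design expectations were corrected by measurement, both
documented here deliberately: (1) the planted-region recovery rate at
per-voxel d = 2 requires ~40 subjects to put half the region at p ≤ 0.001
even with normalization; (2) duplicating a feature column does *not*
preserve the summed weight for margin-regularized models (duplication
halves the effective penalty on that direction) — the duplicates split the
weight exactly symmetrically instead, which is what the suite asserts.

## ROI statistics and TFCE

ROI values are arithmetic means of cluster voxels. The Bonferroni
threshold implements the pairwise rule α/(m(m−1)/2) — 66 tests for 12
ROIs — exactly as the emulated analysis prints it, with the conventional
α/m as an option; whether the pairwise denominator was intentional there
cannot be resolved, so fidelity won over plausibility. Partial correlation
residualizes both variables on [1, covariates] and correlates the
residuals (df = n−2−k, two-sided; equal to plain Pearson with no
covariates; checked against pingouin). The summary-statistic ANOVA
recovers the raw-data F exactly and reproduces the emulated study's
scrubbing-volume F (0.2606 vs the printed 0.2630, a rounding-level match);
the printed mean-FD F does not recompute from its own printed summaries
under any group ordering we tried, so nothing is asserted about it.

The covariate-adjusted group test is the per-voxel OLS t on the group
indicator in `value ~ 1 + group + covariates` (vectorized across voxels;
equal to the pooled two-sample t without covariates; checked against
statsmodels). TFCE uses E = 0.5, H = 2 (field defaults — none are given
in the emulated analysis), step dh = max|t|/100 shared between observed
and null maps, positive and negative tails enhanced separately and
carried with sign. An isolated voxel with t = h₀ integrates to
≈ h₀^(H+1)/(H+1), the closed form the unit test checks. FWE correction
permutes group labels only (covariates stay attached to subjects — the
simple scheme; a Freedman–Lane refit is noted as future work), refits the
t map, and compares observed |TFCE| to the null distribution of the
image-wide maximum; corrected p-values are multiples of 1/n_perm and the
weak-FWE calibration test verifies the family error rate at its discrete
expectation.

## Frozen study conditions (`gbcmvpa.study`)

The headline synthetic analyses run at desk scale: 12³ grids (272 GM
voxels), 240 volumes (230 analyzed), 20 subjects per group for binary
contrasts and 15 for the four-class problem, one 40-voxel planted region
per contrast. Planted loadings were calibrated once over cohort seeds
1–12 and then frozen: 0.28 ("moderate", realized per-voxel standardized
regional effect ≈ 2.9) keeps the binary LOSOCV balanced accuracy above the
emulated study's depressed-vs-non-depressed figure across seeds, and 0.32
("strong", effect ≈ 3.8) does the same for the patients-vs-controls
figure. These are design constants of the synthetic study, chosen so the
clinical figures act as lower bounds on the synthetic analogues; problem
sizes were chosen so the whole acceptance run completes in about a minute
on one CPU.

## Known limitations

* The generator's single-latent-per-region design makes region-edge noise
  coherent within subject, so GBC effect sizes and classifier accuracy
  vary more across cohort seeds than independent-voxel intuition suggests.
* Cluster anatomy is meaningless on synthetic grids; no atlas labeling is
  attempted.
* GPC predictive probabilities use the MacKay approximation; differences
  from other Laplace implementations are ≲ 0.03 in probability.
* LOSOCV inherits its known variance and slight pessimism; no alternative
  CV schemes are provided, matching the emulated analysis.
* The voxel-wise weight test's unit-norm convention means its p-values
  compare contribution *patterns*, not absolute weight magnitudes.
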