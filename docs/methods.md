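# Methods

This note documents the statistical procedures implemented in morphsim,
the synthetic-data model used to exercise them, and the design choices
made where the analysis convention was genuinely open.

## MSN construction

Each subject contributes a regions × features matrix of morphometric
measurements (canonically six surface-derived features per parcel:
cortical thickness, fractal dimension, gyrification index, mean
curvature, sulcal depth, and a surface metric; units are heterogeneous).
Each feature is z-scored across regions within subject (sample SD,
ddof=1), which makes the network invariant to affine rescaling of any
raw feature.  The MSN edge weight is the Pearson correlation between the
two parcels' feature vectors; the diagonal is structurally zero and
excluded from all statistics.

Regional strength is the *signed* mean edge weight of a parcel.  Signed,
because the edge-change taxonomy (decoupling / dedifferentiation /
hypercoupling / hyperdedifferentiation) is defined on signed weights, and
taking magnitudes first would conflate decoupling with strengthening.
Strength is computed on the full-density matrix by default: the
definition is the mean over *all* other regions, and no particular
connection density is canonical.  `threshold_density` (keep the top
⌈density·E⌉ edges by |weight|, deterministic lexicographic tie-break) is
available for sensitivity analyses but off by default.

Missing feature values are rejected at load rather than imputed; there is
no principled imputation rule at the parcel level, and silent imputation
would bias similarity toward the column mean.

## Regional contrasts

Per region, ordinary least squares of strength on
[1, age, sex, age×sex, group], sex M=0/F=1, group dummy control=0/case=1,
fit separately for each case group against controls (two-group models,
not one three-level model, so that each contrast has its own residual
variance).  Age and the interaction are left uncentred, matching the
model as usually written.  The β₄ t-statistic (df = n − 5) with a
two-sided p feeds Benjamini–Hochberg FDR across regions, applied
separately per contrast.  Rank-deficient designs (e.g. a single-sex
subsample makes age×sex collinear with age) are rejected with the
offending columns named.

A caveat the synthetic experiments make vivid: because every edge couples
two regions, a true similarity change at k regions moves the strength of
*every* region that connects to them.  Contrast maps therefore show
spillover — many regions beyond the truly affected ones reach
significance — while the affected regions still dominate the top of the
|t| ranking.  Regional significance should be read as "strength changed",
not "this region is the lesion site".

The edge taxonomy compares group-mean matrices edge by edge: with HC mean
h and case mean c, decoupling is h > 0 > c, dedifferentiation h < 0 < c,
hypercoupling 0 < h < c, hyperdedifferentiation c < h < 0.  Weakened
same-sign edges and zeros match none of the four published definitions
and are reported as unclassified, excluded from the proportions.  The
"altered connections" denominator is not canonically defined; the default
mask is edges with an uncorrected two-sample t-test p < 0.05 between
groups, and any symmetric boolean mask can be supplied instead.

Clinical associations use Spearman correlations (average ranks for ties)
between strength (global mean or per region) and the ordinal NIHSS / mRS
scores, per patient group, with BH-FDR across regions; fewer than four
complete observations or a constant score raise an explicit error rather
than propagating NaN.

## Spin permutation

The spatial null rotates the left-hemisphere spherical centroids by a
Haar-uniform rotation (QR of a Gaussian matrix, determinant corrected to
+1) and the right hemisphere by the sagittal mirror conjugate, then
assigns each parcel the value of the nearest rotated centroid within its
hemisphere.  Nearest-neighbour assignment with reuse was chosen over
exclusive matching: it is the standard parcel-level convention, is
deterministic, and avoids an assignment-problem solve per spin; the
number of distinct source parcels per spin is recorded.  The p-value is
two-sided with the +1 finite-sample correction, so p ∈ [1/(n+1), 1] and
(seed, n_spins) fully determine it.  Maps covering only the left
hemisphere (transcriptomic analyses) spin within the left hemisphere
alone.  The default spin count for production runs is 10,000; the test
suite uses 500 and logs the count.

## PLS transcriptomics

Predictors are the regions × genes expression matrix, column-standardized
(heterogeneous gene scales would otherwise dominate the weights);
the response is the centred contrast t-map over the same regions.  The
first-component weight vector is the normalized covariance of predictors
with the response; subsequent components deflate the predictors (NIPALS
recursion for a univariate response).  Scores are mutually orthogonal, so
the incremental response variance of component k is (tₖ'y)²/(tₖ'tₖ)/(y'y).

Component screening permutes the response across regions (n_perm
refits) and compares the observed incremental variance explained per
component with its permuted distribution; the permutation statistic
could equally be read cumulatively, so the cumulative null is retained
alongside.  Gene-level inference bootstraps regions — the only
exchangeable unit available — refits the first component per replicate,
sign-aligns each replicate weight vector to the original component
(PLS signs are arbitrary), and summarizes each gene by Z = bootstrap mean
weight / bootstrap SD with a two-sided normal tail p and BH-FDR.  The
bootstrapped quantity is the component-1 predictor weight vector; "weight"
and "loading" are used interchangeably in this literature, and the weight
is the quantity that is well-defined for every gene in one refit.
Replicates with a constant resampled response or a constant resampled
gene column are discarded and logged.

Gene calls require both |Z| > 3.0 and q below the FDR gate (default
0.05; a stricter 0.005 preset matches the more conservative convention
also in circulation — both are plain arguments).  Only the first
component is carried into gene calling; later components are computed and
reported but not used.  Per-gene spatial checks emit both the analytic
Spearman p and the spin p (with BH q on each), since either may be wanted
as the FDR input.  Over-representation of called genes in GMT sets is an
upper-tail hypergeometric test against a user-chosen background, BH
across sets, with sets lacking background overlap skipped and logged.

## Synthetic data

No generative model for this kind of study exists to copy — the design is
observational — so the generator is an explicit artifact whose purpose is
to give every estimator a ground truth.  What it emulates: regional
morphometric profiles with strong shared structure and smooth spatial
variation, planted group effects in known regions, subject-level severity
that clinical scores track ordinally, and spatially autocorrelated
expression with a planted gene program.  What it does not emulate:
voxel/vertex-level imaging, lesion geometry, donor/probe structure of
atlas expression, or site/scanner effects — so passing tests demonstrate
statistical correctness of the pipeline, not robustness to those
real-data complications.

The feature model is

    F[s, r, f] = B[r, f] · (1 − e · sev[s] · 1{r affected for group(s)})
                 + offset[s] + N(0, σ_noise),
    B[r, f] = √w_g · g[f] + √(1 − w_g) · L[r, f],

with g a shared cortical profile (normalized to fixed energy), L
per-feature Gaussian fields with covariance exp(−d/ℓ) over great-circle
distance d (right hemisphere mirrored onto the common sphere, so
homotopic regions co-vary), e the effect size, and sev[s] a mean-one
lognormal severity.  Defaults: e = 1.5, σ_noise = 0.5, w_g = 0.9,
ℓ = 1.0 rad, severity sigma 0.1, ages U(40, 70) years (a typical stroke
cohort mean of ~55), sexes balanced, NIHSS/mRS by monotone binning of a
Gaussian-copula latent with rank correlation 0.4 to the severity channel.

The group effect deserves its own paragraph.  An additive shift applied
identically to every feature of a region — the first mechanism one might
try — is *provably invisible* to the MSN: Pearson correlation between
region vectors centres each vector, so a constant offset cancels exactly.
The implemented effect is instead a partial inversion of the affected
region's baseline profile (factor 1 − e·sev ≈ −0.5 at default settings):
the region's morphometric signature rotates away from, then against, its
healthy pattern.  This is the minimal mechanism that moves similarity at
all, and it reproduces the decoupling phenomenology: affected
high-strength regions lose the most similarity, giving the negative
strength-vs-t correlation characteristic of this analysis.  The large
shared-profile weight (w_g = 0.9) reflects how strongly real regional
morphometric profiles co-vary; it also determines how sharply planted
regions separate from spillover in the |t| ranking.

Expression: planted genes are slope·standardized(effect map) plus a
unit-variance smooth field; other genes are field only.  Defaults:
slope 2.0, same kernel as the features.

## Problem sizes and numerics

The suite runs at a reduced scale — 60 regions (30 per hemisphere), 10–30
subjects per group, 300 genes — with full 308/152 shapes exercised in
shape checks; these sizes keep the complete suite under two minutes
while leaving every statistical property measurable.  Calibration checks
use 100–200 replicates against exact binomial or KS criteria; spin tests
in the suite use 500 spins.  Cholesky factorizations add 1e-8 jitter;
density thresholding breaks |weight| ties toward the lexicographically
smaller pair; all randomness flows from numpy `SeedSequence` spawning, so
identical seeds give bit-identical outputs, and reruns of the pipeline
are byte-identical (the config hash in output headers excludes the
output directory).

## Known limitations

* Strength spillover (above) means regional significance is not
  localization; only the rank structure identifies planted regions.
* Bootstrap Z measures the stability of a gene's weight, not null
  significance against chance association; with few regions the normal
  approximation for Z is rough, which is why the FDR gate is applied on
  top of the |Z| threshold.
* The spin null assumes parcels are well represented by spherical
  centroids; very elongated parcels are beyond it.
* The generator's clinical scores couple to a single latent severity; no
  lesion-volume or time-since-onset channels exist.
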