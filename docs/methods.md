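# Methods

## Scope and assumptions

The package quantifies amyloid-like uptake in 3-D PET volumes that are
already reconstructed, corrected and coregistered: the PET volume, tissue
probability maps, atlas labels and any user-drawn mask must share one
voxel grid (same shape; affines equal elementwise within 1e-3 mm).  No
resampling, registration, segmentation, partial-volume correction or
smoothing is performed.  Intervoxel distances are computed from index
offsets times the voxel spacing (the affine's column norms); oblique
affines are therefore treated axis-aligned for distance purposes and
volumes with substantial obliquity should be resampled upstream.  NaN
voxels (typically resampling margins) are counted and reported at load
time and treated as outside every mask thereafter.

## Masks

The target is cerebral gray matter: `gm_prob >= level` (default level
0.5) minus the cerebellar and brainstem atlas labels, so reference tissue
never contributes to target statistics.  White-matter reference masks use
`wm_prob >= level` with level 0.1 ("wm10", retaining border voxels
adjacent to gray matter) and 1.0 ("wm100", border voxels removed).  The
100 % threshold is implemented as `wm_prob >= 1 - 1e-6` because float
probability maps rarely store an exact 1.0.  Cerebellar gray matter,
brainstem and corpus callosum come from an integer label atlas (label ids
configurable by YAML; defaults match the synthetic atlas); a user-drawn
splenium mask may replace the atlas callosum.  Thresholding is monotone
by construction — raising the level never adds voxels — and an empty
reference region is an error naming the region.

## SUVR

`SUVR = PET / mean(PET over reference)`, the field-standard convention;
a median-based reference statistic is available behind a flag for
sensitivity analyses.  NaN or nonpositive reference voxels are excluded
from the reference statistic with a warning.  Target summaries are the
arithmetic mean and the midpoint-convention median of SUVR over the
target mask.  SUVR is exactly invariant under global rescaling of the
input volume, and normalizing to a hotter reference yields a voxelwise
smaller SUVR volume.

## The weighted two-point correlation function

For voxel values v₁, v₂ at distance d (mm), the pair weight is

    w = (v₁ + v₂)/2 · exp(−|v₁ − v₂| / λ)

λ (`lambda_diff`, default 1.0 in SUVR units) sets how quickly
dissimilarity suppresses a pair; it is reported in every output.  The
exact decay form is a package convention satisfying the defining
qualitative contract — weight is largest when both voxels are hot and
close in value; any bounded decay yields the same qualitative behavior
discussed below.

Pairs of distinct in-mask voxels with 0 < d ≤ r_max (default 10 mm) are
binned into half-open bins [k·w, (k+1)·w) of width 1 mm by default (a
pair at exactly r_max joins the last bin).  The curve value of a bin is
the mean weight of its pairs; a per-bin standard error accompanies it.
Empty bins are flagged and warned about — with 2 mm voxels the sub-2 mm
bins are structurally empty — and are filled by linear interpolation
(edge bins by nearest-value extension) *only* for integration.  The AUC
is the trapezoidal integral of the filled curve over the bin centers
(span r_max − bin_width for the default grid), so a constant-c image
yields exactly c per occupied bin and AUC = c × span.  The slope is the
ordinary-least-squares slope over occupied bins.  The AUC is the primary
scalar outcome; the slope is reported alongside.

### Pair sampling

The Monte-Carlo estimator draws `n_pairs` (default 50,000) pairs **with
replacement, uniformly over the set of valid unordered pairs**.  This is
achieved by drawing the first voxel with probability proportional to its
number of in-mask neighbours within r_max (its "degree", computed by FFT
convolution of the mask with the r_max-ball footprint and exact integer
rounding), then drawing the second voxel uniformly from that ball by
rejection (redraw the offset until it lands in the mask; a generous
round cap turns pathological masks into a diagnostic error).  Ordered
pairs then have probability deg(i)/Σdeg · 1/deg(i) = 1/Σdeg each, making
the per-bin mean an unbiased estimator of the exhaustive per-bin mean.
The simpler scheme of drawing the first voxel uniformly from the mask
weights each pair by ½(1/deg(i) + 1/deg(j)) and systematically
over-represents pairs touching low-degree boundary voxels — a real bias
on shell-shaped cortical masks, where most voxels are near a boundary —
so it is not used.  Sampling is fully reproducible: a single run seed
yields per-(subject, timepoint) seeds via SHA-256, and one pair sample
per scan is shared across all normalization schemes so that scheme
comparisons carry no between-scheme sampling noise.

### Exhaustive oracle

`ws2_exhaustive` enumerates *all* valid pairs via a k-d tree and is the
independent validation route; it is guarded to masks of ≤ 5,000 voxels
(≈ tens of millions of candidate pairs).  The test suite checks the
Monte-Carlo curve against it per bin within standard-error bounds and
verifies the expected ~1/√n shrinkage of the deviation.

### How the AUC responds to clustering and activity

On a uniform image of value c, every pair has weight c, so the curve is
flat at c and the AUC is linear in c: the AUC tracks overall activity
exactly.  At **fixed** mask mean, however, heterogeneity can only lower
the curve: w ≤ (v₁+v₂)/2 with equality only for identical values, so the
expected bin value is at most the (pair-marginal) mean and the uniform
image maximizes every bin.  Consequently the AUC *decreases* strictly
along a series of phantoms with growing focal-blob amplitude rebalanced
to constant gray-matter mean — a sign worth knowing when interpreting
the statistic.  In the disease-like regime, where focal clustering adds
to total uptake rather than redistributing it, the AUC *increases* with
blob amplitude; both directions are asserted by the property tests and
reported by the acceptance script.

A visit-to-visit drift of reference-tissue activity rescales the SUVR
volume by s = 1/(1+drift) and changes the SUVR mean by exactly |s − 1|.
The wS₂ pair weight becomes s·m·exp(−s|Δ|/λ): the difference term is
*less* suppressed at s < 1, partially offsetting the mean-term change, so
the relative AUC change is strictly smaller than the relative SUVR-mean
change whenever the image has any pair dissimilarity.  This is the
mechanism behind the drift-robustness property verified in the tests
(+5 % drift: 4.76 % SUVR-mean change vs ≈ 4.5 % AUC change on the
default blob phantom).

## Cohort statistics

Spearman's rank correlation (average ranks for ties, matching the
Pearson correlation of rank vectors; backed by scipy and cross-checked
against a brute-force rank-Pearson oracle in the tests) is computed for
every (scheme, timepoint, metric) cell between the PET outcome and the
biomarker.  Outputs carry the signed ρ — negative is the expected
inverse PET↔CSF direction — plus |ρ|.  Undefined cells (fewer than three
paired finite values, or constant input) are reported as NaN with a
warning, never silently dropped; subjects missing a value are excluded
pairwise per cell.  Duplicate (subject, timepoint, scheme) rows are an
error.  An optional Monte-Carlo permutation p-value is available but not
emitted by default.

The coefficient of variation is the sample SD (n−1) over the mean,
computed across subjects within each (scheme, timepoint, metric) cell;
the pooled CV per metric is the mean of those cells across timepoints
and schemes.  The manifest labels this convention.  (A per-subject
test–retest CV averaged over subjects is the natural alternative; the
across-subject pooling is the default because the cells are
cross-sectional.)

## Synthetic data

The phantom is a coarse geometric brain on an isotropic grid (default
64³ voxels at 2 mm): a spherical cortical shell (target GM, ≈ 19,000
voxels — ample support for 50,000 pairs within 10 mm), a WM core
(probability 1.0) with a graded rim at probability 0.3 so the wm10/wm100
masks genuinely differ, a callosum box carved out of the core, and
detached cerebellum and brainstem spheres.  Compartment activities
default to florbetapir-like contrast (GM 1.0, WM 1.6, rim 1.3 as a
partial-volume-like GM/WM mix, brainstem 1.5, callosum 1.7, background
0).  Focal uptake is a sum of Gaussian bumps (default 6 blobs, σ = 5 mm)
restricted to the GM shell, with centers drawn uniformly from shell
voxels; optional mean rebalancing pins the shell mean to isolate
heterogeneity.  Additive Gaussian noise (default SD 0.05) is applied
inside tissue only; noise uses a stream separate from the anatomy so
test–retest pairs share blobs while re-drawing noise.  All outputs are
byte-deterministic given the seeds.

Cohorts default to n = 21 subjects with two timepoints.  A latent
amyloid burden per subject, N(0.5, 0.38) (negative draws clip to zero
focal uptake in the volume route), drives (i) blob amplitude and (ii) a
diffuse cortical uptake of 0.9 activity units per unit burden — chosen
so the cerebellar-normalized SUVR spans ≈ 1.1–2.0, the range typical of
florbetapir LMCI cohorts.  The pseudo-CSF biomarker is
`220 − 110·burden + η + ε` pg/ml with per-subject biological scatter η ~
N(0, 20) and per-visit assay noise ε ~ N(0, 5), giving a cross-sectional
spread near 165 ± 45 pg/ml and a test–retest CSF CV of a few percent —
i.e. a stable-biology test–retest design.  A plateau variant (200 pg/ml
below the burden threshold, 125 above) reproduces the saturating
CSF-vs-SUVR pattern seen with cerebellar normalization.  The follow-up
scan applies a per-subject multiplicative reference-tissue drift
(SD 2 %).  Because burden and both noises are Gaussian under the linear
link, the population Spearman has the closed form ρ_S = (6/π)·asin(r/2)
with r = −b·σ_burden / √(b²σ²_burden + σ²_noise), which the replicate-
cohort tests recover within small-sample bias.

For replicate-heavy statistical validation (100 cohorts), a record-level
generator maps the same latent burden through strictly monotone
scheme-specific outcome functions instead of simulating volumes; rank
statistics are invariant to monotone maps, so the statistical claims
are identical at a fraction of the cost.  The image pipeline itself is
exercised end-to-end on volume cohorts in the CLI tests and the
acceptance script.

What the generator does not emulate: PET physics (point-spread function,
scatter, attenuation, reconstruction artifacts), anatomical variability
and atrophy, spatially correlated noise, and partial-volume mixing
beyond the single graded rim.  Green tests therefore certify the
estimators and their invariances, not scanner realism; absolute AUC or
CV values from phantoms should not be read as clinical reference values.

## Problem sizes and numerics

Test and acceptance runs use 32³ phantoms at 2 mm (exhaustive oracles on
≤ 5,000-voxel crops), 12³ 1-mm blob images for Monte-Carlo/exhaustive
comparisons, 50,000-pair estimates, 100 replicate record-level cohorts,
and 3–21-subject volume cohorts — sizes at which every quantity is
recomputable on a laptop in seconds to minutes.  Numerical conventions:
affine tolerance 1e-3 mm; wm100 epsilon 1e-6; per-bin variance uses the
n−1 estimator (undefined for single-pair bins); bins with zero pairs are
flagged, warned about and interpolated only for the AUC; the slope needs
at least two occupied bins, else NaN; all derived seeds stay below 2³¹.

## Known limitations

* Distances assume axis-aligned affines; oblique acquisitions must be
  resampled upstream.
* λ is a convention, not a fitted parameter; AUC values are comparable
  only at equal λ, which is why λ is embedded in every output row.
* The exhaustive oracle is limited to small masks by design; whole-brain
  validation is statistical (standard-error bounds), not exact.
* The splenium ROI must be supplied; no drawing tool is included.
* No kinetic modeling, SUV dose bookkeeping, or partial-volume
  correction.
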