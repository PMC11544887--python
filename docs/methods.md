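# Methods

This note documents the models, algorithms and numerical choices behind
`tumortract`, and what the synthetic phantoms do and do not establish about
behavior on real data.

## Scientific setting

Glioblastoma recurs almost universally because tumor cells invade the
surrounding brain beyond the resectable margin, preferentially along white
matter. High-angular-resolution diffusion MRI can map the orientation
structure of tissue; tractography seeded against a segmented tumor region
produces *tumor-associated tractograms* whose geometry (how far coherent
tracts project outward from the tumor, and in how many distinct bundles)
is a candidate imaging marker of invasion and of survival. The package
implements that analysis chain — q-space orientation reconstruction,
deterministic streamline tracking, tumor-tract selection and
classification, tract-derived metrics, quartile survival statistics, and a
tract-associated RNA-seq differential-expression stage — with synthetic
generators standing in for patient scans and biopsies.

## Synthetic DWI phantoms (`phantom`)

Signal model. Per voxel the diffusion-weighted signal follows the
multi-tensor forward model

    S(g, b) = S0 [ Σ_k f_k exp(−b gᵀ D_k g) + f_free exp(−b d_iso) ],

where each fiber compartment k has an axially framed tensor D_k aligned
with the local bundle tangent (default eigenvalues (1.7, 0.3, 0.3)×10⁻³
mm²/s, typical of coherent white matter), and the free compartment carries
the tumor's isotropic diffusivity (2.0×10⁻³ mm²/s, elevated as in necrotic
or cellular-but-disordered tissue) inside the tumor ellipsoid and a
background diffusivity (0.8×10⁻³ mm²/s) outside. Bundles are tubes around
polyline centerlines; a voxel belongs to a tube when its center lies within
the tube radius, and nominal volume fractions are rescaled to sum to ≤ 1 in
crossing voxels. Partial volume is therefore binary at the voxel level —
a deliberate simplification; surface voxels of real bundles have graded
fractions.

Noise. Rician, via two independent Gaussian channels on the complex
signal; SNR is defined as S0/σ. This is the standard magnitude-MR noise
model. The Monte-Carlo mean of the noisy magnitude matches the analytic
Rician mean within 1% in the tests.

Acquisition presets. `human64` (64 directions, b = 1000 s/mm², 1.8 × 1.8
× 4.0 mm voxels), `human27` (27 directions, b = 1200 s/mm², 0.86 × 0.86 ×
3.5 mm) and `mouse512` (512 directions, b = 1200 s/mm², 0.16 mm isotropic)
reproduce the direction counts, b-values and voxel geometries of the
clinical and ex-vivo protocols this pipeline targets. Vendor gradient
tables are not public; directions are placed by electrostatic repulsion
with antipodal symmetry (1000 fixed iterations), which maximizes the
minimum pairwise acute angle to well beyond any random placement.

Crossing-phantom geometry. The end-to-end recovery phantom places k ∈
{1..5} straight tubes (radius 3 mm) through a 9 mm spherical "tumor" at up
to three z-levels. Tubes sharing a level cross at 90°; tubes on different
levels are separated by more than a tube diameter and never touch. This is
a deliberate design constraint: at b = 1000 s/mm² with 64 directions the
spin-distribution function physically cannot separate fiber pairs below
≈ 80° (we measured a single merged bisector peak for separations ≤ 70°),
so a phantom with 36–60° crossings would test the scanner physics, not the
pipeline. Orthogonal crossings are the standard resolvable benchmark and
still exercise multi-peak continuity through the crossing region.

Survival cohorts. Exponential survival with log-hazard linear in the
z-standardized named tract metric: T_i ~ Exp(λ0 · exp(β z_i)), λ0 =
1/714 days⁻¹ (the historical cohort's mean overall survival scale), cohort
size default 66. β is a log hazard ratio per metric standard deviation;
the recovery studies use β = 0.8 ("longer projecting tracts, shorter
survival" at an effect size that a 66-patient quartile analysis can
detect). Metrics are log-normal with means/SDs matching the reported
cohort distributions (mean tract length 29.1 ± 11.7 mm, mean projecting
tract length 64.2 ± 19.6 mm, 5.0 ± 2.1 bundles, tumor volume 43.1 ± 37.9
cm³). Censoring is independent: with probability `censor_rate` a subject
is censored at a uniform fraction of its event time. The exponential (not
Weibull) choice keeps one nuisance parameter; the downstream estimators are
nonparametric and do not assume it.

RNA-seq counts. Negative-binomial counts (dispersion 0.1) with log-normal
library sizes around 5 million reads and log-normal baseline abundances; a
chosen fraction of genes is up-regulated by a fixed fold change (default 2)
in the "tract" group. Default group sizes (tract 6 / tumor 5 / normal 2 =
13 samples) mirror the biopsy design the stage emulates. The generator
records per-gene truth.

## Reconstruction (`recon`)

Tensor fit. Unweighted log-linear least squares of ln S = ln S0 − b gᵀDg
per voxel; measurements with non-positive signal are dropped, and voxels
with fewer than 7 usable measurements are flagged invalid rather than
zeroed. Iteratively reweighted fitting would lower noise-floor bias at low
SNR but is unnecessary at the SNRs studied (MD bias < 2% at SNR 30);
documented limitation. FA/MD/AD use the standard eigenvalue formulas; FA
is 0 by definition when all eigenvalues vanish and lies in [0, 1] by the
formula alone.

Spin-distribution function. ψ(û) = Σ_i S_i sinc(L √(6 D₀ b_i) ⟨g_i, û⟩),
with sinc(x) = sin(x)/x, sampling ratio L = 1.25 and free-water
diffusivity D₀ = 2.5×10⁻³ mm²/s, evaluated on a subdivided icosahedron
(642 vertices, antipodally symmetric; subdivision order configurable) and
min-subtracted per voxel. Both L and the sphere order are configuration
knobs; L trades angular sharpness against noise sensitivity.

Peaks and QA. Local maxima over the sphere's vertex graph are merged
across antipodes, accepted greedily in descending ψ under a pairwise
separation of ≥ 25°, and refined by a local quadratic fit in tangent
coordinates (bringing single-fiber angular error from the ~4° vertex
spacing down to < 0.3°). Quantitative anisotropy (QA) of a peak is its
min-subtracted ψ normalized by the volume-wide maximum peak value — the
"protrusion above the isotropic background" reading; QA is invariant to
global signal scaling. Defaults: ≤ 3 peaks per voxel, QA floor 0.05.
Whether min-subtraction should be per-voxel and normalization per-volume is
a genuinely open convention; this combination is used consistently.

## Tracking (`tracking`)

Deterministic bidirectional Euler integration at a fixed 0.3 mm step.
The direction at a sub-voxel position interpolates the eight surrounding
voxels tri-linearly with three refinements that together define this
tracker:

1. per corner voxel, the peak most aligned (|dot|) with the incoming
   direction is selected and sign-flipped to agree with it;
2. a corner peak misaligned beyond the angular threshold contributes
   nothing (orientational coherence — only maxima of similar orientation
   in neighboring voxels are linked);
3. each selected peak enters the tri-linear average scaled by its QA, so
   the interpolated quantity is the amplitude-weighted peak vector field
   and a spurious low-QA noise peak cannot steer a track.

Without (2) and (3), tracks near bundle surfaces are systematically
deflected by noise-floor peaks in adjacent voxels: on the k = 3 crossing
phantom 27% of tracks fragmented and bundle counting failed badly.

Termination: turning angle > 45° (the threshold is read as "terminate when
the turn exceeds 45°"), interpolated top-peak QA < 0.08 (QA termination is
a tissue property, interpolated from each corner's strongest peak
independently of the direction gate, so one poorly resolved crossing voxel
does not kill a track), leaving the volume, or the step cap
⌈L_max/step⌉ + 1. Finished tracks outside the 0–300 mm length window are
discarded. The first step at a seed uses the strongest-QA interpolated
peak and propagates both senses. Tracking contains no randomness; only
seed-point jitter is seeded.

## Tumor tracts (`tumor_tracts`)

A streamline is tumor-intersecting when any point falls in the ROI after
the world-to-voxel transform (nearest-voxel test). Classification uses a
geometric rule that operationalizes the core/shell/projecting distinction:
*core* if every point is inside; otherwise, with e the maximum
surface distance of exterior points (exact Euclidean distance transform,
world-scaled per axis, tri-linearly interpolated), *shell* if e ≤ 3 mm
(≈ one in-plane voxel diagonal) and *projecting* otherwise. The original
workflow selected projecting tracts manually; the margin rule is an
explicit, monotone stand-in (growing the margin can only move tracts from
projecting to shell).

Metrics: mean tract length over all tumor-intersecting tracts; mean
projecting tract length over projecting tracts only, using full streamline
lengths (the tooling this mirrors reports whole-tract lengths); the
projecting mean is flagged undefined (not 0) when no tract projects.
Tumor volume is voxel count × voxel volume (cm³); intra-tumoral QA/FA/MD/AD
are means over ROI voxels.

Bundle counting: tracts are resampled to 12 equidistant points and
clustered greedily against running centroids under the
minimum-average-direct-flip (MDF) distance, threshold 8 mm; clusters with
fewer than 2 members are discarded. This is the QuickBundles construction;
it is deterministic given input order, which the seed ordering fixes.

## Survival statistics (`survstats`)

OLS of overall survival (days) on each continuous metric with t-based 95%
CI and two-sided p (statsmodels); Welch unequal-variance t-tests for binary
strata (the robust default where the pooled-variance flavor is not
specified); quartile stratification at the type-7 (linear interpolation)
sample quantiles with ties going to the lower group — at n = 66 this
always yields groups of 16–17; Kaplan–Meier product-limit estimation and
the k-sample log-rank test (lifelines), the latter verified against an
independently coded hypergeometric-increment oracle to 10⁻¹⁰. No
multiple-testing correction is applied across the univariate outcome tests,
matching the reporting convention this stage reproduces; treat the p-values
accordingly.

## Expression stage (`transcriptome`)

CPM filtering retains genes with ≥ 5 CPM in ≥ 2 samples (the standard
reading of the filter rule; the literal alternative — discard genes below
5 CPM in ≥ 2 samples — is available via `literal=True`). Library sizes
default to the column sums of the supplied matrix; raw (pre-filter) totals
can be passed explicitly.

The DE route follows the voom construction: log2-CPM with the 0.5-count /
+1-library offset; ordinary least squares per gene for the tract-vs-rest
contrast ("rest" pools tumor and normal, matching the tract-associated
versus bulk-and-normal comparison); a lowess trend (frac 0.5) of √(residual
SD) against mean log2-count; per-observation weights trend(fitted)⁻⁴;
weighted least squares per gene; and empirical-Bayes variance shrinkage by
the method-of-moments fit of a scaled inverse-chi-square prior on the gene
variances (matching the mean and variance of log s² via digamma/trigamma,
with a Newton trigamma inverse). Moderated t uses df = residual + prior.
The implementation agrees with the reference R/Bioconductor route (limma
`voom` + `lmFit` + `eBayes`) to |Δlog2FC| < 0.01 and t-correlation
> 0.999 on shared input, and that agreement is asserted in the test suite
via Rscript.

BH adjustment is the step-up procedure (statsmodels, verified against a
brute-force oracle). DE calls require |fold change| ≥ 2 and q < 0.05.
Enrichment is a one-sided exact hypergeometric over-representation test of
a user-supplied gene set (e.g. cell-motility genes) in the DE set — a
desk-scale replacement for GO-wide GSEA that answers the same
over-representation question without an annotation database.

Known behavior: with plain CPM normalization (no trimmed-mean-of-M
correction), a one-sided DE signal (e.g. 10% of genes up in one group)
shifts that group's library sizes, so truly unchanged genes acquire a
small negative CPM fold change and the realized FDR against simulation
truth exceeds the nominal level (~0.09 at q < 0.05 with fc threshold 1).
This composition bias is shared by the reference route and is why the
null-simulation calibration (realized FDR 0.0, p-values uniform) is the
meaningful check of the testing machinery itself.

## Problem sizes in the default studies

The shipped studies use a 40×40×12-voxel phantom grid (human voxel
geometry), 1–2 jittered seeds per bundle voxel, 200-seed cohort
replications, 1000–2000-replicate null calibrations and 2000–5000-gene
count matrices. These sizes give stable Monte-Carlo estimates (binomial
SE ≤ ~3% on rates) while keeping each study in seconds to a couple of
minutes on one CPU.

## What the phantoms do not show

Parametric tubes and ellipsoids lack gyral geometry, fanning and
bottleneck configurations; no susceptibility/eddy distortion, motion or
"bad slice" artifacts are simulated (the upstream workflow handles those
before this pipeline begins); binary tumor masks are inputs, so
segmentation variability is out of scope; and the exponential cohort and
NB count generators encode exactly the effect structures the estimators
target. Passing tests therefore demonstrate correctness of the
implementation under its stated models, not clinical performance.
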