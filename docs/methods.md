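# Methods

This note documents the models, conventions and numerical choices behind
`ventiqct`, and what the synthetic phantom does and does not establish.

## Coordinate and field conventions

Volumes are axis-aligned scalar grids with voxel spacing and origin in mm
(`world = origin + index · spacing`, identity direction). Displacement
fields live on the **fixed** grid and map fixed-domain physical points
into the moving domain (pull-back): resampling is `out(x) = img(x + u(x))`
with linear or nearest interpolation. The expiration→inspiration
registration therefore produces a field on the inspiration (TLC) grid
whose Jacobian J = det(I + ∇u) is **below 1** where the lung deflates;
per-voxel air-volume change is

    dVair = v · [(1 − β_insp) − J · (1 − β_exp∘T)]

which under voxel-wise tissue-mass conservation (β_exp∘T = β_insp / J)
reduces to `v · (1 − J)`. Tissue fraction uses the standard air/tissue HU
mixture, β = clamp((HU + 1000)/1000, 0, 1). Affine transforms also map
fixed points into the moving domain, matching the resampling direction.

## PRM classification

Thresholds default to −950 HU (inspiration) and −856 HU (expiration),
the established gas-trapping/emphysema boundaries; both are parameters.
A voxel is emphysematous below both thresholds, gas-trapped (fSAD) at or
above −950 at inspiration but below −856 at expiration, normal otherwise.
Percentages are reported per lobe and for the total lung; region counts
always sum to the total and the three class percentages to 100.

## Registration

**SPECT→CT affine (mutual information).** SimpleITK Mattes MI with 32
histogram bins, evaluated over the lung mask dilated by 2 voxels, full
sampling (no stochastic sampling, so results are bit-reproducible), two
multi-resolution stages of regular-step gradient descent (shrink factors
4 and 2): a translation-only stage absorbs the bulk misalignment, then a
full affine refines. With a coarse, blurred tracer image the affine's
higher-order components are only weakly determined — on phantoms the mean
in-lung mapping error is 2–5 mm (about one SPECT voxel) while the
translation it implies at the lung centroid recovers a known rigid offset
to well under one SPECT voxel. Offset-recovery diagnostics therefore
measure the affine-induced displacement of the lung centroid.

**Expiration→inspiration deformable (SSTVD).** The similarity metric is
the mean squared tissue-volume difference: residual
`r = β_insp(x) − J(x) · β_exp(x + u(x))`, so the registration matches
tissue *mass*, not raw intensity — the lung densifies as it deflates and
intensity-matching alone would be biased. The displacement is a
multi-resolution free-form deformation: displacement coefficients on a
coarse control grid (default 16 mm then 8 mm node spacing, image pyramid
at 1/4 and 1/2 resolution), prolonged to the dense grid by trilinear
interpolation. L-BFGS-B minimises the metric plus a first-difference
smoothness penalty on the control grid (weight 0.03, normalised per
difference so it is resolution-independent); the analytic gradient uses
the frozen-Jacobian approximation (the ∂J/∂u term is dropped), which is
exact at convergence of the data term and standard for this metric. On
phantoms with 6 mm peak deformation the mean endpoint error is ~0.7 mm
and the Jacobian-weighted warped tissue volume matches inspiration within
1%, evaluated on a 2-voxel-eroded lung core to exclude the pleural
partial-volume shell.

**Deformation metrics.** Gradients by central differences (one-sided at
boundaries) in physical units. ADI is computed from the principal
stretches λ₁ ≥ λ₂ ≥ λ₃ (singular values of F = I + ∇u):
`ADI = sqrt(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²)`, zero exactly for locally
isotropic deformation.

## SPECT statistics

TC%, CV_Total (SD/mean) and TC_Max are computed on the SPECT volume
transported to the TLC CT domain, over mask-positive lung voxels
(partial-volume edge voxels included). TC_Max is standardised as
max/mean — dimensionless and invariant to the amount of tracer inhaled;
max/median or a high-percentile variant would serve equally and the
convention is a parameterisable choice. CV_Total uses the sample SD
(ddof 1), immaterial at image scale. Cohort-table summaries
(`summarize_table`) default to the population SD (ddof 0), which is the
convention of the packaged per-subject tables.

## Phantom generator

The phantom is a scaled-down thorax: two ellipsoidal lungs (split into
five lobes by axial planes) inside a soft-tissue body, on a 96×96×88 grid
at 1.5 mm spacing — a deliberately coarser grid than clinical CT so the
whole pipeline runs in seconds; the lung measures ~5–10 cm per axis. The
breathing deformation is an analytic, diaphragm-dominant anisotropic
contraction with a harmonic modulation (regionally varying J ≈ 0.75–0.82
at the default 6 mm peak displacement). Disease classes are seeded as
smooth blobs (thresholded Gaussian random field, smoothing σ = 8 voxels)
at **exact** voxel-count fractions, kept off the pleural surface so
partial-volume mixing with the chest wall cannot corrupt recovery.

HU values are drawn per class so the PRM thresholds reproduce the seeded
classes after warping, with class levels placed **symmetrically around
each decision boundary**: resampling at a class interface then flips
voxels in both directions in near-equal numbers and seeded fractions are
preserved to well within the ±2-point contract. The expiration volume is
the inspiration volume pushed through the true map (fixed-point inversion
of x + u(x)) with β scaled by 1/J — tissue mass is conserved voxel-wise,
and recorded inspiration/expiration lung tissue volumes agree within 0.1%
under partial-volume-weighted quadrature. Lung and body are warped
separately (nearest-neighbour fill extends the lung field past its
boundary before interpolation) so lung-edge voxels never blend with
chest-wall values.

The tracer field is proportional to per-voxel fractional air-volume
change (1 − J) — the simplest defensible ventilation surrogate —
multiplied by a deposition enhancement in gas-trapped tissue (default
×2, the causal path from fSAD burden to heterogeneity) and by Gaussian
hot-spot kernels (σ = 2 SPECT voxels) seeded inside fSAD blobs,
emulating focal deposition at narrowed airways. The field is pushed to
the expiration configuration (SPECT is acquired near FRC), blurred to
SPECT resolution with a mask-normalised Gaussian (σ = half a SPECT
voxel; normalisation prevents edge falloff from masquerading as
heterogeneity), resampled onto a 3.895 mm grid displaced by a recorded
random rigid offset of 4–8 mm, scaled to a mean of 150 counts, and
optionally Poisson-degraded. All randomness derives from the PhantomSpec seed;
identical specs give bit-identical volumes.

**What the phantom does not emulate:** airway trees and vascular texture
(the SSTVD metric therefore leans on lobe-scale structure and the
lung boundary), scanner physics (scatter, beam hardening, attenuation),
respiratory motion during acquisition, and anatomically realistic lobe
geometry. Passing recovery tests shows the pipeline's numerics are
sound under the stated statistical structure, not that it meets clinical
accuracy on real scans.

The two-wave panel generator plants a structural model on standardised
variables with stabilities 0.5, synchronous correlation 0.4 and a
one-directional cross-lag x1→y2; residual variances are solved for unit
variance and parameter sets implying a non-positive-definite covariance
are rejected. With a 0.5 effect at n = 200 the correct direction is
recovered in ~95% of replicates; with no effect each spurious direction
is called at the nominal 5%.

## Statistical layer

Correlations are Pearson's r with two-sided t-test p-values, pairwise
deletion of missing values, and the conventional strength bands
(≤0.3 negligible, 0.3–0.5 weak, 0.5–0.7 moderate, 0.7–0.9 strong, >0.9
very strong); with eight subjects the reporting is effect-size-first and
|r| > 0.7 cells are highlighted. Cross-sectional maps pool all
subject-visit rows (n = 22 after dropping the two missing baseline SPECT
visits); longitudinal maps correlate per-subject between-visit changes,
using the tables' printed delta columns when reproducing the cohort (the
table deltas were computed from unrounded source data).

Cross-lagged panel analysis reports six correlations: two synchronous,
two stability, and two cross-lagged **partial** correlations with the
outcome's own prior wave partialled out (r(x1, y2 | y1) and
r(y1, x2 | x1)) — conditioning on the single stability-relevant variable,
not both prior waves. Significance is one-sided (greater than zero),
t-distributed with n−2 df for simple and n−3 for partial correlations.
Assumption flags record synchronicity (both synchronous correlations
significant) and stationarity (both stabilities significant).

EFA extracts principal-component loadings (eigenvectors scaled by the
root eigenvalues of the correlation matrix) and rotates them with Kaiser
Varimax (SVD-based, tolerance 1e-8); factors are sign-oriented and
ordered by rotated variance, and key variables are those with |loading|
above 0.6. Parallel analysis retains the leading run of observed
eigenvalues exceeding the 95th percentile of eigenvalues from random
standard-normal data of identical shape (default 200 replicates). Both
are implemented in-package on numpy eigendecompositions.

## Cohort reproduction

The packaged CSVs transcribe the printed per-subject tables cell for
cell (sha256-pinned). Per-visit PFT values are reconstructed as baseline
plus printed deltas (V1 = V0 + Δ(V1−V0), V2 = V0 + Δ(V2−V0)); a V2−V1
change, where needed, is derivable as the difference of printed deltas
and is flagged as reconstructed. Subjects 1–2 lack baseline SPECT (the
acquisition protocol changed after the first two baseline scans) and are
excluded pairwise. Reference checks use ±0.01 for mean/SD rows (printed
precision) and ±0.05 for table-derived correlations (printed values are
rounded to two decimals from unrounded sources).

## Limitations

Real cohorts of this size make the pooled correlations sensitive to
single subjects; the package reports n alongside every r deliberately.
The affine MI alignment is validated for rigid misalignments only. The
SSTVD implementation is a compact free-form-deformation solver, adequate
for smooth phantom deformations; sliding motion at the pleura and fine
vascular matching on clinical CT are out of scope. The max/mean TC_Max
convention and the (1 − J) tracer proportionality are package choices
where the field has no single standard; both are parameterised.
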