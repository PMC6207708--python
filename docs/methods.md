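# Methods

`striaq` implements an automated quantification workflow for striatal
VMAT2 PET (¹⁸F-DTBZ-like tracers): two routes for bringing a subject's
late-phase transporter image into a common standard space, specific uptake
ratio (SUR) extraction over a striatal ROI atlas, and the group-level
statistics used to compare patients with Parkinson's disease (PD) against
controls and the two routes against each other. Because no image data are
distributed with the package, every analysis runs on synthetic phantom
cohorts whose ground truth is known exactly; this note records the models,
the defaults, and what the synthetic setting does and does not demonstrate.

## Specific uptake ratio

For a target region T and reference region R,

    SUR = (mean uptake in T − mean uptake in R) / mean uptake in R.

The reference is the pons for early-phase (perfusion-like, 0–10 min)
images and the whole occipital region for late-phase (90–100 min,
transporter-specific) images. SUR is dimensionless, invariant under global
intensity scaling, and equals 0 in the reference by construction. Ten
target ROIs are quantified: bilateral caudate, anterior putamen, posterior
putamen, nucleus accumbens and substantia nigra. Laterality follows the
clinical convention: the hemisphere opposite the side of symptom onset is
*contralateral*; controls, having no symptomatic side, are assigned a fixed
pseudo-side (right, so their left hemisphere is tabulated as contralateral;
configurable via `CohortSpec.control_pseudo_side`). Relabelling ROIs rather
than flipping voxel data is the default implementation — numerically
identical for the mirror-symmetric atlas and free of an interpolation step;
`flip_lateral` provides the image-flipping route and the equivalence is
tested.

## The two normalization pathways

**Traditional (MRI-based).** Three registrations are chained: rigid (6 DOF)
late→early coregistration, affine (12 DOF) early→structural coregistration,
and a nonlinear structural→standard normalization against a standard-space
structural reference. The three transforms are composed and applied to the
native late image with a *single* trilinear interpolation (a
`serial_resample` flag reproduces the literal stage-by-stage resampling for
comparison). Early-phase SURs come from the same run via the composed
affine+nonlinear map.

**Template-based (alternative).** The native late image is registered
directly — affine plus, by default, the nonlinear stage — to a
transporter-specific late-phase template, with no structural or early image
involved. The template is the voxelwise mean of the traditionally
normalized control scans, each divided by its mean over the basal-ganglia
mask (union of caudate + anterior/posterior putamen labels; the globus
pallidus is excluded because it is not part of the quantified target set)
so each control contributes equally, then smoothed. Template smoothing
defaults to 4 mm FWHM: on the 3 mm study grid this keeps the template's
basal-ganglia mean within ~0.3% of 1 and its striatal SURs within
Monte-Carlo error of the group means, while 6 mm would dilute both
noticeably. Whether the published alternative route included a nonlinear
stage is not stated; the default here includes it (plain affine is a
configuration switch) because "spatial normalization" to a template
conventionally implies one — and because the nonlinear stage is precisely
what produces the route's characteristic bias (below). The template route's
warp is deliberately more constrained than the structural-normalization
warp (20 iterations, 1 mm step cap, 4 mm total displacement cap, stronger
field smoothing): the workflow it emulates used a tightly regularized
normalization, and an unconstrained warp does not merely bias a low-uptake
putamen toward the template — it remodels it wholesale, inflating PD SURs
by more than one unit and destroying the inter-pathway agreement the
clinical comparison reports. The constrained defaults keep the
over-estimation effect, at a realistic magnitude.

## Registration

All stages minimize the mean squared intensity difference (SSD) over
in-field voxels after both images are normalized to unit mean over the
valid mask, making the cost invariant to global intensity scaling. One cost
serves all stages, including the PET-to-structural step; to soften the
contrast mismatch there, the structural image is histogram rank-matched to
the early-phase image before the affine fit.

Rigid and affine fits run coarse-to-fine: at each pyramid level both images
are Gaussian-smoothed (default levels: stride 4 with 10 mm FWHM, then
stride 2 with 4 mm) and the parameters are refined by a bounded
trust-region least-squares solver on the masked intensity residuals.
Finite-difference steps are absolute (0.25 mm / 0.25° / 0.01 for scale and
shear) — sized so a step moves the image by a resolvable fraction of a
voxel regardless of the current parameter value. Translation is initialized
from the intensity-centroid offset; the affine fit starts from a rigid
pre-fit. The result never reports a cost above its starting cost (the
initial estimate is kept if the solver cannot improve on it at full
resolution) and non-convergence is flagged on the result, not raised.

The nonlinear stage is a demons-style iteration: intensity-difference
forces along the warped image gradient, Gaussian smoothing of each update
(fluid regularization, σ = 2 mm) and of the accumulated field (elastic,
σ = 1.5 mm), a 2 mm per-iteration step cap, and a hard 10 mm displacement
cap (clamping is flagged). The field lives on a stride-2 grid (6 mm
spacing) of the fixed image, 40 iterations by default with an early stop on
relative cost change < 1e-4. This is deliberately a simple, readable
stand-in for high-dimensional normalization packages: it satisfies the same
contract (land the image in standard space, final cost no worse than the
affine-only cost) without claiming diffeomorphic or inverse-consistent
behaviour.

On the default phantoms, known-transform recovery achieves median errors of
~0.15 mm translation and ~0.25° rotation over the configured misalignment
range (tolerances 1.5 mm / 0.5°), scale to ±0.01, and smooth 4 mm warps to
~1 mm mean point error in the striatum.

## Synthetic data

The atlas is parametric: each ROI is an ellipsoid at fixed mirrored
coordinates on a 64×64×54 grid at 3 mm isotropic spacing centred on the
world origin (a desk-scale stand-in for scanner-resolution grids; the grid
is a parameter). Phantoms are piecewise constant: uptake = reference ×
(1 + SUR) inside each ROI, a diffuse background inside a brain ellipsoid
(early-phase background SUR 0.25 against the pons; late-phase background at
the occipital reference level), zero outside. Uptake is painted over
ellipsoids dilated by 4 mm relative to the measurement labels (ties between
adjacent dilated regions go to the nearest normalized distance, and
measurement-label voxels always carry their own ROI's exact value). The
margin puts every measurement voxel in the interior of a constant region,
so ROI means are exact on noiseless untransformed phantoms — the
construction identity `quantify(make_subject_images(truth)) == truth` holds
to float precision — and interpolation partial-volume after registration
biases ROI means only once residual misalignment approaches the margin.

Per-subject misalignment is an affine draw: translation uniform within
±6 mm per axis, rotation within ±6°, anisotropic scale 0.95–1.05, no shear;
the early, late and structural frames additionally differ by small rigid
offsets (±3 mm / ±3°). An optional smooth random truth deformation
(amplitude-capped, default off) stresses the nonlinear stage. Noise is
additive Gaussian with sd = 5% of the reference uptake by default —
chosen as a plain, sufficient stressor; Poisson/reconstruction noise and
scanner PSF modelling are out of scope. All randomness descends from one
seed through spawned generators, and images are realized lazily per subject
with deterministic per-subject seeds.

Cohort SURs are Gaussian draws per (region, laterality, phase) from the
published group means ± SD (26 controls, 39 PD); Gaussianity is an
assumption of the simulator — the study reports only means and SDs, no
per-subject scatter. UPDRS-III motor scores for PD subjects follow
`round(exp(4.85 − 1.07·SUR + ε))`, ε ~ N(0, 0.75), clipped to ≥ 1, linked
to the contralateral anterior putamen late SUR. The log-normal form keeps
scores positive (log-transformed scores are what the regression uses; zero
scores would break the log), and the constants are calibrated so the
simulated R² between log-UPDRS-III and the linked SUR is ≈ 0.3 with a
marginal score distribution near the published 16.2 ± 14.1. UPDRS-I/II and
Hoehn–Yahr stage are generated as plausible companions (they are carried in
the subject table but drive nothing).

## Statistics

ROC analysis uses the empirical Mann–Whitney AUC (pairwise win fraction,
ties half; computed from midranks, identical to exhaustive enumeration)
with controls as the positive high-SUR class, so AUC ≥ 0.5 for
degenerating regions. Group comparisons use Welch's t-test (pooled-variance
available by flag); the demographic gender table uses Pearson's chi-square
*without* continuity correction — with Yates' correction the published
p = 0.92 for a 13:13 vs 20:19 split is not reproduced. Method agreement is
Spearman's rank correlation per region. Motor associations are ordinary
least squares of log-UPDRS-III on SUR (natural log of max(score, 1); the
base only rescales the slope) plus a bounded sigmoid fit
SUR = L / (1 + exp(k·(log UPDRS-III − x0))) from a deterministic grid of
starts. The significance threshold is fixed at p < 0.01 and no
multiple-testing correction is applied, matching the study design.
Paired-difference tables (template − traditional against the traditional
baseline) support the bias-versus-level analysis.

## What the synthetic setting shows — and does not

With the default conditions, the full simulated study reproduces the
qualitative structure of the clinical findings: complete late-phase
putaminal separation of PD from controls (AUC 1.0), weaker early-phase
discrimination (mean AUC ≈ 0.75 for the ipsilateral posterior putamen
distributions), high inter-pathway agreement (Spearman ρ > 0.9 in caudate
and putamen), and — emerging from the mechanics rather than being painted
in — systematic over-estimation of low-uptake putamina by the
template-based route, because the nonlinear stage pulls a dim putamen
toward the bright normal-control template. The paired difference is
negatively correlated with the baseline SUR, as in the clinical scatter.

These phantoms are favourable for registration: piecewise-constant
anatomy, identical across subjects up to an affine map, no partial-volume
at acquisition, no kinetic or attenuation effects. Passing tests therefore
validate the pipeline's bookkeeping, the registration's transform recovery,
and the statistics — not clinical-grade accuracy on real scans. Two honest
limitations surface in the tests themselves: the cross-contrast rigid
stage (late→early) has its SSD minimum a fraction of a voxel off identity
even for perfectly aligned inputs, bounding pipeline SUR recovery near
~1% rather than float precision; and in flat image regions the nonlinear
field is only determined up to the aperture problem, so field accuracy is
asserted through composition-with-truth residuals and label overlap rather
than pointwise equality.

## Problem sizes

Default sizes are chosen for desk-scale runs: the 64×64×54 @ 3 mm grid, a
65-subject image cohort (≈ 4–5 s per subject through both pathways), 500-
and 200-cohort scalar simulations for the AUC summaries, and n = 10,000
draws for generator-moment checks.
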