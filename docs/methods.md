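# Methods

## Kinetic models

**Multi-TI PASL.** The difference signal is modeled with the general
kinetic model under the intravascular-relaxation simplification: the label
decays with the T1 of blood throughout, and the delivery (tissue-exchange)
factor is unity. The resulting curve is the piecewise ramp/plateau form
documented in `signal_models.pasl_kinetic_signal`. This is the default
because, at inflow times of 0.35–2.6 s, the shape information that
identifies the arrival time lives in the rising edge and early plateau,
where blood relaxation dominates; the full single-compartment model adds a
tissue T1 and an exchange factor that are not identifiable from ten
difference samples and would mostly trade off against CBF. The full model
(apparent tissue rate `1/T1' = 1/T1_tissue + f/λ`) is available via
`model="single_compartment"` and reduces continuously to the simplified
form as the blood and apparent tissue rates coincide. Q2TIPS is modeled
only through the fixed bolus duration τ = 0.7 s; no saturation-pulse
simulation, background-suppression or readout modeling is attempted.

**Single-delay pCASL.** The forward curve is the continuous-labeling
solution with arrival time Δt and blood-T1 decay only. Evaluated at the
readout (τ + PLD), the arrival time cancels exactly for Δt ≤ PLD — which
is why the standard quantification formula needs no arrival estimate — and
attenuates the signal for Δt > PLD. The quantification operation is the
standard closed form; applied to late-arrival voxels it therefore
underestimates flow, the mechanism the sequence-discrepancy check
demonstrates quantitatively (the late pocket of the control-like phantom,
arrival 1.86 s vs a 1.5 s delay, quantifies at ~71% of truth).

**Blood T1.** Whole-blood R1 is the hematocrit-weighted mean of plasma and
erythrocyte rates, with the erythrocyte rate rising linearly with
desaturation: `R1 = (1−Hct)·r1_plasma + Hct·(r1_ery_oxy +
r1_deoxy·(1−SaO2))`. Default coefficients (0.3965, 0.7815, 1.30 s⁻¹) give
the 3 T behaviour expected of this model class — T1 monotonically falling
with hematocrit, weakly with desaturation — and land near 1.99 s at
anemic hematology (Hct 0.25, SaO2 0.97) and 1.77 s at normal hematology
(Hct 0.41, SaO2 0.98). Tests treat these only as plausibility bands
(±0.15 s); alternative calibrations can be supplied as a coefficient
mapping.

## Voxel-wise fitting

The model is linear in CBF, so for any candidate BAT the least-squares CBF
is the projection of the (M0-normalized) voxel series onto the unit-CBF
basis curve, clipped to [0, 400] ml/100g/min. The fit therefore reduces to
a 1-D profiled search over BAT on [0.1, 3.0] s: an exhaustive coarse grid
(step 0.05 s — the objective is multimodal in BAT at low SNR, so global
seeding matters), a dense local grid spanning ± one coarse step (41
points), and one parabolic interpolation step through the local minimum.
Ties take the smallest BAT; everything is deterministic. Noiseless
recovery is ~1e-4 relative; the bounds cover late watershed arrivals with
headroom. Voxels whose optimum sits at CBF = 0 are flagged low-signal and
get an undefined BAT (arrival is meaningless without signal); voxels with
non-positive M0 or outside the reliability mask are NaN and propagate as
missing values into ROI means, never as zeros.

Reliability screening pools the mean and sample SD (ddof = 1) of four
5-voxel corner squares, replicated on every slice and pooled over
timepoints — ghosting is an in-plane EPI phenomenon, and pooling maximizes
the noise sample. "At least greater than mean + 1 SD" is read as a strict
inequality on the per-voxel max over the series.

## Watershed segmentation and lesions

The iWSA threshold is the 70th percentile (linear interpolation between
order statistics) of BAT over eroded-white-matter voxels that are reliable
and fitted; equal-to-threshold voxels go to the watershed side (the rule
names a lower threshold, read inclusively; with constant BAT the whole ROI
is watershed). Erosion uses a cubic box structuring element of width 2
voxels. Percentile-after-reliability is a deliberate choice: unreliable
voxels carry no BAT and appear downstream as their own "unclassified"
category.

The FLAIR rule is scale-invariant: threshold = 1.02 × mean cortical
intensity, strict `>` at the boundary (an inclusive variant sits behind a
flag). Burden is reported in voxel counts on the FLAIR grid, split by
arrival class, with voxels eroded away or unreliable counted as
unclassified.

## Cohort statistics

Test selection is a per-variable, per-group Shapiro-Wilk gate at α = 0.05;
disagreement between groups falls through to Mann-Whitney (the
conservative reading). The MWU effect size is r = |Z|/√N with the
tie-corrected normal approximation. FDR is Benjamini-Hochberg per declared
family (group × parameter-map type). "Age- and sex-adjusted" is
residualization on age and sex with the grand mean re-added. Mediation is
product-of-coefficients with case-resampling bootstrap (default 1000
replicates) and a percentile 95% CI; the indirect-effect p value is the
two-sided bootstrap sign test, and for nested linear models the
direct + indirect = total identity holds exactly. Missing hemoglobin /
saturation values are substituted with group means before CaO2 is derived.

## Synthetic data

The phantom is a piecewise-constant digital object on the 64×64×24
acquisition grid: gray-matter shell (CBF 54 ml/100g/min, BAT 0.72 s in the
patient configuration; 43 / 0.82 in controls), early-arrival white-matter
core (34 / 0.74; 26 / 0.85), and a late-arrival pocket (24 / 1.51;
17 / 1.86) sized to 30% of the eroded white matter so the percentile rule
has a well-defined target. M0 is 100 inside the brain; additive Gaussian
noise with SD 0.05 on each difference volume gives a peak gray-matter
difference-signal SNR of ~15 — the difference noise of a
background-suppressed 3D-GRASE acquisition is approximately Gaussian, and
that SNR is typical of such protocols; a Rician option is deliberately
deferred since difference images are signed. Corners carry noise but no
signal, exercising background estimation.

The cohort generator draws group-specific normals (log-normals for lesion
burden) matching the study-scale summary table, truncates Wechsler scores
to [40, 160], and plants the mediation triple
`FA = base + a·(CBF − μ) + ε`, `PSI = base + direct·(CBF − μ) +
b·(FA − base) + ε` with defaults a = −0.000375, b = 160, direct = −0.16 —
an indirect effect of −0.06 with ~27% of the total mediated, at
study-scale noise (FA SD 0.02, PSI residual SD 12.1 chosen so the marginal
PSI SD is ~13).

What the generator does *not* emulate: vascular-territory geometry,
partial-volume mixing at compartment borders, motion, dispersion of the
bolus, spatially correlated noise, and registration error (alignment is
out of scope throughout — all volumes of a subject live on one grid and
the orchestrator refuses silent resampling). Passing tests therefore
validate the estimators and the pipeline logic under the stated noise
model, not robustness to acquisition artifacts.

## Problem sizes and determinism

The recovery checks use 60 noiseless voxels with uniformly drawn
parameters and a 7 × 10 (CBF × BAT) grid with 10 noise replicates each;
segmentation checks use the full default phantom (~10,600 classified WM
voxels). Mediation calibration uses 200 replicate cohorts in the test
suite (fixed seeds, deterministic) and 400 in the acceptance script, each
with 1000 bootstrap replicates: the percentile CI of a weakly identified
coefficient product covers at ~93%, so enough replicates are needed that
the binomial noise of the coverage estimate itself does not dominate. All
randomness flows from explicit seeds; a pipeline rerun with the same
configuration is byte-identical (volumes are written as uncompressed
NIfTI so no container metadata can differ).

## Known limitations

Single-compartment kinetics without dispersion; no partial-volume
correction beyond mask erosion; the blood-T1 calibration is a generic
two-pool model, not a protocol-specific measurement; lesion apportionment
for voxels outside both arrival classes is a single "unclassified" bucket;
Kendall's W is not implemented (no result attaches to it); the printed
lesion-presence p value of the motivating cohort is not reproducible from
its 2×2 table (φ is, and is what the package asserts).
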