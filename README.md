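# aslhemo

Arterial spin labeling (ASL) hemodynamics for studies of regional perfusion
stress — built around the use case of sickle cell anemia (SCA), where
cerebral blood flow (CBF) is chronically elevated to compensate for reduced
arterial oxygen content, yet the deep watershed white matter may remain
under-supplied. The package quantifies CBF and bolus arrival time (BAT)
from ASL, delineates each subject's **individual watershed areas (iWSAs)**
physiologically from their own BAT map, computes FLAIR lesion burden, and
runs the cohort statistics that link hemodynamics, microstructure and
cognition.

## What it computes

**Multi-inflow-time PASL fitting.** The difference signal of a pulsed-ASL
sequence with a Q2TIPS-bounded bolus (duration τ) follows the general
kinetic model; in the identifiable intravascular-relaxation form:

```
ΔM(t) = 0                                    t < Δt
ΔM(t) = 2·M0b·f·α·(t − Δt)·exp(−t/T1b)       Δt ≤ t < Δt + τ
ΔM(t) = 2·M0b·f·α·τ·exp(−t/T1b)              t ≥ Δt + τ
```

with `f` = CBF (ml/g/s), `Δt` = BAT, `M0b = M0/λ`, labeling efficiency
α = 0.98, τ = 0.7 s, λ = 0.9. Because ΔM is linear in `f`, the voxel-wise
two-parameter least-squares fit is profiled: CBF is solved in closed form
at each candidate BAT, and BAT is found by exhaustive coarse search plus
dense local refinement. Voxels are first screened against the noise of
four ghost-free background corner ROIs (keep if the peak difference signal
exceeds mean + 1 SD).

**Single-delay pCASL quantification** (α = 0.85, τ = 1.8 s, PLD = 1.5 s):

```
CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))
```

Blood T1 is derived per subject from hematocrit and oxygen saturation
(fast-exchange two-pool calibration) — anemic blood relaxes slowly
(T1 ≈ 1.99 s at Hct 0.25) versus normal blood (≈ 1.77 s at Hct 0.41).

**iWSA segmentation.** Within the box-eroded white-matter mask, voxels at
or above the 70th percentile of the subject's own BAT distribution form
the individual watershed area; the rest is early-arrival white matter.

**Lesion burden.** Inside generous lesion seed masks, voxels whose FLAIR
intensity exceeds `1.02 × mean cortical FLAIR` enter the burden mask,
apportioned across early-WM / iWSA / unclassified.

**Cohort statistics.** Shapiro-Wilk-gated t / Mann-Whitney comparisons
with Benjamini-Hochberg FDR per declared family, Cohen's d / rank r / φ
effect sizes, age-and-sex residualization, OLS regression with VIFs, and
bootstrap product-of-coefficients mediation (percentile CI, CaO2 = 1.34·Hb·SaO2
+ 0.003·pO2 as the oxygen-content covariate).

A synthetic module generates every input with known ground truth: digital
phantoms with gray-matter shell / early-WM core / late-arrival watershed
pocket compartments, FLAIR volumes with planted hyperintense lesions, and
a two-group cohort table with a planted CBF → FA → processing-speed
mediation triple.

## Worked example

```python
from aslhemo import (PhantomSpec, make_phantom_multiti, fit_multi_ti,
                     segment_iwsa, summarize_roi)
from aslhemo.reliability import estimate_background, reliable_voxel_mask
from aslhemo.roi import erode_mask

ph = make_phantom_multiti(PhantomSpec(seed=42))       # SCA-like phantom
noise = estimate_background(ph.diff_series)
mask = reliable_voxel_mask(ph.diff_series, noise)
maps = fit_multi_ti(ph.diff_series, ph.m0, ph.acq, ph.blood, mask)
roi = segment_iwsa(maps.bat, erode_mask(ph.masks["wm"], 2))
```

This prints (via `summarize_roi` on the fitted maps):

```
background: mean=-0.0001, sd=0.0497; reliable voxels=85638
BAT threshold = 1.019 s; watershed voxels = 3172
early WM  CBF =  33.97 ml/100g/min, BAT = 0.738 s  (n=7399)
iWSA      CBF =  24.48 ml/100g/min, BAT = 1.507 s  (n=3172)
```

The fit recovers the phantom's planted compartments (early WM: 34
ml/100g/min at 0.74 s; watershed pocket: 24 ml/100g/min at 1.51 s), and
the percentile rule isolates the late-arrival pocket. The same pipeline is
available from the shell:

```
aslhemo run-all --seed 1 --out study/
aslhemo simulate --seed 1 --out study/   # inputs only
aslhemo fit-multiti --diff study/mti_diff.nii --m0 study/mti_m0.nii --t1-blood 1.99 --out maps/
```

`run-all` writes hemodynamic maps (NIfTI), ROI/lesion/comparison tables
(TSV), a mediation summary (JSON) and a provenance record; reruns with the
same configuration are byte-identical.

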