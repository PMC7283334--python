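# Methods

This note documents the models, defaults and design choices behind `petref`,
and what the synthetic experiments do and do not demonstrate.

## Forward model

**Tracer kinetics.** Tissue activity follows the irreversible two-tissue
compartment model standard for FDG: free tracer C1 exchanges with plasma
(K1 mL/g/min in, k2 /min out) and is phosphorylated irreversibly into C2 at
k3 /min. The measured concentration is (1−vB)(C1+C2) + vB·Cp with fractional
blood volume vB. The solver is an exponential-integrator recursion exact for
a plasma curve that is linear within each 0.5-s step; tests verify agreement
with a `solve_ivp` oracle at rtol 1e-10. Frames report the *mean* activity
over each frame interval, as a scanner histogramming list-mode counts does.
All activities are decay-corrected (no ¹⁸F half-life anywhere), which keeps
the closed-form oracles exact.

**Plasma curve.** The ground-truth input function rises linearly from zero to
1000 kBq/mL at 0.5 min (constant-rate 20-s infusion) and decays as
830·e^(−0.5t′) + 150·e^(−0.03t′) + 20·e^(−0.01t′). The tail rates were chosen
once so the plasma curve is slowly varying across the late-scan Patlak window
(t ≥ 20 min): Patlak linearity is an asymptotic property, and a fast-decaying
tail mixture leaves curvature in the window that biases the fitted slope by
~2% for grey-matter kinetics. With this curve the window slope matches the
closed form to better than 1%, consistent with treating t* = 20 min as the
point where the graphical plot is effectively linear.

**Phantom.** Nested ellipsoids: a cortical grey-matter ribbon (4 mm) around a
deep white-matter core with CSF ventricles; the ribbon is split per
hemisphere into 34 angular parcels carrying Desikan-Killiany names (the
name-to-sector assignment is alphabetical and deliberately arbitrary —
anatomical fidelity is not the point; exercising partial-volume effects at
GM/WM/CSF boundaries is). Cerebellar lobes have their own GM shell and WM
core; pons and midbrain are midline cylinders; two 4-mm carotid tubes sit
below the brain with >12 mm clearance from active tissue so their
partial-volume loss is a pure scale factor. The candidate-region table has
exactly 84 entries (68 cortical, 10 subcortical, 4 cerebellar, pons,
midbrain). The label volume is exactly mirror-symmetric in x, and every
structure is painted into empty voxels in a fixed priority order, so the
phantom is bit-reproducible.

**Resolution and noise.** The scanner PSF is an isotropic Gaussian, default
FWHM 6 mm (typical clinical PET; configurable). Voxel noise is Gaussian with
variance proportional to activity over frame duration — count statistics
without projection-space simulation; the ROI-level counterpart divides the
variance by the region's voxel count. The default noise scale (1.5) puts
late-frame voxel noise near 20% and regional noise near 1%.

## Partial-volume correction

The modified Müller-Gärtner correction is
(PET − wm_est·G(WM) − csf_est·G(CSF)) / G(GM), computed where G(GM) ≥ 0.3
(configurable); voxels outside that domain are NaN and excluded from ROI
means, never zeroed. The "modified" element is the region-based white-matter
estimate: the mean over the WM probability ≥ 0.95 core eroded by 6 mm
(Euclidean distance transform), which is untouched by spill-in at clinical
FWHMs. CSF activity is assumed zero.

One modeling decision deserves emphasis: the correction's target ("GM")
compartment is defined as *all candidate parenchyma* — cortical and
subcortical grey matter, cerebellar cortex and white matter, pons, midbrain —
while the spill compartment is the deep cerebral white-matter core. This
keeps every one of the 84 candidate regions inside the correction's validity
domain, so PVC and non-PVC rankings cover the same regions. The cost is that
Müller-Gärtner cannot undo mixing *between* two target-compartment tissues:
cerebellar white matter, enclosed by the hotter cerebellar cortex shell,
retains a large positive bias after correction, and thin cortical parcels
inherit a small bias from their neighbors. This is a faithful reproduction of
the method's real limitation, not an implementation artifact.

PVC is applied frame-by-frame before kinetic modeling (the white-matter
estimate is recomputed per frame); a map-level correction of the finished
CMRg image is also possible through the same functions but is not the
default path.

## Kinetics and units

Patlak: y(t) = Ct/Cp against x(t) = ∫₀ᵗCp dτ / Cp, ordinary least squares
over frames with t ≥ t* = 20 min (9 late frames under the default schedule).
The abscissa depends only on the input function, so voxelwise and
cohort-scale fits reuse one precomputed weight vector; a test pins this to
per-voxel recomputation. CMRg = Ki·C_glc/LC ÷ ρ × 100 in µmol/100 g/min,
with LC = 0.80, tissue density ρ = 1.0 g/mL, and C_glc in mmol/L (numerically
µmol/mL, so the only explicit conversion is the 100 mL-per-100-g factor).
The recovery target for the measured tissue curve is (1−vB)·K1k3/(k2+k3):
the vB·Cp term contributes only to the Patlak intercept.

## Input function construction

The IDIF is the per-frame mean over the carotid label. Its partial-volume
loss is absorbed into a single least-squares scale factor against the six
blood samples — the calibrated IDIF matches the true plasma curve to ~1.5% at
the sampling times on the noiseless phantom. Concatenation hands off from
IDIF frames to blood samples at the first blood-sample time (blood is truth
at late times). The tri-exponential fit runs bounded nonlinear least squares
from 8 log-spaced rate initializations with the continuity constraint
ΣAᵢ = peak enforced softly during optimization and exactly on output; ties
between starts break by lowest residual, then lowest λ₃. Neither metabolite
nor dispersion/delay correction is modeled.

## Cohort generator

Effects are planted on **CMRg**, the biological endpoint. Because FDG
competes with glucose, the tracer-uptake multiplier carries a factor
(reference glucose 5.0 mmol/L) / (subject glucose); converting Ki back to
CMRg cancels the subject's glucose exactly. Without this coupling the group
difference in fasting glucose (≈4.8 vs 5.2 mmol/L) would masquerade as a
pons age effect.

Per-subject regional multipliers are
(1 + slope·(age−25)) × (1 + 0.02·[F]) × (1 + group offset) × noise, where
noise is a shared global lognormal factor (σ = 0.10) times independent
regional lognormal noise (σ = 0.03). The shared factor represents global
inter-subject metabolic variability — precisely the component SUVR
normalization exists to remove; leaving it out makes the whole-brain mean
unrealistically quiet (σ/√84) and no single reference region could compete
with it.

Default aging effects: uptake and volume slopes drawn once (fixed seed) from
−[0.1%, 0.4%] per year per region pair; pons slopes exactly zero (the planted
null the pipeline must recover); midbrain small but nonzero. Aging cohort:
30 young (18–30 y) + 29 older (65–85 y), sex Bernoulli(0.55 F).

Clinical effects: global hypometabolism MCI −7.5% / AD −15% in every region,
with focal excess in the AD-susceptible targets (posterior cingulate
−8.5%/−17%, precuneus −10%/−22%) and the pons unaffected. The posterior
cingulate deficit is nearly all shared with the whole-brain mean — so a
whole-brain reference absorbs it, while a pons reference preserves it: the
mechanism the group comparison demonstrates. Clinical groups are age-matched
over 65–75 y, as in case-control designs; this matters because the age-flat
pons cannot cancel age-driven cohort variance that a whole-brain mean (whose
constituents all decline with age) partially does.

## Cohort-scale execution

Rendering and voxelwise-correcting a dynamic image per subject per replicate
would be pure waste: for a fixed phantom the PSF is linear, so regional means
of the blurred (and Müller-Gärtner-corrected) image are fixed linear
functionals of the per-region activities. `RegionalForwardModel` precomputes
those mixing matrices once (87 convolutions); a test pins its output to the
voxelwise render → correct → ROI-average path at rtol 1e-9. The replicated
experiments (50 cohorts of 59 subjects; 84 regions; PVC and non-PVC Patlak
per subject-region) then run in seconds. Problem sizes used by the default
experiments: 64³ grid at 2 mm, 32 frames, 50 replicates — large enough that
every region is populated and partial-volume effects are strong, small
enough to iterate comfortably.

## Statistics

LMG relative importance with two predictors reduces to
r²_age = ½[R²({age}) + (R²({age,sex}) − R²({sex}))]; shares are nonnegative
here and sum to the full-model R² by construction (asserted to 1e-12 against
explicit ordering enumeration). The reported p-value is the two-sided t-test
of the age coefficient in the full model — the decomposition itself carries
no test, and this choice is named in the output. Laterality merging uses a
paired two-sided t-test at α = 0.05, uncorrected; merged intensity values are
volume-weighted so merging commutes with voxel-level pooling; identical sides
(p undefined) merge. Group contrasts are Welch t-tests, uncorrected, with
z-scores standardized to the control group.

## What passing tests do and do not show

The phantom demonstrates that the *procedure* recovers planted structure
through a realistic chain of distortions (PSF mixing, blood-volume
contamination, finite-window Patlak bias, count noise): the pons attains
rank 1 in ≥90% of replicates because zero slope was planted there, and the
pons-referenced clinical contrasts dominate because part of the disease
signal was planted globally. None of this validates the anatomical claim
that the human pons is metabolically age-stable — that is an empirical input
taken from quantitative imaging, not something a simulation can establish.
Real data add motion, scatter, attenuation-correction error, segmentation
error and co-registration error, all outside this model; the phantom is
pre-aligned and perfectly segmented by construction.

## Numerical and degenerate-input policy

Negative rendered activities are clipped at zero by default (off for
equivalence tests). Patlak points with Cp ≤ 0 are dropped with a warning;
fewer than 3 late points is an error. Empty carotid masks, empty eroded WM
cores, degenerate IDIF calibration, unpaired laterality rows, constant
predictors and sub-minimum group sizes all raise with messages naming the
offending object. All randomness flows from integer seed sequences
(`numpy.random.default_rng([seed, stream])`) with fixed per-stage stream
ids; identical seeds give bit-identical phantoms, cohorts, images and
tables.
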