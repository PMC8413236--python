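# Methods

## The computerised score

The quantity of interest is the fraction of the upper-zone visceral pleural
surface occupied by dense, pleurally-based fibroelastotic tissue. The
surface is operationalised in image terms: on each axial slice, the
*pleural shell* is the set of lung voxels removed by `depth` iterations of
4-connected 2-D erosion of the lung cross-section (default depth 3 pixels;
a 6-connected 3-D erosion variant exists behind `erosion_3d`). The shell is
restricted to the *upper zone*: axial slices from
`apex + ceil(5 mm / slice spacing)` down to the carina slice (inclusive;
configurable). Shell voxels with HU ≥ `dense_threshold_hu` are classified
dense, per-slice 8-connected dense components smaller than
`min_component_shell_voxels` are discarded as noise, and the score pools
counts over both lungs. Axial slice 0 is the most cranial slice everywhere,
and all mm→slice conversions use the ceiling so the apical exclusion never
under-excludes.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `shell_depth_pixels` | 3 | in-plane pixel band representing the visceral pleural surface |
| `dense_threshold_hu` | −200 HU | separates fibroelastotic/soft tissue (≈ +40 HU) from aerated lung (≈ −850 HU) with a wide margin on either side; configurable and echoed in all outputs |
| `min_component_shell_voxels` | 5 | suppresses single-voxel noise at 30 HU additive noise without eroding genuine lesion arcs (phantom experiments) |
| `cutpoint_percent` | 2.5 | the working dichotomisation threshold for survival/classification analyses (1 and 5 are the other candidate cutpoints) |
| lung-air threshold | −320 HU | midway between aerated lung and soft tissue |

The denominator pools the upper-zone shell of both lungs (one score per
patient); mediastinal and costal pleura are not distinguished. The
radiologist gate (`gate_by_radiologist`) zeroes the score when the visual
read found no PPFE, and dichotomisation is inclusive (`gated ≥ cutpoint`).

## Lung segmentation and the solidify step

Segmentation is threshold-based: air voxels not connected to the grid
border are internal air; the component reachable from the most cranial
slices is the airway lumen and is removed; the two largest remaining
components are the lungs, labelled right/left by in-plane centroid. Dense
subpleural lesions fail the air threshold, so the raw mask has peripheral
bites exactly where the tissue of interest lies. The `solidify` step
restores them:

- `"hull"` (default): per-slice convex hull of each lung
  (`skimage.morphology.convex_hull_image` with pixel-square
  `offset_coordinates`). On convex cross-sections this reconstructs the
  boundary to within a chord sagitta of the lesion's angular width; the
  sub-voxel ring of soft tissue it can admit is eliminated downstream by
  the small-component filter.
- `"fill"`: slice-wise hole filling only — exact on lesion-free anatomy
  (Dice 1.0 against phantom truth) and idempotent, but blind to peripheral
  lesions.
- `"none"`: raw threshold components.

Known consequences of the hull default: on a lesion-free phantom its Dice
against truth is ≈ 0.988 (the added ring), and re-segmenting its own
rendered output adds another sub-voxel ring (not idempotent). Both are
properties of the boundary-reconstruction choice, not of the score, and the
`"fill"` mode retains the exact/idempotent behaviour. Real lungs are not
convex (concave medial border); the hull mode is adequate for convex
phantoms and mildly over-inclusive mediastinally on real anatomy — a
documented limitation, not a validated clinical segmentation.

Carina localisation tracks the cranial airway component caudally and
returns the first slice on which its cross-section has split (matching
manual identification on phantoms to ±1 slice); a manually supplied carina
slice always wins, mirroring clinical practice.

## Phantoms

Phantoms are analytic: an elliptic-cylinder soft-tissue thorax (+40 HU),
two half-ellipsoid aerated lungs (−850 HU), a tracheal air column
bifurcating at a known slice, additive Gaussian noise (default sd 30 HU),
and subpleural lesions (+40 HU) as angular sectors of the peripheral band.
Ground truth is exact voxel counting on the noise-free label grid — never
the HU rendering — using the same erosion definition of the shell
(independently verified in tests against a city-block distance-transform
recount).

`spec_for_coverage` aims a requested coverage by choosing sector bounds
from the empirical quantile of the shell-voxel angle distribution (the
angular density around an ellipse is non-uniform), lays lesions down as up
to five narrow foci per lung (PPFE is typically multifocal; narrow sectors
keep the convex-hull chord error small), and extends each focus
`ceil(sagitta) + 1` voxels deeper than the shell band, where the sagitta
uses the ellipse's largest curvature radius a²/b — so a boundary
reconstruction error of up to the sagitta cannot push the measured band out
of the lesion. Requested coverage then maps to counted truth within ±1
percentage point, and the full measurement chain recovers truth with a mean
absolute error of ≈ 0.6 pp over 0–40% coverage.

What the phantoms do **not** emulate: real CT texture, partial-volume
boundaries, respiratory motion, non-convex lungs, fissures, vessels, and
apical scarring distinct from the lesion model. Passing phantom tests shows
the measurement chain is internally consistent at clinical-scale geometry,
not that the score is accurate on clinical scans.

## Synthetic cohorts

One row per subject: age ~ N(68, 9²), 79% male, 71% ever-smokers, 67% ever
on antifibrotics, DLco ~ N(50, 16²) %predicted, baseline FVC ~ N(77, 20²)
%predicted — values chosen to resemble a contemporary IPF population.
PPFE categories default to probabilities (0.45, 0.44, 0.11) for
absent/moderate/marked (between the two cohort prevalences the score was
built for), with a continuous computerised score drawn conditional on
category (lognormal; marked shifted above 5%).

FVC trajectories follow the mixed-effects structure the decline estimator
assumes: intercept = baseline FVC plus N(0, 0.15²) L; slope = −0.12 L/yr
base, +0.04 if on antifibrotics, −0.01 for ever-smokers, plus N(0, 0.08²)
L/yr, **minus** `extra/100 × intercept` where `extra` is the category's
additional 1-year decline in percent of baseline (defaults 0 / 5.2 / 18.3);
residual sd 0.12 L (realistic spirometry noise); visits at 0, 0.25, 0.5,
0.75, 1.0, 1.5 years (the 18-month modelling window).

Survival is exponential proportional hazards: baseline 0.16 /yr; default
HRs 2.4 (moderate), 7.7 (marked), 0.97 per DLco point, 0.64 antifibrotic;
an optional HR on the cPPFE ≥ 2.5% flag for dichotomised-score studies;
optional shared gamma frailty per centre; censoring U(0.5, 8) years,
independent. The implied event fraction has a closed form
(`expected_event_fraction`) used as a generator invariant.

## Decline estimation

`fit_fvc_lme` is a REML `statsmodels` MixedLM with random intercept + slope
per subject. The 1-year prediction is subject-specific (fixed part plus
predicted random effects) — a population-level prediction would make the
per-patient decline uninformative; a marginal mode exists behind
`subject_specific=False`. "Observed baseline FVC" is the measurement
closest to the baseline CT within ±3 months, ties toward the earlier one.
Eligibility: a baseline measurement within 3 months and another in 3–18
months; exclusions are logged with machine-readable reason codes.

Because the PPFE category is deliberately absent from the trajectory model
(as in the estimator's definition), the category's slope effect lives in
the random slopes and is attenuated by BLUP shrinkage — ≈ 4–7% at the
default noise level, so the recovered marked-category coefficient sits near
17–17.5 pp against a generative 18.3 pp. This is a property of the
estimator under these conditions, quantified in the acceptance run, not a
defect of the fit. In noise-free configurations the pipeline is exact
(coefficients recovered to < 0.001 pp).

Derivation-style cohorts use OLS for decline ~ PPFE + covariates;
validation-style cohorts use a mixed model with a random intercept per
centre (the centre term acts on the single per-subject decline, so a
centre-level slope on study time has nothing to act on — design choice).
Multivariable OLS fits report the studentised Breusch–Pagan test.

## Survival machinery

Standard Cox fits, Schoenfeld tests (rank time-transform; the global test
combines per-covariate statistics), Kaplan–Meier estimation and the
log-rank test are lifelines. The shared gamma-frailty Cox model is
implemented here: an EM algorithm whose M-step is a Newton–Raphson
maximiser of the Efron-ties partial likelihood with the log-frailties as
offsets (columns and offset centred internally; the estimates are invariant
and exp() stays in range), and whose E-step sets each centre's posterior
mean frailty to `(1/θ + D_g) / (1/θ + H_g)`. The frailty variance θ is
chosen by the profiled marginal likelihood on a grid including θ = 0, using
the closed-form gamma integral per group; at θ = 0 or with a single centre
the fit coincides with the plain Cox model (verified to 1e-4). Against R's
`survival::coxph(..., frailty(centre))` the hazard ratios agree to ~0.2%;
θ itself differs (R profiles it differently) with negligible effect on the
coefficients. Reported standard errors condition on θ̂.

C-index bootstrap: subjects resampled with replacement, model refitted,
concordance evaluated on the resample; mean and percentile 95% CI over 500
iterations (seeded; bit-reproducible). Median-survival CIs invert the
pointwise log-log Greenwood band: the lower (upper) limit is the earliest
time at which the band's pessimistic (optimistic) curve crosses 0.5 — the
reflected-bound reading; a curve that never reaches 0.5 yields
"not reached", not an error.

Fixed-horizon classification: deaths strictly before the horizon are
events; subjects followed to at least the horizon alive are non-events;
censored-before-horizon subjects enter no cell (boundary convention
documented and configurable). AUCs are mid-rank Mann–Whitney statistics;
variances and paired comparisons use the DeLong structural-components
estimator (verified against r-pROC to 1e-6).

No multiple-testing correction is applied anywhere; p < 0.05 is the
working significance level throughout.

## Problem sizes and numerical choices

The test suite and acceptance script use phantoms of 120×128×128 voxels at
1 mm spacing, 20-phantom recovery sweeps, cohorts of 1000–2500 subjects for
effect-size recovery (hazard-ratio values averaged over 4–6 replicate
cohorts to report the estimator's expectation rather than one draw), and
200-replicate null calibrations — sizes at which Monte-Carlo error is well
inside the tolerances being checked. MixedLM convergence failures raise,
never silently fall back. The Cox Newton solver stops at the last finite
iterate under monotone-likelihood separation and flags singular information
matrices. Known finite-sample behaviour: the partial-likelihood MLE of a
large log-HR (7.7) is ≈ 3% high at n = 2500; it is reported uncorrected.

## Limitations

- The segmentation is phantom-grade, not clinical-grade: no fissure or
  vessel handling, convexity assumptions in the hull mode.
- The dense-tissue threshold and noise-suppression defaults are principled
  stand-ins, disclosed in every output, not values validated on clinical
  CT.
- Gamma is the only frailty family fitted by default (log-normal behind a
  flag is not implemented; the EM structure would change).
- Synthetic cohorts are correctly specified for the models fitted to them;
  they cannot detect misspecification sensitivity (e.g. non-linear FVC
  trajectories, informative censoring).
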