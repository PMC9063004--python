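# Methods

This note documents the model conventions, numerical choices and known
limitations of `deltarad`. Everything quantitative stated here is computed
by the test suite or the example scripts; nothing is quoted from external
results.

## Dose scale and bin assignment

Schedules are normalized with the linear-quadratic biologically effective
dose, `BED = n·d·(1 + d/(α/β))` with `α/β = 10` Gy, and characterized by
the per-fraction rate `BED/n`. Two delta windows are defined on cumulative
delivered BED: **BED20** (threshold 20 Gy, closed upper bound 30 Gy) and
**BED40** (threshold 40 Gy, no upper bound). Because a setup image is
acquired *before* that day's delivery, dose delivered through fraction `k`
is credited to the image of fraction `k + 1`; with this convention the
assignment reproduces the image pairs of all 30 reference schedules.
Conventions worth noting:

* Equal dose per fraction is assumed within a schedule (adaptive replans
  are out of scope); the packaged reference table stores published values
  verbatim.
* When only `total_bed` and `bed_per_fraction` are given, `n` is recovered
  as `round(total/rate)` accepting a ratio within 0.1 of an integer —
  published rates are rounded to 0.1 Gy, so `n·rate` may miss the total by
  a few tenths of a Gy (one reference schedule does: 54.8 vs 5 × 11.0).
* An unreachable bin yields `None` (the patient is excluded from that bin,
  never an error); a first crossing of 20 Gy that overshoots 30 Gy is
  flagged out-of-window and excluded from BED20.

## Preprocessing

Texture statistics are ROI statistics: the mean, SD and empirical CDF are
computed over in-mask voxels only. The dynamic range is limited by
*clipping* to `μ ± 3σ` (sample SD, `ddof = 1`); clipping rather than
exclusion keeps the voxel lattice intact for the matrix builders. A
constant ROI is a logged no-op. Quantization to `G = 64` levels is
histogram equalization: level `= ceil(G · F̂(x))` clamped to `[1, G]`,
with ties sharing the level of their common CDF value (deterministic, no
random tie-breaking). The mapping is monotone; occupancies are as equal as
ties permit. Out-of-mask voxels carry level 0 and are excluded everywhere.
Mask/volume grid mismatch is a hard error; no resampling is in scope, and
the native anisotropic voxel (1.5 × 1.5 × 3.0 mm³) is treated on the index
grid without physical-distance correction.

## Texture matrices and the 39-feature panel

All four families use the full 3D 26-neighborhood. GLCM and GLRLM use the
13 unique directions (antipodal pairs merged); per-direction matrices are
*summed* into one matrix before features are computed (merged-3D
aggregation), not feature-averaged. GLCM uses displacement one, symmetric
counting, no distance weighting. GLSZM zones are 26-connected components
per level (`scipy.ndimage.label`). NGTDM averages only in-mask neighbors,
and voxels with no in-mask neighbor are excluded from the counts so masked
ROI edges cannot fabricate differences. Conservation identities (GLCM
probabilities sum to 1, zone sizes sum to the voxel count, per-direction
runs partition the ROI) are asserted on every build.

GLCM variance and entropy are computed on the joint distribution; sum
average is `Σ p(i,j)(i+j)`. Homogeneity is the inverse-difference form
`Σ p/(1+|i−j|)`. Run percentage under merged aggregation is
`n_runs/(N_v · 13)`, so an ROI of isolated voxels scores exactly 1.

Five features are reported volume-decoupled by default, with the plain
IBSI forms always available as flagged twins:

* GLRLM gray-level and run-length non-uniformity: divided by the run count
  a second time (the "normalized" variants), removing linear volume
  growth.
* NGTDM coarseness: multiplied by the number of contributing voxels
  (coarseness scales as 1/N); NGTDM busyness: divided by it (busyness
  scales as N). The two go in opposite directions because the raw
  statistics scale oppositely; a uniform multiplication of both would
  decouple one and double the other's volume dependence.
* GLCM energy: the probability-based angular second moment is already
  volume-free, so modified and plain forms coincide.

Degenerate statistics (single-level ROI: GLCM correlation, the NGTDM
coarseness/busyness denominators) return NaN — a quiet sentinel that the
delta stage treats as missing (listwise deletion per bin, no imputation).
The registry keeps the published display names and IBSI codes as metadata;
two printed codes are duplicated across variance pairs in the source
panel, so features are keyed by class + name, never by code.

## Delta features

`delta = f_pre − f_post`, so an increase under treatment is negative; the
percent-change form `100·(f_pre − f_post)/f_pre` follows the same sign
convention and is used for summaries only — the raw difference feeds the
models (config-switchable). A patient whose assigned bin image is missing
is dropped from that bin with a warning, never zero-filled.

## Selection and internal validation

Per bin, a 500-tree classification forest (Gini splits, `mtry =
floor(√39) = 6`, unlimited depth, minimum node size 1, bootstrap per tree,
OOB score recorded) ranks features by mean decrease in impurity; ties
break lexicographically. Rows are sorted by patient id before fitting so
the ranking depends on the data, not storage order. No class weighting is
applied despite the 11/19 imbalance.

Internal validation: 1,000 iterations; each draws `round(2n/3)` patients
*without replacement* ("20 at a time" read as a subset size; a
with-replacement variant is config-selectable), standardizes the two
covariates on the training subset, fits an intercept + 2-covariate
logistic regression by maximum likelihood (unpenalized; a separated,
non-convergent fit falls back to a ridge-stabilized refit and is counted),
scores **all** patients, and records the Mann–Whitney AUC (ties ½).
Single-class training draws are redrawn and counted. Percentiles use
linear interpolation on the empirical distribution. Stage seeds derive
from one pipeline seed via `SeedSequence` substreams.

Two properties of this protocol matter for interpretation:

* **Optimism.** Scoring the training patients shifts the whole AUC
  distribution upward: label-independent feature pairs produce mean AUCs
  near 0.59–0.61, not 0.50 (the suite measures this). The percentile band
  is therefore an internal-consistency band around an optimistic center,
  not a null confidence interval — it frequently, but not always,
  straddles 0.5 under the null.
* **Selection optimism.** Choosing the best 2 of 39 features on the same
  30 patients and then validating with the protocol above yields mean
  AUCs around 0.7 even when every feature is label-independent. For this
  reason the suite checks the absence of signal in the late bin two ways:
  the early-selected signature evaluated on the late bin (persistence,
  which is free of per-bin selection optimism), and the qualitative
  early > late ordering of the per-bin reports.

## Synthetic cohorts

The generator emulates the study conditions: 30 patients (11 responders /
19 non-responders), the reference fractionation mix (BED/fraction ∈
{11.0, 11.9, 12.3, 14.4, 20.0, 26.4} Gy; the reference rows are used
verbatim at the default size), ellipsoidal masks of roughly 500–3000
voxels on a 32³ grid, and per-patient correlated Gaussian random fields
(white noise convolved with a Gaussian kernel, base correlation length 1
voxel). Noise has two components with defaults of 5% each: i.i.d. voxel
noise (relative to the in-mask field SD) and a coherent per-acquisition
*smoothness jitter* of the correlation length. The jitter reflects how
daily setup images actually vary — blur and repositioning move an entire
radiomic panel together — and it is what gives the null delta panel its
realistic low effective dimensionality; with purely i.i.d. noise the 39
null deltas span many independent chance dimensions and best-of-panel
selection optimism inflates far beyond what correlated real panels show.

The response signal is a texture drift, not an intensity drift: responders'
correlation length increases by `effect_size` (default 0.5, i.e. +50%) on
the setup image their schedule assigns to BED20, and nowhere else.
Histogram-equalized quantization discards first-order changes, so the
signal lives exactly where the second-order panel looks. The drift is
deliberately *not* family-specific: a correlation-length change moves
co-occurrence, run, zone and neighborhood-difference statistics alike, so
recoverability is asserted as "the selected features are genuinely
class-separating", not "the selected features are GLCM".

With all stochastic components set to zero, every fraction volume is
byte-identical and all deltas vanish — the end-to-end zero test.

What the generator does **not** emulate: bSSFP contrast and banding, coil
profiles, inter-patient intensity scale differences (irrelevant after
equalization), daily recontouring variability (masks are constant across
fractions), tumor shrinkage, and any correlation between schedule and
outcome. Passing tests therefore demonstrate that the pipeline recovers a
controlled second-order signal under realistic noise — not that real
tumors carry such a signal.

## Problem sizes used by the suite

The acceptance checks run at the study's cohort geometry (30 patients,
11/19, 1,000 bootstrap iterations, 500 trees). Monte-Carlo style
properties average where the quantity is noisy: the null calibration uses
six zero-effect cohorts × three a-priori feature pairs; signal recovery
uses four effect cohorts; the brute-force texture oracle uses 200 random
ROIs of ≤ 4×4×4 voxels with ≤ 4 gray levels; determinism uses a
12-patient cohort on a 24³ grid with 200 trees/iterations. Feature
extraction crops to the mask bounding box, which changes no statistic and
keeps a 30-patient cohort under ~10 s.

## Known limitations

* The reference AUC figures of the motivating analysis are not
  reproducible here — they require the original patient images, which are
  not public; the pipeline reproduces the published arithmetic, the
  fraction-pair table and the qualitative early/late behavior instead.
* The exact closed forms of the volume-dependence modifications used in
  the original analysis are not published; the forms above are the
  standard decoupling choices, and the unmodified twins are always
  emitted alongside.
* DICOM-RT structure sets are not parsed; NIfTI masks are the contract.
* 2D/2.5D aggregation modes, first-order and shape features, filtered
  variants, and ratio-style deltas are out of scope.
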