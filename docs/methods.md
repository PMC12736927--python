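# Methods

This note records the models, conventions and design choices behind
`aquaspec`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral container and grids

Spectra are absorbance (unitless) on a strictly increasing wavelength
grid in nm.  The default emulated instrument has 125 uniformly spaced
channels over 908–1676 nm (≈6.19 nm spacing), a handheld-NIR class
configuration covering the first overtone of water; the grid is fully
configurable.  Absorbance is canonical; a reflectance helper
A = log10(1/R) lives in the synthetic module, fixing the conversion
point at data generation.  Every transform appends a label to an
append-only processing log that serialises with the data, so a file
records how far along the chain it is.

## Multiplicative scatter correction

MSC fits each spectrum to a reference by ordinary least squares over
all channels and applies the inverse affine map.  The reference
defaults to the mean spectrum of the set being corrected, computed once
(not iterated); it can be supplied explicitly.  Fitted slopes with
|b| < 1e-12 raise rather than amplify noise.  Because each row's
correction depends only on the fixed reference, MSC with a held
reference is idempotent, and it exactly inverts the affine
per-measurement scatter model the synthetic generator injects — this is
deliberate, making scatter-removal accuracy testable against ground
truth rather than only against itself.

## Savitzky–Golay second derivative

Defaults: window 11 channels, polynomial order 3, derivative order 2,
scaled per nm (values in nm⁻²) using the grid spacing.  These are
common chemometric settings for ~6 nm channel spacing; all are
configurable.  Edge channels where the window does not fit —
(window−1)/2 on each side — are dropped from the output grid instead of
extrapolated: the aquagram and water-band analysis ranges (≥1348 nm)
sit far from the grid edges, so trimming loses nothing of interest and
keeps the filter's exactness properties clean.  The filter is exact on
polynomials up to the fitting order; its accuracy on band-shaped
signals depends on the window-to-bandwidth ratio.  On a 30 nm-sigma
Gaussian sampled at 1 nm, window 11 / order 3 reproduces the analytic
second derivative to <1% of peak-to-peak; at the default 6.19 nm
spacing the same window spans ~2.3 sigma and the deviation grows to
~16% — accepted, since the analysis uses the derivative for band
separation and modelling, not as a calibrated differential operator.

## Difference spectra

Per-group day-minus-baseline differences operate on group-averaged
input (one row per group × day) and subtract the baseline-day mean from
every other day's mean, keeping the day and recording the baseline.
The operation is antisymmetric under swapping day and baseline.

## Aquagram

The aquagram statistic is the plain z-score of MSC-corrected absorbance
at each WAMAC wavelength, with the mean and standard deviation taken
over *all* measurements in the set passed in; group values are means of
per-measurement z-scores.  Consequences and choices:

* the normalisation pool is controlled by pre-filtering (the pipeline
  pools all treatments × days of one cultivar × leaf), because
  comparing groups requires a common pool;
* the standard deviation is the sample (n−1) form, the chemometric
  convention; switchable to population via `ddof`;
* no vector-norm or unit-circle scaling variants — the statistic is a
  plain z-score by construction;
* inputs are MSC-corrected raw absorbances, not derivatives; a warning
  is issued if the processing log lacks an MSC step;
* WAMAC wavelengths are read from the nearest grid channel, ties
  breaking toward the lower wavelength.

The classic 12-coordinate scheme (1348, 1360, 1373, 1385, 1410, 1422,
1441, 1453, 1466, 1478, 1490, 1503 nm) spans free water through water
clusters with 1–4 hydrogen bonds; the extended 7-coordinate scheme
(1416, 1447, 1503, 1521, 1534, 1551, 1571 nm) emphasises strongly
bound, polymer-associated water.  Published WAMAC lists vary by a few
nm between instruments and studies, so both sets are defaults only and
any custom (label, wavelength) list is accepted.

## PLS day-of-stress model

NIPALS PLS1 on column-centred predictors and centred response, with
X-deflation after each latent variable (y-deflation is available but
changes nothing for a single response); the regression vector is
assembled as b = W(PᵀW)⁻¹q, and the coefficient path over 1..K latent
variables comes from one fit because NIPALS models are nested.
Convergence tolerance 1e-12 with a 500-iteration cap applies to the
general inner loop; for one response it converges in a single pass.
Rank exhaustion stops extraction early with a warning and pads the
coefficient path.

Protocol conventions:

* each replicate spectrum is an independent observation (no averaging)
  by default; a per-leaf averaging toggle exists in the pipeline;
* models are fitted per cultivar × leaf on stressed plants only, with
  the integer day of chilling (0–7) as response; recovery-day spectra
  are excluded;
* the calibration/validation split is by whole plants — 1, 2, 4, 5, 7,
  8, 10 vs 3, 6, 9 by default — so no plant's spectra straddle the sets;
* leave-one-out cross-validation refits the model for every held-out
  sample; SECV is the root-mean-square LOO residual (an (n−1)
  denominator is available), and the chosen LV count is the first
  minimiser of SECV (parsimony on ties);
* SEC uses the (n − LV − 1) denominator; SEP is the RMS error on the
  untouched validation set; R is the Pearson correlation between
  reference and predicted values.

## Physiology and metabolites

Electrolyte leakage is 100·E1/E2 (conductivity before/after
autoclaving), degree-0 homogeneous in the pair; E1 > E2 yields >100%
with a warning rather than an error, tolerating instrument noise.
Group comparisons use the equal-variance Student t-test by default
(Welch by flag), starring p < 0.05/0.01/0.001.  Metabolite matrices are
log2 of condition-mean over control-mean (median switchable), control
column identically zero, with not-detected cells carried as NaN.
T-tests run on raw concentrations by default (log2 switchable).  No
multiple-testing correction is applied by default — single-cell tests
are the classical presentation of such tables — but a
Benjamini–Hochberg option exists; with ~100 cells per table, expect a
handful of false single-test stars.

## Synthetic generator

The generator emulates the design of a two-cultivar chilling
experiment: 10 plants per cultivar per treatment (control / stress /
recovery), three leaf types, daily spectra over days 0–7 of stress plus
a recovery timepoint at day 10, two replicate spectra per leaf per day
(three at recovery).  Per cultivar × treatment × leaf the row count is
trimmed to a uniform draw from 140–150 (25–30 at recovery), emulating
occasionally discarded field measurements.

Leaf absorbance is a sum of Gaussian bands on a 0.05 AU continuum:
weak O–H bands at 970/1087/1155 nm, free and weakly bound water at
1373/1416/1450 nm (the 1416 nm free-water band dominating at 0.5 AU),
water with 1–4 hydrogen bonds at 1466/1478/1490 nm and polymer-bound
water at 1534/1571 nm.  Gaussian shapes (rather than Lorentzian/Voigt)
are adequate at this resolution and give closed-form derivatives for
oracle tests.  Stress moves band amplitudes linearly with day:
free/weakly bound water declines (−0.020 AU/day at 1416 nm in the
sensitive cultivar) while strongly bound water rises (+0.004 to +0.006
AU/day), producing the aquagram signature of chilling — falling values
at 1348–1410 nm, rising values at 1466–1490 nm.  The tolerant cultivar
changes at 0.3× the sensitive rate — smaller, but still carrying enough
day information for sub-day PLS errors, consistent with both cultivars
being predictable; leaf factors (cotyledon 1.2×, first 1.0×, second
0.6×) order the effect sizes by leaf.  Recovery applies the cumulative
day-7 change times 1.4 (sensitive: damage persists and worsens) or 0.3
(tolerant: mostly recovered).

Each measurement receives multiplicative gain b ~ LogNormal(0, 0.08)
and additive offset a ~ Normal(0, 0.01) — exactly the affine model MSC
inverts — plus white channel noise (sd 0.0015 AU) and a per-plant
amplitude multiplier (sd 0.02) held constant across days.  With ~18–20
spectra per day group, the group-mean noise (~0.0004 AU) is well below
the smallest per-day amplitude step (~0.004 AU), i.e. noise ≲10% of the
effect, which is what makes strict day-by-day aquagram monotonicity a
fair expectation.

Physiology trajectories: sensitive electrolyte leakage rises 8 → 35 →
60 → 92% over days 0/3/5/7 and 100% at recovery (values are clamped to
[0, 100], so with 3-point replicate noise the recovery group mean sits
~2–3 points below the 100% ceiling); tolerant stays near 10% with a
mild day-7 rise.  Net photosynthesis retains 10% (sensitive) vs 70%
(tolerant) of the 20 µmol m⁻² s⁻¹ control level at day 7; transpiration
and stomatal conductance scale identically.  Metabolite tables draw
5 lognormal replicates per cell around condition means whose log2
ratios to control equal the configured effect matrix (e.g. sucrose −6.7
in the sensitive cultivar at day 7, cinnamic acid +1.1 in the tolerant),
with one not-detected cell (ferulic acid, sensitive, day 7).

What the generator does *not* emulate: radiative-transfer leaf optics,
temperature-dependent band shifts, day-level environmental batch
effects, drifting instruments, or non-affine scatter.  Passing
recovery tests therefore demonstrate that the analysis chain retrieves
the structure this model encodes — they do not certify performance on
real leaves, where scatter is only approximately affine and water-band
trajectories are not linear in time.

## Problem sizes and numerical conventions

Tests and the acceptance script run the generator at its default design
(≈1900 spectra × 125 channels; ~100 calibration spectra per PLS model,
LOOCV to 10 latent variables), with 100-seed repetition for the
aquagram trend check and 200 simulations for the null-calibration
check of LOOCV — sizes chosen so the whole suite completes in well
under a minute of compute while keeping Monte-Carlo margins wide.
Floating-point conventions: MSC and LOOCV agree with closed-form /
brute-force oracles to 1e-10; derivative linearity and idempotence to
1e-10; aquagram pooled normalisation to 1e-8; CSV numerics are written
at 12 significant digits.  Degenerate inputs (constant references,
zero-variance responses, zero-sd coordinates, missing baseline days)
raise errors naming the offender rather than propagating NaNs.

## Known limitations

* The permutation cross-check of the Student t-test is exact only
  asymptotically: at 5 replicates per group the discrete permutation
  null (252 splits) deviates from the t p-value by up to ~0.1
  mid-range; the tight 3-Monte-Carlo-SE agreement is asserted at 20
  replicates per group.
* PLS1 only (single response); no SIMCA/PLS-DA classification and no
  variable selection beyond regression-vector inspection.
* No instrument drivers, dark/white calibration, or JCAMP/SPC binary
  formats; CSV dialects only.
* Regression-vector band attribution treats a changed band's footprint
  as its ±1 sigma extent: second-derivative features of overlapping
  Gaussians legitimately fall between band centres, so centre-distance
  alone would mis-score genuinely informative channels.
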