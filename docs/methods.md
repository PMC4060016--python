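# Methods

## Overview

The package models the landscape-scale impact of an invasive paper wasp in
four chained stages: a presence-only species distribution model (SDM)
delimits the climatically suitable area; plot surveys give nest density and
occupancy per land-cover class; the two combine into a national nest total;
and a foraging-intensity model converts nests into prey consumed per pixel
per season. Each stage is usable on real rasters/CSVs and on synthetic
inputs with known ground truth.

## Coordinate and raster conventions

Projected metres, cell-centre registration, row 0 at the north edge.
The default cell is 500 m (25 ha); area arithmetic always uses
cell_size²/10⁴ ha. Nodata propagates: any operation touching a nodata cell
yields nodata. Rasters are single-band float32 GeoTIFFs (ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags) written and read with tifffile; write→read
round-trips values, geometry and mask bit-exactly for float32. Reprojection
and multi-band imagery are out of scope.

## Presence-only distribution model

**Form.** Log-linear density over the landscape: p(cell) ∝ exp(β·f), with
features linear + quadratic in the six standardized environmental variables
(standardization constants from the background sample only; optional
pairwise products). This keeps the likelihood convex and the response curves
unimodal; hinge/threshold features of MaxEnt 3.3.3 are deliberately omitted,
which is the main structural divergence from that software.

**Fit.** β maximizes mean_presence(β·f) − log Σ_background exp(β·f) −
λ‖β‖₁. The L1 term is handled exactly via the split β = u − v with u, v ≥ 0,
giving a smooth bound-constrained problem solved by L-BFGS-B (ftol 1e−8,
default λ = 0.01). The raw output exp(β·f)/Z sums to 1 over the background;
the logistic output is eᴴ·raw/(1 + eᴴ·raw) with H the entropy of the fitted
background distribution, so a presence at the entropy-typical raw score maps
to 0.5.

**Bias correction.** Collection effort is estimated as a quartic (biweight)
kernel density of the occurrence points, rescaled to max 1 and floored at
eps = 1e−3 so no cell has zero weight; default bandwidth 2× the mean
nearest-neighbour distance among occurrences. Background cells are drawn
without replacement with probability proportional to this surface, so the
fitted density ratio cancels the effort term. This is the standard
interpretation of supplying a bias file to a presence-only SDM; the simulator
makes the effort process explicit (kernels at known centres), letting tests
measure that bias-weighted background lowers coefficient RMSE relative to a
uniform background under biased sampling.

**Ensemble and threshold.** 50 runs by default; each shuffles the
occurrences, trains on round(0.75·n) and tests on the rest against one fixed
background evaluation sample (default 10,000 cells or all valid cells).
Test AUC is the ½-tie Mann–Whitney estimator. The per-run threshold is the
nearest-rank 10th percentile of training-presence logistic scores
(⌈0.1·n⌉-th smallest); the ensemble threshold is their arithmetic mean, and
suitability ≥ threshold (closed bound) defines the suitable mask.
Non-convergent runs are excluded from means and logged.

**Variable importance.** Jackknife gains (each variable alone; all others
without it) use the unregularized training gain over the uniform null.
Percent contribution is permutation importance — the drop in training gain
when a variable's raw values are permuted across presence + background cells
(5 permutations averaged), normalized to 100%. The path-dependent
contribution bookkeeping of the original software is not reproducible and is
not attempted.

## Density and occupancy

Plots are 10 × 10 m, so density = 100 × nests/plots in nests/ha, rounded
half-up to an integer; occupancy is rounded half-up to 2 dp. Rounding
happens *before* extrapolation: the report-table convention is that the
printed per-class values are the inputs to the area arithmetic, and only the
rounded values make the row and total arithmetic mutually consistent.
Detection is assumed perfect, so densities are conservative; no
MacKenzie-style detection model is applied. Low-preference unsurveyed
classes receive nominal (3 nests/ha, ψ = 0.03); unsuitable classes zero.
The class comparison uses a tie-corrected Kruskal–Wallis H on per-plot
counts with a χ² reference (df = k−1); all-tied input returns H = 0, p = 1.

## Extrapolation

occupied_ha = ⌊A_c·ψ_c⌋ and total_nests = ⌊A_c·ψ_c·D_c⌋, rows floored
before summation (a 1e−9 epsilon guards against float representation error
at exact integers). The unfloored values are carried in extra columns for
raster-side consistency checks. Whether nominal classes should be clipped to
the suitable mask is genuinely open; here all classes are restricted to the
mask, consistent with combining densities with the distribution model.

## Foraging and impact

F = 60·r·m·q with defaults r = 0.33 returns/min, m = 0.30, q = 0.75 →
F = 4.455 (display-rounded 4.5; component ranges give 2.4–8.4). Rasters use
the unrounded F. Seasonal foraging time counts hours with radiation ≥ 0.432
MJ m⁻² h⁻¹ — the WMO 120 W m⁻² bright-sunshine definition, adopted because
the source radiation data are MJ m⁻² while foraging time is naturally in
sunshine hours; the threshold is configurable and a precomputed hours raster
can bypass the conversion entirely. Night hours have ~zero radiation, so no
separate daylight rule is needed. Per cell of class c inside the mask:
nests = 25·ψ_c·D_c (unrounded), prey = nests·F·hours. The national budget is
reported both as the raster sum and as total_nests × F × mean seasonal hours
(≈ 540 h, the mean of within-distribution seasonal sunshine values), with a
min/max hours bracket. A sensitivity mode weights nests by continuous
suitability instead of the binary mask.

## Synthetic landscape generator

Gaussian random fields are smoothed white noise (separable Gaussian filter,
σ = correlation length in cells) — simpler than spectral synthesis and
sufficient for controlled autocorrelation. Elevation drives tmax/tmin via a
6.5 °C/km lapse rate; degree days accumulate from a per-cell sinusoidal
annual cycle; rainfall increases and solar decreases with elevation, so the
usual collinearity among climate layers is present. Land cover rank-
transforms one smooth field to uniform and slices it at cumulative class
weights (patchy, near-exact frequencies). Occurrences are drawn ∝
exp(β_true·z)·bias with bias a floored quartic-kernel mixture at known
centres. Plot counts are zero-inflated shifted Poisson: occupied ~
Bernoulli(ψ), nests | occupied ~ 1 + Poisson(λ−1), with defaults ψ =
(0.27, 0.23, 0.09) and λ chosen so expected density 100·ψ·λ matches the
surveyed 34/29/9 nests/ha while keeping counts > 3 rare. The sunshine stack
draws per-cell-hour Bernoulli bright states around a smooth probability
field whose mean targets ~540 bright hours over 89 days × 12 candidate
daylight hours (season fixed as 1 Feb–30 Apr, non-leap).

What the generator does **not** emulate: real spatial covariance structure
of climate, temporal weather autocorrelation, imperfect nest detection,
spatially correlated plot placement, and land-cover classes that track
topography. Passing tests therefore demonstrate estimator correctness and
internal consistency of the pipeline under known generating processes, not
predictive skill on real New Zealand data.

## Problem sizes and numerical choices

The bundled demo runs a 100×100-cell landscape (250,000 ha) with 253
occurrences, a 10-run ensemble and 5,000 background cells; statistical
property checks use 80×80 landscapes, 20 replicates for the bias-correction
comparison, 200 replicates for estimator recovery and 2,000 for rank-test
calibration — sizes chosen to make sampling error small relative to the
effects being measured while keeping a full run interactive. Optimizer
tolerances: ftol 1e−8, gtol 1e−9, max 500 iterations. Ties in AUC are ½;
percentile thresholds use the nearest-rank convention; degenerate inputs
(all-tied ranks, empty masks, zero-variance features, all-zero sampling
weights) return defined values or raise typed errors rather than NaN.

## Known limitations

No uncertainty propagation onto the national totals (bootstrap CIs would be
the natural extension); no detection-probability correction; the binary
suitable/unsuitable combination discards suitability gradation unless the
sensitivity mode is used; the bias grid estimated from occurrences partially
absorbs genuine habitat signal when effort and suitability are spatially
confounded, attenuating (not removing) the benefit of bias-weighted
background sampling.
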