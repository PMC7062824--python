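# Methods

This note documents the modelling assumptions, parameter defaults and
numerical choices behind `popcast`, and what the synthetic test world does
and does not establish about behaviour on real census data.

## Cohort-component engine

The projection is a deterministic recursion on counts indexed by
province × sex × single-year age (0–99 plus an open 100+ interval) ×
seven education stages. Within a projected year the order of operations
is: survival, provincial migration, education progression, international
migration; births are computed from the previous year's female population
with current-year rates, enter at age 0 in the illiterate stage, and are
not exposed to migration in their birth year. This ordering mirrors the
multiplicative structure of the recursion and is fixed; reordering the
multiplications would change nothing for the diagonal terms but would
redistribute the education feeder streams.

**Education timing and branching.** Progression probabilities are
attached to transitions, not to (age, stage) cells: each transition fires
exactly once per cohort, in the year the cohort reaches the destination
stage's entry age (primary 6, junior 13, senior 16, college 19, bachelor
19, master 23). Senior high has two outgoing branches (college,
bachelor), so stay-probability is 1 − G_college − G_bachelor; validation
rejects rate sets where the joint outflow exceeds 1. A linear
"stage − 1" chain cannot express this branching; the DAG is the minimal
generalization consistent with per-branch progression caps.

**Life table.** Life expectancy uses a standard period life table with
a_x = 0.5 for ages 0–99. The schedule's last entry is treated as the
central death rate m of the open interval, which contributes 1/m
remaining years per survivor; at m = 0 each survivor is credited 10
years (so a zero-mortality schedule yields e₀ = 110). The cap only
matters for degenerate inputs — any realistic calibrated schedule has
m₁₀₀ well above 0.1.

**Calibration.** Fertility and mortality are calibrated to scenario
targets by a single scalar per year (and per province × sex for
mortality), preserving the base-year age/education profiles. The TFR
scalar is exact by linearity (the implied TFR is the female-weighted mean
age schedule summed over ages 15–49). The mortality scalar is found by
Brent's method on k ↦ e₀(clip(k·q, 0, 1)), which is monotone decreasing;
the bracket k ∈ [0, 10] comfortably covers life-expectancy targets
between roughly 30 and 110 years for the hazard families used here.
Round-trip tolerances: TFR 1e-9, LE 1e-6 years.

**Migration rebalancing.** Because assumptions are stated as rates, the
implied interprovincial person-flows (rate × at-risk population) need not
sum to zero. Whichever side (total inflow or total outflow) is larger is
scaled down by the ratio smaller/larger, preserving proportions within
that side. When all nonzero flows share one sign the ratio is 0 and that
side is zeroed — the only balanced solution of the stated rule; the
all-zero case passes through unchanged.

## Scenario construction

Levels map to trajectories through stated anchors with linear
interpolation in calendar year between anchors and constant extension
after the last one. Choices where the anchor set underdetermines the
path:

- **Medium TFR after 2030** grows from 1.65 at the constant annual factor
  (1.802/1.706)^(1/70) taken from the two UN medium-variant anchors; we
  scale the growth rate onto 1.65 rather than jumping to the UN level, so
  no particular 2100 TFR value is asserted.
- **Low TFR** follows the medium path through 2020, then declines
  linearly to 0.75 × medium(2050), constant after; **high TFR** rises to
  2.0 by 2020 and to 1.25 × medium(2050), constant after.
- **Life expectancy** grows at (base rate/10) × (provincial base LE /
  national base LE) years per year, with base rates 1.0 / 0.5 / 1.5 per
  decade for medium / high / low mortality. The direct
  provincial-to-national ratio is deliberate: when the national value is
  a population-weighted mean dominated by high-LE provinces, the
  unweighted provincial mean gain lands slightly below the nominal base
  rate, as expected for this adjustment; the inverse ratio cannot produce
  that (its weighted mean gain is bounded below by the base rate by
  Jensen's inequality).
- **Provincial migration** uses a full 3 (income category) × 3 (level)
  anchor grid — e.g. high-income provinces phase NetPIM to zero by
  2010/2020/2030 under high/medium/low migration; medium-income provinces
  decline to 50% at mid-century and 0 by 2100 under the medium level;
  low-income provinces rise to 150% (high) or fall to 50% (low) by 2050
  and hold.
- **International migration** is −0.3015‰ (the mean of the 2005–2010 and
  2010–2015 estimates), constant through 2050 and linearly decaying to 0
  at 2100; high/low levels scale the whole path by 1.5/0.5.
- **Education progression** compounds at province-specific historical
  growth rates (medium), is frozen (low), or adopts the largest
  cross-province growth rate (high); SSP4 routes provinces to
  high/medium/low paths by income category. Caps: 0.999 on the three
  compulsory-stage transitions, 0.30/0.60/0.30 on
  college/bachelor/master entry; rates stay at a cap once reached.
- **Sex ratio at birth** converges linearly to 1.07 by 2050 and holds.

TFR is treated as a national target: provincial fertility matrices keep
their base-year relative differentials and share one national scaling
factor per year.

## Urbanization

The logistic curve is fitted on the logit transform
ln(PU/(b−PU)) = c(T−d) by ordinary least squares, with T in years since
1995. Saturation levels come from the 2015-level band table
(≥70%: 100/100/100; [60%, 70%): 90/80/75; <60%: 85/80/70 percent for
fast/medium/slow; lower band edges inclusive). Reference pools for
fast/slow are the provinces within +5/−5 percentage points of the
target's 2015 level, excluding those with smaller/larger 1995–2015
increases; the pooled series are logit-transformed with the *target's* b
and stacked into one OLS for c, and d is re-anchored so the curve passes
exactly through the target's 2015 observation. An empty pool falls back
to the own-history fit (logged). A declining fitted pace (c ≤ 0) is an
error: the logistic model does not represent de-urbanization. Default
SSP mapping: SSP1/SSP5 fast, SSP2 medium, SSP3 slow, SSP4 fast in
high-income provinces and slow elsewhere.

## Downscaling

The base weight grid zeroes water pixels and adds two ancillary terms —
inverse road distance and inverse distance to the provincial
population-weighted centroid — each min–max rescaled into
[1.0e-5, 1.1e-5]. The terms are ~5 orders of magnitude below the
population signal, so they perturb allocations negligibly while making
non-water values pairwise distinct, which the mask sort requires. Per
coarse cell, round-half-up(urban fraction × pixels) pixels are urban,
highest previous-year value first; water pixels are never selected and
the count caps at the cell's land pixels; residual ties break on flat
pixel order. Allocation is proportional-to-previous within
province ∩ mask strata, which guarantees per-province mass conservation
(checked to 1e-6 persons every year). A province with urban population
but no urban pixels spreads it uniformly over its top 1% of land pixels
(warned). Urban fractions between epochs interpolate linearly. With
constant totals and fractions the recursion reaches a fixed point after
one step, since allocation proportional to itself is idempotent.

## Validation metrics

PE = (P−A)/A × 100 (positive = overestimate), APE = |PE|. Grid
comparisons report RMSE, %RMSE = RMSE/mean(actual) × 100, MAE, and MAD
defined as the median absolute deviation of the errors from their median
(the mean-deviation alternative duplicates MAE and was rejected). Zones
with no pixels are excluded with a warning; cells with zero reference are
excluded from cell-by-cell comparisons.

## Synthetic world

The generator supplies every pipeline input with known ground truth:

- **Population** (default 5 provinces, 2–20M people each): a
  survival-shaped age pyramid with mild cohort growth and jitter;
  education shares respect stage entry ages exactly.
- **Fertility**: a unimodal schedule over ages 15–49 (gamma-like shape
  peaking near age 27) with education multipliers 1.3 → 0.7, scaled so
  each province's implied TFR equals its ground-truth draw
  (U(1.3, 1.9)) to 1e-9.
- **Mortality**: a Gompertz–Makeham hazard with an infant term,
  per-sex senescence coefficients, scaled so each province × sex life
  table hits the ground-truth LE (males U(70, 77), female advantage
  U(3, 6) years) to 1e-6.
- **Migration**: income-category base rates (high +0.6%, medium −0.2%,
  low −0.5%) with a young-adult age profile.
- **Urbanization histories** lie exactly on logistic curves with
  b ∈ U(0.70, 0.95), c ∈ U(0.04, 0.09), d ∈ U(8, 30) (noise optional and
  bounded).
- **Raster world** (default 120 × 120 fine pixels, coarse factor 12):
  Voronoi provinces around random seeds, a smoothed-noise water blob
  (cleared where it would drown a province), a continuous log-normal
  population field peaked at province seeds (pairwise-distinct values
  almost surely), synthetic road lines with a distance transform, and
  coarse urban fractions increasing across epochs 2010/2050/2100.

All randomness derives from a single config seed via independent named
streams; identical configs give bit-identical outputs.

**What the synthetic world does not emulate:** real census heaping and
undercount, education-differential mortality, age-varying sex ratios,
provincial TFR heterogeneity driven by policy, coastline/road geometry,
or the empirical autocorrelation of population rasters. Passing tests
establish the correctness of the mechanics (calibration, recursion,
conservation, recovery), not the realism of any particular national
projection.

## Problem sizes and determinism

Default test and pipeline sizes — 3–5 provinces, 120 × 120 rasters,
91-year horizon — were chosen so a full century run completes in about a
second while still exercising every branch (multiple income categories,
water, coarse-cell heterogeneity). The engine itself is seed-free given
its inputs; reruns are bit-identical, and GeoTIFF payload checksums are
stable across runs.

## Known limitations

- Mortality has no education gradient (the census-style inputs carry
  province × sex × age only), though the state space would admit one.
- The TFR target is national; provincial targets would need one scalar
  per province and a provincial TFR path.
- Probabilistic (stochastic) projection intervals, household structure
  and sub-provincial administrative projection are out of scope.
- The urbanization model cannot represent declining urbanization, and
  policy feedbacks (e.g. relaxation of megacity population ceilings) are
  not modelled.
- GeoTIFFs carry WGS84 georeferencing tags (pixel scale, tiepoint, EPSG
  geokey) written directly; they are readable by GDAL-based tools but the
  writer does not support projected CRSs or compression.
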