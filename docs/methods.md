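# Methods

## Census model and units

A site census comprises one 10 × 1 m photo-transect analysed by point
counts (10–13 images, 75 points per image), two 30 × 4 m parrotfish belt
transects (seven bioeroding species, 15-mm fork-length bins labelled by
lower edge, closed-open, initial/terminal life phases), and urchin counts
(four species, 20-mm test-size bins) along the benthic transect. Percent
cover is stored internally as fractions and rendered as percent only at I/O
edges, which prevents double-scaling bugs. Production and bioerosion are in
kg CaCO₃ m⁻² y⁻¹, skeletal densities in kg m⁻³, accretion in mm y⁻¹,
elevation in m; conversions happen only at the documented boundaries
(g → kg in the grazer terms, mm → m in elevation projections).

## Carbonate budget

Gross production G = Σ cover × calcification × rugosity. The rugosity
multiplier (≥ 1; 3.3309 for *A. palmata*, giving an effective
36.24 kg m⁻² y⁻¹ at 100 % cover) corrects planar cover to
three-dimensional colony surface; coralline algae take a multiplier of 1.
Bioerosion components are stored as positive magnitudes and subtracted:
net = G − (parrotfish + urchin + macro + micro), asserted to 1e-12.

Framework density is the cover-weighted mean of coral skeletal densities;
net-erosional sites use the regional default 1670 kg m⁻³ (their accretion
rate describes the erosion of existing, mixed framework, not the standing
assemblage). Only net-positive sites receive the sediment/void credit
A = F × (1 + sed/frame + void/frame) with sed/void/frame = 33/18/49 % of
core linear depth — eroding framework earns no credit, so A = F there.
Under the defaults the positive-branch ratio A/F is exactly 100/49.

"Available substratum" for the two endolithic terms is ambiguous in common
usage: macrobioerosion acts on dead-coral cover by definition, and by
default microbioerosion uses the same fraction; `site_budget` takes a
`micro_substrate` override for analyses that count pavement or other
consolidated substrate as micro-available.

Elevation projections multiply a constant site accretion rate by the years
elapsed from the 2016 survey baseline (84 y to 2100). Zonal bathymetry
adjustment adds each (sector × habitat) mean elevation change to labelled
grid cells; grids are ESRI ASCII text rasters, elevation positive-up,
nodata propagated untouched.

## Rate tables as configuration

The operative constants — *A. palmata* calcification 10.88 with rugosity
3.3309, default density 1670 kg m⁻³, urchin reingestion 0.57, macro 0.4 and
micro 0.27 kg m⁻² y⁻¹, core composition 33/18/49 — are defaults that YAML
config can override. The per-species parrotfish table and the urchin
size→rate relationship come from licensed methodology spreadsheets that are
not redistributable, so the package ships structural placeholders: the
parrotfish table covers all 7 species × 15-mm bins (105–600 mm) × 2 phases
with an allometric length³ dummy calibrated so a large terminal-phase
excavator erodes ~200 kg y⁻¹ (the magnitude field studies report), and the
urchin relationship is a configurable power law a·size^b (g ind⁻¹ y⁻¹)
with a hard domain check. Tests never anchor on placeholder values.

## Growth assays

Dry skeletal mass follows Archimedes: m_dry = m_buoyant/(1 − ρ_sw/ρ_sk)
with defaults ρ_sw = 1.023, ρ_sk = 2.93 g cm⁻³ (standard buoyant-weight
practice; both overridable). The planar footprint is the caliper ellipse
π/4 · d_max · d_min. Calcification = Δ dry mass / normalising area / Δt;
the normalising area defaults to the interval mean (config: start/mean/end)
because mass accrues continuously over a growing footprint. Record times
may be dates (converted at 365.25 d y⁻¹) or decimal years. Colonies with
complete mortality are flagged and excluded from rate summaries; partial
mortality (negative extension) is legitimate data. Species summaries are
exposed at both colony and station level since either averaging could
underlie a reported species mean.

## Restoration projection

The cohort model is deliberately minimal: one outplanting cohort
established 2030 (the 2020–2030 window is collapsed to its endpoint, after
which the first modelled decade 2030–2040 includes growth and mortality),
isometric planar growth of 196.21 cm² y⁻¹ per colony starting from zero
area (including the ~28 cm² branch-tip footprint would shift the
decade-end covers away from their closed-form values; it is negligible
against ≥ 2000 cm² colonies), no sexual recruitment, no colony overlap,
containment in the 166,407 m² reef-crest habitat. Decadal survival composes
3 % colony survival with 55 % fragmentation re-establishment = 58 %,
rounded to 0.60; the increasing/decreasing-impact schedules multiply
*survival* by 0.95/1.05 per decade, which reproduces all four published
endpoints (44 % and 80 % final-decade survival; 20–56 % mortality range) —
multiplying mortality instead does not, so the survival-multiplier reading
is adopted and asserted. Cover is linear in N by construction; a
per-colony binomial Monte-Carlo oracle validates the deterministic model.

Restored budgets add ΔC × 29.07 kg m⁻² y⁻¹ (the measured planar rate,
deliberately *without* rugosity correction — conservative relative to the
census-table 36.24), recompute framework density with the updated covers,
and leave grazing bioerosion unchanged; a flag lets added coral displace
dead substratum and shrink the endolithic terms proportionally. ΔC is
capped at 0.30, an ecological-limit convention, and live-coral cover + ΔC
may not exceed 100 %.

The historic-baseline offset quantifies processes the budget omits
(physical erosion, dissolution): the gap between a budget-chain accretion
potential at the historic 62 % *A. palmata* cover and the maximum
Holocene-recorded accretion (13.4 mm y⁻¹). The operative default offset is
the published 3.08 mm y⁻¹ constant; the recomputation is exposed
separately because its input rate is itself uncertain. Keep-pace margins
are boundary-inclusive (margin ≥ 0 keeps pace). The shipped five-scenario
sea-level table anchors only the Low 2100 rise (0.36 m relative to 2016);
the rest are illustrative monotone defaults meant to be replaced by a
station-specific table.

## TWL post-processing

TWL tables are an input contract produced by an external hydrodynamic
model; forcing values (wave heights, periods, surge, datum) ride along as
metadata only. Interpolation is piecewise-linear and exact at nodes, with
hard bounds at the tabulated offsets (+0.0 to +2.0 m): out-of-range
requests error rather than extrapolate, because reef TWL response is
strongly nonlinear outside the simulated envelope and the tables contain
no shallower-than-present configurations. Elevation gains are applied per
sector. Alongshore summaries use SD/√n over shoreline points; restoration
runs combine SE_twl and SE_elev by root-sum-square, so the combined SE can
never fall below either component. Mean reductions are computed per point
and then averaged (the per-sector-mean alternative is a one-line groupby
the caller can do on the returned table).

## Synthetic data

The generators emulate the sampling designs — multinomial point counts per
image over a fixed category simplex, Poisson grazer counts per transect,
linear growth with Gaussian measurement noise and whole-colony mortality,
and per-point TWLs linear and monotone in the sea-level offset — threaded
through one explicit `numpy.random.Generator` (seed ⇒ byte-identical
files). Default census parameters depict a degraded Caribbean fore reef:
~7 % live coral, 35 % dead framework, and grazer densities that put total
bioerosion near 4 kg m⁻² y⁻¹, so default synthetic budgets are
net-erosional with accretion potential around −1.6 mm y⁻¹ — the regime the
pipeline is built to analyse. Growth truth rates default to the measured
*A. palmata* means (29.07 kg m⁻² y⁻¹, 6.99 cm y⁻¹, 196.21 cm² y⁻¹); TWL
defaults use 145 northern / 71 southern shoreline points.

An `exact` census mode replaces draws with expectations (largest-remainder
apportionment of cover × points; intensities as counts), enabling
machine-precision comparisons against closed-form budget oracles; it
requires cover × points-per-image integral and integer intensities, and
refuses otherwise rather than silently approximating.

What the generators do **not** emulate: spatial autocorrelation between
neighbouring sites, observer mis-identification, size-structured grazer
demography, storm-pulse mortality, or hydrodynamic realism in TWLs.
Passing tests therefore demonstrate the correctness of the accounting and
projection machinery on data with the right sampling structure and
magnitudes — not the field accuracy of any particular rate table.

## Numerical choices and degenerate inputs

Budget identity asserted to 1e-12; cover sums to 1 ± 1e-9. Zero total
points, zero coral cover with positive net production, empty aggregation
groups, non-positive measurement intervals, dead-endpoint calcification,
and out-of-domain urchin sizes all raise typed errors naming the offending
record. Single-site groups report SE = 0 with an explicit `se_defined`
flag rather than NaN. Grid adjustment requires congruent shapes and a
delta for every non-`none` zone label. The sediment/void/frame percentages
must sum to exactly 100.

## Problem sizes

Test and script workloads use the native study dimensions where they are
cheap — 54-site censuses, 30-colony assays, 216-point TWL tables — and 200
Monte-Carlo replicates of a 10,000-colony cohort for the stochastic
population cross-check, which bounds sampling error well below the
reported precision.

## Known limitations

Chemical dissolution and storm physical erosion are not explicit processes
(the historic offset is their only proxy). The cohort model has no size
structure, recruitment, or density dependence, so long-horizon covers are
scenario arithmetic, not forecasts. Placeholder grazer rates make default
absolute budgets illustrative until a real rate table is supplied. ESRI
ASCII is the only grid dialect. TWL behaviour outside the tabulated
sea-level envelope is undefined by design.
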