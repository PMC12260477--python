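# Methods

This note documents the models, conventions and numerical choices behind
`habconn`, in the order the pipeline runs.

## Synthetic landscapes

The generators exist so that every downstream stage can be exercised and
validated without geodata.

**Habitat rasters.** A neutral landscape model with a single
autocorrelation knob: standard-normal white noise is smoothed with a
Gaussian filter of radius `clustering` (in cells, wrap-around boundaries),
and the top `round(p · n_cells)` cells become habitat. Rank thresholding —
rather than independent Bernoulli draws — pins the realized habitat
proportion to within one cell of the request, which matters because the
scenario filters respond sharply to habitat fractions. Ties in the
smoothed field break by row-major position, so outputs are bit-identical
for a given spec and seed. Defaults follow the study design the package
emulates: 4.5 km cells (2.5 arc-minute climate grids near the equator,
20.25 km² per cell), ~35% habitat, moderate clustering.

**Land cover** uses the same smoothed-noise ranking to carve the grid into
classes with exact cell counts (largest-remainder rounding); class codes
are 1 = forest, 2 = savanna, 3 = anthropic. **Suitability surfaces** are
maxima of Gaussian kernels at random centers (bandwidth one-eighth of the
grid diagonal), clamped to [0, 1]. **Response curves** sample the
continuous one-breakpoint model `y = β₀ + β₁x + (β_r − β₁)(x − ψ)₊ + ε`
with i.i.d. Gaussian noise.

What the generators do *not* emulate: real land-cover spatial structure
(roads, rivers, deforestation fronts), anisotropy, the correlation between
suitability and land cover, and observation error in occurrence data.
Passing tests therefore demonstrate the correctness of the computations and
the qualitative behaviors (monotone IIC erosion, breakpoint recovery), not
calibration to any real landscape.

## Habitat mapping

Distribution-model fitting is out of scope; the module starts from model
scores or binary maps. The presence/absence threshold is chosen from the
*observed* score values (sensitivity and specificity are step functions, so
optima occur at data points), minimizing |sensitivity − specificity|; the
TSS-maximizing criterion (max sens + spec) is available as an option since
the balance criterion admits both readings. Ties break toward the lower
threshold, and a cell is predicted present when score ≥ threshold — both
conventions must be fixed for reproducibility. Models pass the performance
gate when AUC ≥ 0.7 and TSS ≥ 0.7; the ensemble is the cell-wise mean of
passing models only, and zero passing models is an error rather than a
silent fallback. Available habitat is predicted presence intersected with
the guild's admissible land-cover classes (forest → forest, savanna →
savanna, both → union). Nodata propagates and is excluded from all counts.

## Landscape sampling

The region is tiled with equal-area pointy-top hexagons (default 1200 km²,
side ≈ 21.49 km — a standard local-landscape extent for amphibians),
anchored at the bounding-box lower-left corner; ids run row-major, making
the grid deterministic. Hexagons straddling the region edge are kept whole,
with habitat fractions computed over in-region cells only, so edge
landscapes can legitimately span 1–100% habitat.

Raster cells are assigned to hexagons by cell-center containment (boundary
ties to the smaller id): an exact partition with no fractional cells. At
4.5 km cells against 21.5 km hexagons the discretization error in the
fraction is small. A habitat-amount scenario with threshold *t* deletes all
habitat inside hexagons whose fraction is below *t* (the "at least" rule,
≥) *before* patch extraction — deletion can split patches, which is the
intended reading of removing a landscape. Habitat in retained hexagons is
untouched, so habitat area and IIC are non-increasing in *t*.

## Patch graphs

Patches are connected components of habitat cells, 8-connectivity by
default (diagonal contact at multi-km cell sizes is contiguous habitat;
4-connectivity is an option), labeled deterministically in row-major order
of first cells.

Inter-patch distance defaults to the *edge approximation*
`max(0, min center-to-center distance − cell size)`: raster centers
overestimate gap widths by about one cell, and connectivity practice
measures edge-to-edge distances. The plain centroid distance is retained
for sensitivity checks. This matters at coarse resolutions: with 4.5 km
cells, a 1 km dispersal threshold can never bridge even a one-cell gap
under raw center distances; the edge approximation mitigates (0-cell gaps
— diagonal contacts under 4-connectivity — and sub-cell configurations
connect) but cannot fully reproduce links derived from polygonized
vector data.

Two patches are linked when their distance is within the species' dispersal
distance (default 1 km, a conservative generic value for herpetofauna;
sensitivity analyses use 0.5/1.0/1.5 km). Link counts `nl_ij` come from
per-node BFS over the unweighted edge set; unreachable pairs carry an
explicit infinity and contribute zero to IIC (the limit of 1/(1+nl)).
`A_L` defaults to the full analysis-region area and must be held fixed
across scenarios for a species — IIC values are only comparable against a
common denominator.

CONEFOR-style files are one `id<TAB>area` line per node and one
`id1<TAB>id2<TAB>distance` line per linked pair (partial connection file:
absent pairs are unconnected); reading accepts tab or space delimiters and
reports malformed lines, duplicate ids and unknown ids with line numbers.
Write→read round-trips are exact.

## Connectivity indices

IIC sums `a_i·a_j/(1 + nl_ij)` over *ordered* pairs including `i = j`
(each patch contributes its squared area), divided by `A_L²` — the
double-sum form with independent full-range indices. dIIC% removes a node,
recomputes link counts among survivors, and reports the relative drop. The
decomposition computes dIICintra (`a_k²` term), dIICflux (the `2·a_k·a_j/
(1+nl_kj)` cross terms) and dIICconnector *directly* from the link counts
before and after removal — never as a residual — and the test suite checks
both that connector ≥ 0 and that the three parts sum to dIIC to 1e-9.
Areas are in km², `A_L²` in km⁴, with no internal rescaling; the
double-precision identity holds comfortably at these magnitudes.

## Threshold regression

The segmented model `y = β₀ + β₁x + β₂(x − ψ)₊` is fitted by iterative
linearization: at working ψ, regress y on {1, x, (x−ψ)₊, −I(x>ψ)} and
update ψ by γ̂/β̂₂ (γ̂ the gap coefficient, β̂₂ the slope change),
converging when |γ̂| < 1e-8·sd(y) (max 50 iterations). The profiled RSS is
only piecewise smooth in ψ — with few distinct x values the iteration can
stall in a local optimum — so the fit is multi-start: the iteration from
ψ₀ (default: the x-median) always competes against a restart from the best
of 19 interior x-quantiles, and the candidate with the lowest profiled RSS
wins. The procedure is deterministic given (x, y, ψ₀). If no interior
breakpoint improves on the plain line, the fit reports `converged=False`
with the linear coefficients rather than raising.

AIC uses the Gaussian-likelihood convention
`n·ln(2π·RSS/n) + n + 2·(k+1)` with k = 2 (linear) or 4 (segmented,
counting ψ) regression coefficients plus one variance; ΔAIC =
AIC(segmented) − AIC(linear) is convention-invariant for this same-form
comparison. Note that because ψ is *searched*, the null distribution of
ΔAIC is not centered at +4: spurious improvements make ΔAIC ≈ 0 typical on
no-break data, which is why the breakpoint's significance is assessed by a
dedicated test rather than by AIC alone.

The breakpoint CI is delta-method by default — SE(ψ̂) = SE(γ̂)/|β̂₂| from
the final linearization, with a t quantile at n − 4 df — with a residual
bootstrap (explicit seed, percentile interval) as an option. The
significance test is a parametric bootstrap of H₀ (no slope change):
simulate from the fitted linear model by resampling its centered
residuals, refit both models, and compare RSS improvements; p = (1 + #{sim
≥ obs})/(B + 1). Constant y returns p = 1 by convention. In simulation at
the study design (seven scenarios × eight series, 5% noise), the delta CI
covers the planted breakpoint ≈ 94% of the time at the 95% level, and the
test's type-I error sits at ≈ 5%.

Habitat amounts are reported in percent (the table/CLI layer converts
fractions before fitting); `fit_segmented` itself is scale-agnostic and
returns ψ in the units of its x input.

## Priority mapping

Each habitat cell inherits its patch's dIIC%, giving a per-species
importance surface. Critical landscapes follow two rules, deliberately
decoupled from the regression estimate: the forest-guild rule keeps
hexagons with at least 30% habitat (the operational threshold), and the
savanna-guild rule keeps every hexagon with any habitat, because those
species' landscapes never reach the threshold. Per-species critical-area
rasters are stacked by cell-wise summation into an overlap (richness) map.
Protected-area coverage is the percentage of a species' habitat cells
inside a binary protected mask; masks are produced from polygons by the
same cell-center rasterization used everywhere else.

## Problem sizes and determinism

The test suite and the reproduction script run on 40×40 to 100×100 cell
grids (180–450 km extents at 4.5 km cells), random graphs up to 40–50
nodes for oracle comparisons, and 200–500 Monte-Carlo replicates for the
regression calibration — sizes at which every documented behavior is
already stable and the whole suite runs in minutes. All stochastic steps
take explicit seeds; no global random state is used anywhere.

## Known limitations

- Planar km coordinates only; no geographic CRS or spherical hexagons.
- Binary Euclidean-threshold links; no least-cost paths, resistance
  surfaces, or the probabilistic PC index.
- Exactly one breakpoint; no multi-breakpoint or smooth (GAM)
  alternatives.
- The delta-method CI leans on asymptotics; with very few distinct x
  values the bootstrap CI option is the safer choice.
- The bootstrap significance test is one reasonable choice among several
  for segmented fits; different test constructions give different p-values
  on the same data.
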