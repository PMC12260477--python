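# habconn

Graph-theoretic landscape connectivity under habitat loss: from habitat
rasters to patch graphs, the Integral Index of Connectivity (IIC), scenario
sweeps over minimum habitat amount, and segmented-regression detection of
the habitat-amount threshold at which regional connectivity erodes.

## The problem

The extinction-threshold hypothesis predicts that below a critical
proportion of habitat in a landscape (classically around 30%), connectivity
collapses nonlinearly and populations become isolated. `habconn` implements
the analysis pipeline used to test this prediction with *functional
connectivity* as the response: landscapes are sampled as equal-area
hexagons, habitat-poor landscapes are progressively excluded, and the
resulting erosion of a regional connectivity index is modeled with a
piecewise regression whose breakpoint estimates the threshold. It is aimed
at landscape ecologists and conservation planners working with fragmented
systems (the motivating case: forest and montane-savanna herpetofauna in
anthropogenic Amazonian landscapes).

## The model

Habitat patches are nodes of a graph, weighted by area `a_i` (km²); two
patches are linked when their inter-patch distance is within the species'
dispersal distance. With `nl_ij` the number of links on the shortest
topological path between patches *i* and *j* (pairs in different components
contribute nothing) and `A_L` the total landscape area (habitat plus
matrix),

    IIC = [ Σ_i Σ_j  a_i · a_j / (1 + nl_ij) ] / A_L²

over all ordered pairs including *i = j*. IIC ∈ (0, 1]; higher is more
connected. A patch's importance is the relative drop on removal,

    dIIC% = 100 · (IIC − IIC_without) / IIC
          = dIICintra + dIICflux + dIICconnector,

splitting additively into the patch's own habitat, its direct connections,
and its stepping-stone role on paths between other patches.

The threshold is estimated by the one-breakpoint segmented model
`y = β₀ + β₁·x + β₂·(x − ψ)₊` fitted by iterative linearization, compared
to the plain line via AIC, with a delta-method (or bootstrap) confidence
interval for ψ and a parametric-bootstrap test of the slope change.

A synthetic-landscape module (neutral landscape model: smoothed noise with
exact-count thresholding) replaces the study's geodata so the entire
pipeline runs, and is tested, without downloads.

## Worked example

```python
import numpy as np
from shapely.geometry import box
from habconn import *

# 1. simulate a clustered binary habitat landscape (180 x 180 km, 4.5 km cells)
spec = SimulationSpec(n_rows=40, n_cols=40, cell_size_km=4.5,
                      habitat_proportion=0.35, clustering=2.5, seed=7)
habitat = gen_habitat_raster(spec)

# 2. tessellate into 1200 km^2 hexagonal landscape samples
region = box(0, 0, 180, 180)
grid = habitat_fractions(build_hex_grid(region, cell_area_km2=1200.0), habitat)

# 3. IIC under progressive habitat-amount scenarios (common A_L)
profile = SpeciesProfile("generic_herp", guild="both", dispersal_distance_km=1.0)
A_L = 40 * 40 * 4.5**2
sweep = scenario_sweep(habitat, grid, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7],
                       profile, A_L)
print(sweep.to_string(index=False))
```

```
     species  min_fraction  n_patches  habitat_area_km2      iic
generic_herp           0.1          7          11056.50 0.054514
generic_herp           0.2          6           9720.00 0.046812
generic_herp           0.3          5           9558.00 0.045015
generic_herp           0.4          5           8525.25 0.038270
generic_herp           0.5          5           7472.25 0.027017
generic_herp           0.6          5           7472.25 0.027017
generic_herp           0.7          5           7229.25 0.024720
```

IIC declines monotonically as habitat-poor landscape samples are excluded:
even landscapes holding little habitat contribute to regional connectivity.
Fitting the breakpoint model to simulated multi-species series (seven
scenarios × eight series, breakpoint planted at 32% habitat, 5% noise):

```python
x = np.sort(np.tile(np.arange(10.0, 75.0, 10.0), 8))
clean = 10 - 0.05 * x - 0.15 * np.maximum(0.0, x - 32.0)
y = clean + np.random.default_rng(1).normal(0, 0.05 * np.ptp(clean), x.size)
fit = fit_segmented(x, y)
lo, hi = breakpoint_ci(fit, level=0.95)
p = breakpoint_test(x, y, fit, n_sim=199, seed=1)
print(f"breakpoint = {fit.psi:.1f}% habitat (95% CI {lo:.1f}-{hi:.1f}%)")
print(f"R2 = {fit.r2:.2f}, dAIC = {fit.delta_aic:.2f}, p = {p:.3f}")
```

```
breakpoint = 30.5% habitat (95% CI 27.6-33.4%)
R2 = 0.99, dAIC = -73.86, p = 0.005
```

The estimated breakpoint recovers the planted 32% threshold within noise;
the negative ΔAIC and small p say the two-segment model genuinely beats a
single line.

A command-line interface mirrors the library
(`habconn simulate|habitat|sample|graph|connectivity|threshold|priority`);
all rasters are plain-text ASCII grids and all tables tab-separated text,
including CONEFOR-style node/connection files for interoperability.

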