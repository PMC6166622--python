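# Methods

## Scope and model structure

`larvanet` couples an individual-based Lagrangian transport model to a
connectivity/network analysis layer. The pipeline is deliberately
modular: `forcing` fabricates the physical world, `hydro` defines the
current-field contract, `biology` the life-history rules, `transport`
the particle stepping, and `connectivity`/`netgraph` the derived
statistics. Every stage runs on synthetic forcing, so the full system
is testable on a laptop with no ocean-model output or habitat GIS.

## Physical world

**Grid.** Regular lon/lat cells (default 0.01°, about 1.1 km) with
velocities at cell centers (an Arakawa-A-like arrangement — the
simplest contract for bilinear interpolation). Longitudes use the
[0, 360) °E convention. The vertical axis is layered with thickness
non-decreasing downward; the default desk-scale scheme has 10 layers
(5, 10, 15, 25, 50, 75, 100, 150, 300, 510 m thick) and a 50-layer
scheme growing geometrically from a 5-m surface layer to a 510-m
bottom layer is available via `layer_edges_50()`.

**Currents.** Daily (u, v) snapshots per layer, zero on land, held
constant within each day (no temporal interpolation — the stepper
re-reads the day's field at each 2-h step). Analytic flow components
(uniform drift, solid-body/Rankine gyre, alongshore jet decaying
offshore, composites) are identical across layers by default; a seeded
Gaussian day-to-day perturbation is optional. Steady fields are stored
as broadcast views, so memory stays O(one field) regardless of series
length. Files round-trip through NetCDF (dims time/layer/lat/lon,
variables u, v, mask, bathymetry) via xarray's scipy backend.

**Islands and bathymetry.** Circular/elliptical islands; depth grows
linearly with distance from the nearest shoreline (0.05 m/m by
default, 2 m at the coast, capped at 1500 m), so depth along any
offshore ray is non-decreasing. Land components are labeled and each
island named; exactly one island is focal. Neighbor islands are
settle-only "exogenous sinks": their sites receive larvae but never
spawn, and they are excluded from island-scale indices.

**Habitat sites.** Sites sit evenly spaced in bearing around each
island, in water within 1 km of the shoreline, and carry one of six
habitat types (reef, sand, rock, rubble, pavement, intertidal). A
species spawns from and settles to only sites whose habitat is in its
habitat set. Contiguous runs of same-habitat sites form regions of
2–11 sites; run lengths are drawn uniformly within those bounds and
habitats are apportioned to regions by largest remainder against the
requested mix, then shuffled — this guarantees every requested habitat
type is represented whenever there are at least as many regions as
types, so no species is silently excluded from a run. Coasts are
N/E/S/W bearing quadrants from the island center. Site generation is
bit-reproducible for a fixed seed.

## Biology

**Spawning.** Events occur at every suitable site on every eligible
day: day-of-year inside the species' window(s); for lunar spawners
only when the phase is within half a day of the target (phase from
simple synodic arithmetic — reference new moon 2000-01-06 18:14 UTC,
period 29.530588853 d; day-level accuracy is all a daily decision
needs); clock-window spawners draw the hour uniformly in their window,
all others release at noon (the sub-daily choice is irrelevant under
daily-constant forcing). Fecundity is equal across sites and events.
The per-species budget (default 2,000 larvae, a desk-scale stand-in
for the saturation-scale releases of ~10⁶ recorded in the reference
column) is split as evenly as possible over events and matches
exactly.

**PLD and depth.** PLD is drawn once per larva, uniform between the
species bounds. Broadcast-spawned fish drift 24 h as buoyant eggs
uniformly in 0–5 m — the buoyant limit, since only "passive buoyant"
is known — then draw a pelagic depth, either uniform in the species
band or from a genus-level piecewise-constant depth profile. The three
packaged profiles (trevally, parrotfish, goatfish) are *synthetic
stand-ins* shaped like ichthyoplankton survey profiles
(near-surface-weighted for trevally/parrotfish, mid-depth mode for
goatfish); they exercise the discrete-distribution machinery but are
not digitized data. Depth is held fixed for the rest of the pelagic
phase; only the layer assignment changes with bathymetry.

**Mortality.** Half of larvae survive to half the maximum PLD.
Survival over dt is 2^(−dt/half-life) with half-life = PLD_max/2,
applied continuously as an independent Bernoulli per 2-h step (whether
the original removal was continuous or end-of-PLD is ambiguous;
continuous is the natural reading of a half-life). Multiplicativity
p(a)·p(b) = p(a+b) makes the discretization exact at any step size.

## Transport rules

Step order: advect/diffuse → land check → layer clamp → mortality →
age increment → settlement test. Displacements are u·dt plus a
Gaussian kick of per-axis std √(2·D·dt) (53.67 m at the defaults
D = 0.2 m²/s, dt = 7200 s), converted to degrees on a sphere of
R = 6,378,137 m — the same radius as the Haversine distances, so
transport and connectivity geometry agree. A candidate position in a
land cell is rejected (the larva waits; beaching behavior is otherwise
unspecified, and rejection guarantees larvae are never stranded
inland). Leaving the grid terminates the trajectory (`left_domain`),
mirroring the discarding of trajectories that enter a boundary zone.
Settlement is tested once, at the assigned PLD, to the nearest
suitable site within the 1-km radius; `continuous_competency=True`
switches to testing every step from the minimum PLD (sensitivity
alternative — the primary wording says larvae are removed *at* their
PLD if outside a settlement zone).

**Randomness.** One master seed; each species gets an independent
`SeedSequence([seed, crc32(name)])` stream driving a fixed-order
vectorized cohort, so runs are byte-identical for a given seed and
config. (A per-particle hash substream was considered; a per-species
stream achieves the same reproducibility because execution order
within a species run is deterministic.)

## Analysis conventions

* Undefined ratios (0/0) propagate as NaN, never 0 — "no settlers" is
  missing data, not a perfect sink.
* Exports/imports for the source–sink index are raw settler counts to
  or from *other* focal-island sites; self-settlement is reported
  separately as local retention, and exogenous islands are excluded.
* Dispersal kernels use fixed 5-km histogram bins (deterministic and
  test-friendly; no smoother).
* Graph edges require dispersal proportion ≥ 0.1% and are never
  self-loops. Cut nodes use weak connectivity. Weighted betweenness
  uses edge cost −log(proportion): multiplicative path probability
  becomes additive cost, so the shortest path is the most probable
  dispersal route. The reciprocal cost 1/proportion is implemented as
  an alternative since the weighting convention is not standardized;
  −log is the default. Ties among equal-cost paths split counts
  fractionally.
* "Barycentric" horizontal interpolation is implemented as bilinear on
  the regular grid; the two agree at nodes, on edges, and for constant
  fields, and the difference elsewhere (the diagonal choice of the
  triangulation) is below test tolerances. Land corners get weight 0
  with the remaining weights renormalized, which avoids artificial
  onshore drag at wet/dry boundaries.

## Demonstration experiments (`scenarios`)

* `survival_experiment` — mortality on, settlement off, still water,
  10,000 octopus larvae: the alive fraction at half the maximum PLD
  measures the stepper's Bernoulli thinning against its 0.5 anchor.
* `directional_ssi_run` — steady 0.02 m/s eastward drift past an
  all-intertidal ring, limpet life history (PLD 3–18 d spreads
  settlement along the downstream path). Upstream regions can only
  export and the lee side mostly imports, so the source–sink index
  must be positive at the westernmost defined region and negative at
  the easternmost.
* `retention_kernel_run` — quiescent ocean (pure diffusion) around a
  ring carrying all six habitats, five species spanning the disperser
  classes. Alongshore spread at settlement scales as √(2·D·PLD), so
  mean settled distance must rank short < medium < long while
  settlement success ranks the other way; the cross-species
  correlations (PLD vs settlement, log-PLD vs distance) take the
  corresponding signs. The retention-dominated regime is chosen
  deliberately: it isolates the PLD–diffusion scaling from circulation
  details and keeps the class ordering a property of the model rather
  than of a particular flow field.

## What the synthetic world does and does not show

The generator reproduces the *structure* the analysis assumes — daily
layered currents, an island with shoreline habitat pooled into
regions, exogenous neighbor sinks — not any real circulation: there is
no mesoscale turbulence spectrum, tide, wind, or seasonal cycle, and
the desk-scale domain (~100 km) cannot reproduce archipelago-scale
numbers such as real settlement fractions, 25–90 km class-mean
dispersal distances, or island-to-island exchange fractions. Passing
tests therefore demonstrate that the mechanics (transport physics,
life-history scheduling, index algebra, graph metrics) are correct and
that qualitative signatures (direction of source–sink contrast, PLD
ordering of kernels and settlement, correlation signs) emerge for the
right reasons — not that any site-specific prediction for a real
island is reproduced.

## Problem sizes and numerical choices

Default experiments use a 0.01° grid (~100 × 80 cells), 40–48 sites,
2,000–10,000 larvae per species, and calendars of 26–515 days chosen
so every species' spawning window plus pelagic tail fits the series;
the full acceptance sweep runs in a few minutes on one CPU. Degenerate
inputs are defined explicitly: a depth on a layer boundary assigns
downward; a dry interpolation stencil raises an on-land signal (and
contributes zero velocity inside the vectorized stepper); empty
spawn calendars warn and return no events; a series shorter than a
species' maximum PLD is a configuration error raised before stepping.

## Known limitations

No larval behavior beyond depth preference (no swimming, orientation,
or diel migration), no pre-competency window, no temperature-dependent
PLD, no density-dependent fecundity, no tides or interannual (ENSO)
variability, and no between-island spawning: larvae may settle to
neighbor islands but never arrive from them, so island-scale indices
describe within-island dynamics only.
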