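# Methods

This note documents the models, conventions and design choices behind
`greenequity`, in the order the pipeline runs them.

## Grid conventions

All spatial data share one planar metric CRS; no geodesy exists anywhere in
the package.  Grids are north-up, row-major, 0-based, with cell (r, c)
covering the half-open box `[x₀+c·res, x₀+(c+1)·res) × (y₀−(r+1)·res,
y₀−r·res]`.  A point on an interior vertical edge therefore belongs to the
cell to its right, and on a horizontal edge to the cell below.  Buffer
queries (`cells_within`) count cells whose *centers* lie within the radius
(inclusive): center membership matches raster practice, is unambiguous, and
makes the brute-force oracle trivial.  Bilinear resampling interpolates the
source cell-center lattice at target cell centers and clamps to the nearest
edge/corner value outside the lattice (constant extrapolation) — city
domains are interior crops of larger model domains, so reflected or NaN
edges would be wrong.  The two-pass lerp formulation preserves constant
fields exactly and cannot overshoot the four neighbouring values beyond
float rounding.

## Synthetic cities

The generator emulates the *structure* of real inputs — a 5 m land-cover
raster (tree, grass, water, building, mineral, bare), building points with
population, rectangular statistical zones with count tables and one median
income each, and 3 km + 1 km PM₂.₅ baselines — not any particular city.
Continuous fields are radial: `centre + slope·distance + N(0, sd)`.
Defaults (chosen as plausible European-city magnitudes and then left alone):

| field | centre | slope /m | noise sd |
|---|---|---|---|
| baseline PM₂.₅ (µg m⁻³) | 12.0 (15.5 Paris-like, 10.8 Aarhus-like) | −2·10⁻⁴ | 0.15 |
| tree-canopy probability | 0.08 | +3·10⁻⁵ | 0.02 |
| median income (currency) | 22 000 (Paris-like) / 32 000 (Aarhus-like) | +1.0 / −1.0 | 800 |

The slope *signs* are the planted social geography: `paris_like` has a poor,
dirty, tree-sparse centre; `aarhus_like` a rich, dirty centre.  Both are
recorded in `city.truth` so recovery tests know what to look for.

Buildings are placed uniformly (optionally with a radial density bias via
rejection sampling), populations drawn log-normal(μ=3.0, σ=0.7) — median
≈20, mean ≈26 residents per building, a deliberate mid-rise scale so a few
hundred buildings carry a realistic population.  Zone population is the sum
of its buildings' populations, which makes disaggregation conservation
exact by construction.  Subgroup proportions come from a softmax link on
standardised zone income, `score_s = log(base_s) + β_s·(z + ε)`, with
city-wide base shares (e.g. 86/14 citizen/non-citizen, 7/93
unemployed/employed) and effect sizes β chosen so richer zones are modestly
more employed, more educated and more likely citizens.  Counts stay
fractional — rounding to whole persons would break the conservation
invariant the weighted-mean identities rely on.

Randomness uses one root seed with an independent child stream per field
(land cover, PM₂.₅, income, buildings, populations, subgroups), so changing
one gradient's parameters never perturbs another field's draws, and a fixed
config+seed is reproducible byte-for-byte on disk.

What the generator does *not* emulate: street networks, correlated
micro-structure of land cover, multi-modal income distributions,
within-zone segregation, temporal variation.  Passing tests therefore show
the pipeline's arithmetic and orderings are right under controlled
gradients, not that any real city behaves this way.

## The 3-30 editor

The '3' target is operationalised as ≥2 tree cells (5 m) within 30 m of a
building; the '30' target as ≥30% of a zone's cells under tree canopy or
water.  Grass is *not* counted toward the 30% by default (configurable):
the target is written around tree canopy and blue space, and counting grass
would let treeless lawns satisfy it.  "Neighbourhood" is identified with
the statistical zone, the only operational areal unit available.

The editing order is a design choice the targets themselves do not fix:
buildings in ascending id, candidate cells nearest-first with row-then-
column tie-breaks; then zones in ascending id, converting eligible cells
adjacent to existing canopy first (a contiguity heuristic) with the RNG
seed ordering otherwise-equal candidates.  Any deterministic rule meeting
the postconditions would do; this one is simple and auditable.  Sealed
mineral surface *is* eligible for conversion — dense centres cannot reach
30% any other way — while buildings and water never are.  Infeasibility
(not enough eligible cells) is reported per unit, never raised.  The editor
is monotone (trees only added), idempotent, and minimal in the '3' step
(at most the deficit is converted per building).

## Meta-model chain

`pcPM(w) = c₂w² + c₁w + c₀` (percent) with shipped coefficients Aarhus
`(0, −3.9134, −0.1636)` and Paris `(6.0425, −8.9865, −0.8939)`.  Both are
validated at construction to be ≤0 on a 10⁻³ grid of [0, 1]; the Paris
quadratic's vertex at w = 8.9865/(2·6.0425) ≈ 0.7436 is its minimum, so the
marginal benefit of woodland declines beyond ~74% cover.  The chain is:
woodland fraction per 3 km cell (tree class only — grass is far less
effective at capturing particulates and is excluded), `Δ = pcPM(w)/100 ×`
coarse baseline, bilinear resample of Δ to 1 km, addition to the fine
baseline.  The same coarse baseline multiplies pcPM for both the current
and scenario land cover, and both deltas are applied to the fine surface as
given; the scientifically meaningful quantity is the scenario-minus-current
difference, which the exposure table exposes per subgroup.  A delta that
drives any fine cell to ≤0 µg m⁻³ is an input error and raises.

## Exposure statistics

Disaggregation: `pop(a,u) = count(a,z)/pop(z) × pop(u)` for building u in
zone z — fractional weights throughout.  Exposure per subgroup is
`Σ w·v / Σ w` with PM₂.₅ sampled at the building point from the 1 km
surface (cell value, no interpolation) and tree cover as canopy area within
300 m of the building centroid (the centroid, not the footprint edge, is
the buffer origin; reported in hectares, carried in m²).  Income quintiles:
zones ranked by median income (ties by zone id), cumulative building
population cut at 20/40/60/80% using a midpoint rule, bottom/middle/top
classes inherited by every building in the zone with *total* building
population as the weight.  This single-median treatment produces more
extreme income contrasts than the count-based categories — a property of
the data structure, reproduced deliberately rather than smoothed.  Display
rounding is 2 decimals for concentrations and hectares, 3 for concentration
deltas; machine-readable output keeps full precision.

## Numerical choices and degenerate inputs

Grid nesting and alignment are verified to 10⁻⁹ of a cell; non-nesting
grids raise rather than resample silently.  The zone '30' threshold uses
`ceil(target·n − 10⁻⁹)` cells so exact fractions (30 of 100) are not pushed
over by float error.  Weighted means reject negative weights and raise for
absent subgroups (zero total weight) instead of returning NaN.  Quintile
classification is undefined when all zone incomes are identical and raises.
Concentration GeoTIFFs are written float64 so round trips are lossless;
land cover is uint8 with a fixed class-code table.

## Test scales

The suite exercises the full pipeline at deliberately compact sizes — the
oracle-equivalence city uses 25 zones and 2 000 buildings on a 9 km domain
(1800² land-cover cells); the contract and pattern-recovery sweeps use 20
seeds of 3–6 km cities — sizes at which brute-force oracles (full-raster
enumeration, per-building double loops) remain exact and fast.

## Known limitations

The '300' component of the greening rule (a ≥1 ha green space within
300 m) is out of scope, as are pollutant species other than PM₂.₅,
barrier/dispersion effects of vegetation, sub-annual variation, removal
*quantities* (only concentration change is modelled), health-impact
translation, and intersectional cross-tabulations (e.g. age × income).
Meta-model residual uncertainty is not propagated: predictions are treated
as exact, so subgroup differences smaller than model error should be read
as orderings under the model, not detectable effects.
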