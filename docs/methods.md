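# Methods

This note documents the models, conventions and design choices behind
`landmetrics`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Landscapes and grids

The unit of analysis is a *landscape*: one square window of a regular
tessellation of a categorical raster. Grids are anchored at the raster's
top-left origin; trailing partial rows/columns are dropped, so every
landscape is full-sized and metric values are comparable within an extent.
Windows that are entirely ocean or NoData in *every* year are removed
(coastal windows with any land in any year survive, as do windows of
inland water). Anchoring and the full-window rule are this package's
conventions — there is no canonical standard for how coastal partial
windows should be handled, and padding or keeping partial windows would
mix landscapes of different effective extents into one grid.

Cropping to a region polygon uses cell-center containment (centers exactly
on the boundary are kept), a single documented rule that avoids sliver
ambiguity. Inputs must already be co-registered in an equal-area
projection; the package never reprojects or resamples. Continent labels
are assigned by the polygon covering the landscape centroid, first match
winning on shared boundaries.

## Metric conventions

The six class-level metrics follow the standard FRAGSTATS-lineage
definitions. Four conventions are fixed by default and exposed in
configuration so their influence can be tested:

- **Patch connectivity 8** (queen): diagonal neighbours join a patch.
- **Core neighbourhood 4** (rook): a cell is core when its 4 neighbours
  are same-class; window-border cells are never core, because their
  missing neighbours cannot be verified — the conservative reading of
  "surrounded by cells of the same class". Core-area depth is fixed at
  one cell.
- **TE excludes the window boundary**; faces against water and NoData
  count as edge like any other class contrast.
- **The LSI edge term includes the window boundary**, so a landscape
  entirely covered by one class has LSI exactly 1.

Edge lengths are accumulated as integer face counts and scaled by the
cell size once, so TE is exact and LSI is one float division of two
integers. The LSI denominator is the closed-form minimum polyomino
perimeter (4m, 4m+2 or 4m+4 with m = ⌊√n⌋), verified in the test suite
against exhaustive enumeration of all polyominoes up to n = 9.

When a class is absent, metrics whose value is then logically zero (CA,
NP, TE, TCA, NDCA) are reported as zero; LSI is 0/0 and stays missing.
Missing LSI records are excluded from both numerator and denominator of
any mean. Water-class rows are dropped from the record set (water still
participates in edge and core computations as a neighbouring class).

## Scaling screening

For each metric and class, the mean value over all landscapes of one
extent is regressed on landscape side length L, once linearly and once as
a power law (OLS of log mean on log L; R² reported on the fit's own
scale, i.e. log-log for the power model). A metric is *scale-predictable*
when, for every class, the better of the two fits reaches an R² threshold
(default 0.98) and the fitted direction (sign of slope/exponent) is
identical across classes. Screenings of this kind are traditionally done
by visual inspection of mean-versus-extent curves; the threshold-plus-
direction rule is this package's reproducible proxy for a smooth linear
or power-law relationship, and the threshold is configuration, not dogma.
Ties between equal R² go to the linear model.

On a composition-stationary map (class frequency p independent of
location) the expected CA in a landscape of side L is p·L², so the CA fit
must recover exponent 2 — this is used as an end-to-end validation with
known truth. LSI grows approximately linearly in L for stationary maps:
the edge term scales with L² while the minimum-edge term scales with
√(p)·L, leaving a ratio linear in L up to boundary effects.

## Change analysis

Net change is value(year₁) − value(year₀) per landscape, class and
metric. The nine-category classification crosses sign(ΔCA) with
sign(ΔLSI), applied only to landscapes with CA > 0 in *both* years
(presence is any cell by default; a minimum-cell threshold is accepted in
configuration). "No change" is exact zero for ΔCA — areas are integer
cell counts times a constant, so equal areas subtract to exactly zero —
and |ΔLSI| ≤ 1e-9 relative for LSI, guarding only the final float
division; both tolerances are parameters. Yearly trends and continental
summaries report mean and *sample* (n−1) standard deviation across
landscapes.

## The synthetic generator

The generator emulates the structure the analysis assumes: a persistent,
contiguous, edge-anchored ocean mask; several land classes in spatially
clustered patches; and gradual, spatially coherent yearly transitions.

The initial map is a modified-random-clusters neutral landscape model:

1. Bernoulli marking of land cells with probability
   `cluster_density × 0.407` (the site-percolation threshold for
   8-neighbour connectivity). Scaling by the threshold keeps marking
   subcritical over the entire density range; unscaled marking would
   cross the percolation transition inside the parameter range, where a
   single spanning cluster destroys both composition control and the
   monotone density–aggregation relationship.
2. 8-connected labelling of marked cells into clusters.
3. A fraction `1 − cluster_density` of the unmarked land is filled
   i.i.d. at the target class proportions (speckle, as in classic
   modified-random-clusters generators); the remaining unmarked cells
   attach to their nearest marked cell, giving each cluster a contiguous
   territory. A pure nearest-cell fill was rejected because it makes
   *low*-density maps the most aggregated (few seeds own huge Voronoi
   territories), inverting the intended meaning of the density knob.
4. Territories are assigned to classes largest-first, each to the class
   with the largest remaining quota (quota = target proportion ×
   territory cells). Assigning whole territories rather than bare
   clusters keeps realized composition unbiased; measured mean absolute
   composition error at 200×200 cells is ~0.002.

Yearly change is driven by explicit operators — `expand` (seeded
single-cell accretion onto the class frontier, Eden-style, so growth is
compact), `contract` (boundary-cell removal), `fragment` (removal of
articulation/corridor cells that split a patch, falling back to boundary
cells), and `convert` (relabelling whole smallest patches). Operators can
be confined to a cell window (`region`), which is how designed
experiments keep change inside designated landscapes. Rates are cells per
year (patches per year for `convert`), applied "up to" the rate when
candidates run out. Ocean and NoData cells are never modified. Every
changed cell is appended to a truth log whose replay reproduces each
year exactly; tests verify this, plus cell/ocean conservation and
bit-identical determinism from one seeded stream advanced in a fixed
order (ocean, marking, speckle, then operators by year and list
position).

What the generator does *not* emulate: real geography, class-specific
transition probabilities of any particular dataset, classification
uncertainty, or resolution effects. Passing tests therefore demonstrate
correctness of the *computation* (metrics, tessellation, fits,
classification) under controlled truth, not fidelity of any conclusion
about real land-cover data.

## Problem sizes and numerical choices

The validation studies use sizes chosen to give tight statistics while
remaining quick on a single CPU: the oracle comparison uses 1000 random
12×12 windows with 3–5 classes (every metric compared exactly, no
tolerance); the scaling study uses ten 400×400-cell maps with extents
10/20/40 km (≈2100 landscapes per map); the recovery study uses ten
200-landscape-year series of 100 landscapes of 20×20 cells each, a
designated 25% expanding at 5 cells/landscape/year over 1992–2020. The
20 km landscape size hosts the ~149-cell final patch comfortably
(Eden-growth radius ≈ 7 cells), so confined expansion cannot saturate a
window. Degenerate inputs are defined, not special-cased: absent classes
give zero patches and missing LSI; empty scopes raise; a zero-rate
operator is the identity.

## Known limitations

- LSI's boundary-inclusive edge term is one of two defensible
  conventions; the alternative (boundary excluded) is a configuration
  flag away, and comparisons against other implementations should check
  which convention they use.
- The R²-based predictability rule is a proxy for expert visual
  judgement; near-threshold verdicts deserve inspection of the curves.
- Continental assignment by centroid misattributes landscapes straddling
  a boundary; area-overlap assignment is not implemented.
- The pipeline holds the full raster stack in memory; planetary-scale
  series should be processed per region or per extent.
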