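# Methods

## The model

`dasygrid` implements polygon-binary dasymetric mapping: ancillary polygons
mark land only as *populated* or *unpopulated*, and each source zone's
population is spread at uniform density over its populated part (the target
zone). No per-land-use density weights are estimated — the method's wager is
that with fine source zones (block-scale) and fine ancillary data (parcel
and building scale), the binary mask already captures most of the spatial
signal, and everything stays transparent and reproducible.

Assumptions worth stating explicitly:

- people live only inside the assembled target geometry, and uniformly so;
  occupancy differences between dwellings inside one zone are invisible;
- residential land-use codes are trustworthy for *small* parcels; large
  residential parcels contain mostly open land, so only their buildings
  count;
- every building inside a large residential parcel is residential; in
  no-parcel zones (step C) every building counts, residential or not —
  a known over-apportionment to barns and stores;
- building detection is imperfect; the method deliberately leans on parcel
  boundaries where it can so that missed buildings (false negatives) do not
  erase populated area.

## Target-zone assembly

Steps A–D are described in the README. Decisions taken where the procedure
was genuinely open:

- **Sliver gate placement.** Whether a zone "contains residential parcel
  area" (the A/B-vs-C gate) is evaluated *after* sliver removal: a zone
  whose only residential pieces were slivers proceeds to the building
  fallback. Anything else would make the sliver filter cosmetic.
- **Sliver threshold semantics.** Removal is strict `<`; a piece exactly at
  the threshold survives. The descendant count is over the whole collection
  (a parcel split 3 ways across zones has n = 3 everywhere), and the filter
  applies to parcel descendants only, never to building fragments.
- **Building membership.** A building belongs to a container (large-parcel
  piece, or zone in step C) when its representative interior point lies
  strictly inside; the footprint is then clipped to the container. This
  assigns a straddling building to exactly one side; a representative point
  exactly on a shared boundary (measure-zero) is assigned to neither.
- **Density cap.** Zones denser than 1 person per 10 m² (strict `>`, on the
  TOTAL variable, falling back to the summed vector) first get their own
  removed slivers restored; if still over the cap the target becomes the
  whole zone (step D). The intermediate building-only stage is skipped
  because it cannot increase area. Both actions are recorded per zone in
  the audit table.
- **Zero-population zones** emit no target; their pixels are genuine zeros.
- Overlapping parcels are unioned per zone before area computation, so
  duplicated coverage never double-weights area.

## Gridding

Pixel values are people per pixel on a north-up grid whose top-left origin
is snapped to integer multiples of the resolution (default 100 m), so
independently produced grids align. Cells are half-open; pixel content is
computed by exact polygon–cell intersection areas (axis-aligned rectangles
take an analytic path; general polygons use prepared-geometry clipping).
Accumulation is float64; files are float32, single band, one per variable,
with no nodata (in-extent unpopulated pixels are true zeros). Conservation
(grid total = input total per variable, ≤ 1e-6 relative) is a tested
property, not a post-hoc rescaling. Grid differencing converts to density,
block-averages to the common resolution and converts back — implemented as
the algebraically identical block sum, which preserves totals exactly but
requires the extent to tile evenly.

## Validation protocol

The coarse-constrained assessment reruns the full pipeline with the coarse
nesting as source zones and compares per-fine-zone estimates to observed
counts. Estimates are computed by vector overlay (density × exact
intersection area), not from pixels, avoiding pixel-straddle artifacts; a
pixel-center aggregation mode exists behind `mode="pixel"` for sensitivity
checks. Metrics — RMSE, squared Pearson correlation of counts, median
percent error, median absolute percent error — are all computed over the
same population: fine zones with observed count > 0. Even-length medians
use midpoint interpolation. When either series is constant, R² is reported
as 0 (undefined correlation); fewer than two populated zones is an error.

## CRS and I/O policy

All layers must share one projected, meter-unit CRS; the tool reprojects
nothing, ever — every threshold in the method is in m², and silent
reprojection would corrupt them. The CRS is carried as an identifier string
(e.g. `EPSG:3310`); known geographic identifiers are rejected. Vector
layers travel as GeoJSON FeatureCollections with a legacy `crs` member;
rasters as GeoTIFF-tagged TIFFs (pixel scale, tiepoint, geo-key directory
for EPSG codes) written and read with tifffile. Invalid polygons are
repaired on read by a make-valid contract (positive-area polygonal part
kept; repairs logged; empty repairs dropped with a warning). Zones missing
from the population table get zeros with a warning; table rows matching no
zone are an error.

## The synthetic landscape generator

The generator is first-class, tested code: it emulates the study's input
conditions so that every stage can be scored against known truth.

What it emulates, and the defaults (all on `SceneParams`):

- **Nesting**: coarse zones split recursively into rectangles; each holds
  Poisson(20) fine zones (`fine_per_coarse=20`, the ~1:20 block-to-block-
  group ratio). The default extent sizes fine zones at ~0.79 km², the
  statewide mean block area. Rectangular splits (not Voronoi) keep areas
  and nesting exact and platform-independent.
- **Clustered settlement**: a few town centers; a fine zone's settlement
  probability decays with distance (Gaussian, `settlement_sigma_frac=0.14`
  of the extent) plus 2% backscatter. Within a settled zone the built-up
  core occupies a corner sub-rectangle (~6–30% of the zone) — settlement is
  clustered *within* zones too, which is the regime dasymetric mapping
  exists for.
- **Neighborhood styles**: a settled zone is an ordinary town (small lots
  of ~2–4 × 10³ m², mixed with commercial and open tiles; 3% of lots span
  2×2 tiles and exceed one acre), an exurb of multi-acre home lots
  (`exurb_prob=0.15`), or an apartment district (`hd_district_prob=0.08`,
  high-density classes, ~45 people per building). Country coarse zones are
  split into ranch country (18-acre rural-residential holdings,
  `rural_per_coarse=1.2`) and wilderness (parcel-less cabin clusters,
  `cabin_per_coarse=2.0`). Styling whole zones, and segregating ranch from
  wilderness at the coarse-zone level, mirrors how real enumeration units
  cover internally similar landscapes; these rates were chosen so that the
  person-level step shares (A≈87%, B≈9%, C≈3.4%, D≈0.3% when this method is
  applied to statewide census data) and the method's block-group-to-block
  error profile are jointly approximated — the generator reproduces roughly
  93/4/2.5/0.1 shares and median errors of the same magnitude.
- **People**: Poisson per building (means 3.0 small/large-lot, 2.6 rural,
  45 high-density, 2.2 cabin, 0 commercial; vacancy = a zero draw).
  Demographic composition per fine zone from a Dirichlet over the seven
  exclusive race/ethnicity groups (multinomial per building), minors from a
  Beta(22, 78) share — roughly the statewide minors fraction.
- **Detection error**: each true building is dropped with probability
  `detection_fn_rate=0.076` and Poisson(`0.015 × n_true`) spurious
  footprints are inserted, only in open/non-residential space — the
  adversarial case for step C.

One integer seed drives a single `numpy.random.default_rng` stream
end-to-end; identical parameters give byte-identical output files.

What it does **not** emulate — so what passing tests do not show: real
street networks and topography; parcel digitizing error and boundary
mismatch between layers (synthetic parcels are clean axis-aligned
rectangles, so the general-polygon clipping path is exercised mainly by
the unit fixtures); vintage mismatch between census and ancillary data;
spatially correlated demographic structure beyond the zone level; census
undercount. Error magnitudes on real landscapes can differ from the
synthetic ones even though the qualitative ordering (dasymetric beating
uniform weighting) is robust across seeds.

## Problem sizes used in the test suite

Statistical suites run at the sizes their checks need rather than at
production scale: conservation uses 100 seeded scenes of ~10³ fine zones
(~10⁴ parcels) each; the method-vs-baseline direction uses 100 seeded
scenes of ~160 fine zones; rasterization is checked against a 10⁶-point
Monte Carlo clipping oracle on 50 random polygons; smaller unit fixtures
are exact. The Monte Carlo oracles exist only in tests — production
gridding is exact clipping throughout.

## Known limitations

- Single-class (binary) treatment: apartment districts inside a mixed
  coarse zone are systematically under-allocated relative to single-family
  land, since only area — not expected density — weights the split.
  Multi-class weighting is out of scope by design.
- Step C counts non-residential buildings as populated.
- The per-zone audit attributes a zone's whole population to its final
  step, overstating the building-borne share for mixed zones.
- No reprojection, no GeoPackage/Shapefile support: inputs must arrive as
  GeoJSON in one projected CRS.
- The density cap is evaluated on one variable (TOTAL by default);
  per-variable capping is not implemented.
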