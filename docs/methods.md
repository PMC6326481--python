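# Methods

## Geometry substrate

All geometry is planar, in a metric projected CRS (the Galápagos workflow
runs in EPSG:32715; any local UTM zone works). Geographic (degree) inputs
are refused at the I/O boundary with an explicit message — the package
bundles no reprojection engine, so reprojection is the caller's job.
Patches are simple polygons with optional holes. Conventions:

- Holes subtract from area, and their rings contribute to perimeter and to
  the node count; the convex hull is computed from the exterior ring only.
  This matches standard GIS semantics for measurement of multi-ring
  polygons.
- A "node" is any stored distinct vertex (the closing vertex counted once
  per ring). Duplicate consecutive vertices are dropped at ingest: they
  are digitization artefacts and would inflate node counts. Collinear
  vertices are *not* dropped — a digitizer's click is a direction change
  at the working scale even if numerically collinear.
- The minimum-mapping-unit filter keeps patches with area ≥ MMU
  (default 10 m²): the boundary case is retained, only strictly smaller
  patches are erased.

## Complexity metrics

Complexity 2 = 0.8·ampl·nodes + 0.2·conv is deliberately unnormalized: it
grows with the node count, which is what makes a finely digitized layer
score an order of magnitude above coarse legacy maps. It is invariant
under rigid motion and uniform scaling (all three factors are
scale-free); Complexity 1 (perimeter/area) scales as 1/s. The layer-level
"Complexity 3" is the mean node count per polygon; the per-polygon
quantity is simply the node count. A flag restricts the node count to the
exterior ring when hole vertices should not enter the score. Layer
summaries are computed after MMU filtering whenever a filtered product is
being characterized.

## Accuracy assessment

Validation points are uniform in a disc (radius default 100 m → 3.14 ha)
via the square-root radial transform. Point-in-polygon classification
counts boundary points as inside. Kappa uses the standard marginal-product
chance agreement; it is reported as undefined (an exception, not a number)
when both marginals are single-class. The two-proportion Z-test pools the
proportions; correct counts may be fractional so that rounded published
accuracies (e.g. 99.1 % of 500) can be compared directly. The z multiplier
for 99 % confidence in survey sizing defaults to 2.58 — the conventional
table value, which reproduces n = 573 for a 4 099-polygon census at a 5 %
margin — with 2.576 available via the argument.

Digitizer QA needs a numeric notion of "coinciding perimeters", which the
field protocol leaves visual. We operationalize it as the arc length of
the candidate exterior lying within a distance tolerance (default 5 m,
half the 10 m² MMU scale) of the reference exterior, normalized by the
candidate perimeter; a polygon passes at a fraction ≥ 0.5. The repeated
("iterated three times") validation is exposed as a repeats option that
redraws points with a fresh seed and reports per-repeat and mean accuracy.

## Classification chains

MLC fits one Gaussian per class by sample mean and covariance on the RGB
bands, with a relative ridge on the diagonal so constant training regions
stay invertible; priors are equal by default (the common GIS-tool default)
and configurable. Ties in the posterior break by class-name order, so
classification is deterministic. Classification is invariant to bandwise
affine rescaling applied consistently to training and scene.

MLC2 splits the scene by the coastline polyline with a pixel-centre rule:
the scene extent is polygonized against the coastline and the side holding
a user-supplied land reference point is land. Each side is classified with
its own class set.

The hybrid chain masks vegetation at NDVI ≥ 0.2 (inclusive threshold),
then grows segments inside the mask: a pixel joins a segment while its
Euclidean distance, in band space min–max normalized over the mask, from
the segment's running mean is at most the difference threshold (default
0.75). Segments smaller than the minimum size are merged into their most
spectrally similar touching neighbour (smallest first, via union-find);
isolated undersized segments with no in-mask neighbour are kept, since
there is nothing to absorb them into. The normalized-distance reading of
the source segmentation tool's "difference threshold" is a documented
stand-in — the tool's internal semantics are not published — and the
minimum segment size is configurable because the canonical 750 px presumes
full-scene imagery; desk-scale benchmark scenes use a proportionally
smaller minimum (200 px for the 300×200 px scene), keeping the
speckle-absorption role of the parameter at the smaller problem size.
Segment selection uses the any-overlap rule: one overlapping MLC2-mangrove
pixel pulls in the whole segment.

Raster-to-polygon tracing uses 4-connected components (diagonal contact
does not join patches — it would create self-touching rings) as unions of
pixel squares in map units, followed by the MMU filter.

## Change analysis

Cross-epoch grouping buffers every polygon by half the distance threshold
(default 15 m, set by the MMU and the measured co-registration error
between epochs) and links polygons whose buffered footprints intersect,
via union-find over both epochs together. Within a group, the stable area
is the intersection of the epoch unions, contraction the t-only area,
expansion the t+Δ-only area; groups with only one epoch present are
disappearances or generations. The two conservation identities hold
exactly by construction, and the decomposition is symmetric under time
reversal with EXP↔CON and GEN↔DIS. Only the five first-level categories
are implemented; higher-level displacement/convergence events of the
original moving-polygons technique are out of scope. Epoch co-registration
is a user-supplied rigid shift (estimated externally from stable
features); automatic co-registration is out of scope. The K-S test
delegates to the standard asymptotic two-sample implementation.

## Coastal statistics

Distance bands are Euclidean buffers of the coastline, half-open intervals
[e_{i−1}, e_i); cover beyond the last edge is appended as an open-ended
band so cumulative fractions reach 1. d50/d90 interpolate the cumulative
profile linearly between band edges. The "fraction of coastline protected"
depends on an arbitrary fronting distance that field reports rarely state;
we default to 50 m and print it next to the number — published
coastline-protection percentages are therefore not comparable unless the
convention matches.

## Synthetic landscape generator

The generator is the package's test bed: it emulates the statistical
structure of an arid-archipelago fringing mangrove system, not its
appearance.

- **Coastline**: a smoothed Gaussian random walk (wiggle 150 m sd,
  smoothed over 700 m) across a 40 km × 5 km domain; land below. The
  domain is wide enough that the default census of 300 patches does not
  saturate the fringing strip — crowding would push patches inland and
  bias the fringe statistics.
- **Patch census**: sizes are log-normal (median 1 400 m², log-sd 1.2,
  capped at 20 ha), which puts ~85 % of patches under 0.5 ha. Centre
  distance from shore is log-normal (median 80 m, log-sd 1.0); patches
  above 1 ha are additionally held within 200 m of shore (extensive
  stands hug the shoreline; inland brackish ponds host only small
  pockets). Together these place roughly half the cover within ~100 m and
  over 90 % within the 500 m fringe depth. The size draw is held fixed
  while placement is retried, so crowding rejections cannot bias the size
  marginal (verified by a K-S check at n = 2000). Patch boundaries are
  star polygons with radial noise; the amplitude dial (default 0.35)
  spans smooth legacy-map styles (≈0) to crenulated faithful
  digitizations.
- **Two epochs**: a scripted fraction of patches expands (mitred buffer,
  4–12 m), contracts (2–6 m), or disappears, and new patches are
  generated clear of everything; defaults plant a net cover gain of
  roughly a fifth to a quarter over the decade (the realized percentage
  varies with the census draw because expansion area scales with the
  perimeters of the selected patches). Every event's exact area is
  recorded in a ledger. A 40 m minimum spacing between distinct patches
  guarantees the 15 m-threshold grouping reassembles each patch lineage
  alone, so ledger recovery by the change module is exact — that is a
  designed property, not luck.
- **Scene**: a 600 × 400 m window on the coast at 2 m pixels. Truth
  classes are painted geometrically (water / lava / shoreline sand /
  deciduous / mangrove, mangrove last) and pixels are drawn from
  per-class Gaussian spectra over R, G, B, NIR reflectances in [0, 1]
  (per-band sd 0.02). The tonality encoding: mangrove medium green with a
  strong NIR plateau; deciduous lighter green with lower NIR; lava
  brown-black with NIR slightly below red so its NDVI is reliably
  negative; sand bright; water dark and NIR-free. Training sets are
  sampled from the truth raster; truth points are labelled from it.
- **Confusable scene**: the benchmark for the chain comparison. The
  deciduous RGB mean is pulled toward mangrove by an overlap parameter
  (default 0.9 ≈ 1σ RGB separation — wet-season tonality), deciduous
  patches are planted flush against mangrove patches so the vegetation
  mask is contiguous across the pair, and sea-surface algae mats with the
  exact mangrove RGB signature (but no NIR) cover ~15 % of the sea. The
  whole-image chain is trained on the four standard covers plus water —
  field workflows have no algae class — so algae commits to mangrove
  under MLC1, while the land/sea partition of MLC2 resolves it
  geographically, and the hybrid chain's whole-segment selection commits
  the adjoining deciduous cover. This construction yields the accuracy
  ordering reference > MLC2 > {MLC1, HYBRID} with gaps of several points;
  the absolute accuracies depend on the fixture, not on any real imagery.

What the generator does **not** emulate: spatial autocorrelation of
within-class texture (the "cauliflower" canopy pattern), illumination and
sensor mosaicking artefacts, clouds, tides, and mixed boundary pixels
beyond raster discretization. Passing tests therefore demonstrate
algorithmic correctness and the direction of the documented failure
modes, not expected accuracy on real imagery.

## Numerical choices and degenerate inputs

- Geometry predicates and overlays delegate to GEOS via shapely; areas of
  overlay products are compared at 1e-6 relative tolerance in tests.
- ampl and conv are clamped at 0 to absorb floating-point noise for
  convex inputs; "convex" in the invariants means ampl = conv = 0 within
  1e-9.
- Covariance ridge: 1e-9 of the mean band variance, escalated ×10 until
  the Cholesky factor exists.
- NDVI is NaN where NIR + R = 0 (and on nodata); NaN never passes the
  vegetation threshold.
- Degenerate rings (< 3 distinct vertices), self-intersections,
  non-finite coordinates, zero-area hulls, empty layers, single-class
  kappa marginals and pooled proportions of 0 or 1 all raise typed
  exceptions rather than returning numbers.

## Problem sizes

The default benchmark uses 300 patches on 40 km of coast and a
300 × 200 px scene; the size-distribution check uses 2 000 patches on
300 km. These sizes make the full suite run in well under a minute while
leaving every statistical check (K-S on sizes, Monte-Carlo Z-test
calibration at 2 000 simulations, 1 000 random epoch pairs) at
conventional power.

## Known limitations

- No reprojection: inputs must already be metric.
- ESRI shapefile I/O is not included (GeoJSON/WKT are the interchange
  formats; KML is read-only) and rasters exchange as plain ASCII grids.
- The segmentation is a faithful re-statement of region growing with a
  normalized-distance threshold, not a re-implementation of any specific
  GIS tool's internals.
- Only two map classes (mangrove / non-mangrove) in the accuracy module;
  no kappa variance estimator.
- The change module reports area totals per category; per-group event
  genealogies beyond level-1 categories are not built.
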