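# Methods

This note documents the models, conventions, and numerical choices behind
`hextable`, and what the synthetic fixtures do and do not establish about
behaviour on real data.

## The sampling frame

The frame is a hexagonal point lattice over a rectangular study extent in
a projected planar CRS (meters). "Spacing" means the nearest-neighbour,
center-to-center distance s (default 161 m ≈ 0.1 mile): rows sit s·√3/2
apart vertically, odd rows are offset by s/2, the origin point is anchored
at (min_x, min_y), and points on the extent boundary are kept. Every
interior point has exactly six neighbours at distance s; the construction
is pure arithmetic and therefore deterministic.

Centroids of polygons with area strictly below 67,261 m² (16.6 acres) are
appended to the frame (`origin_flag = "centroid"`, ids continuing the
sequence) so that small, dense geographic units contribute at least one
sample point each. Invalid polygon geometries are skipped with a logged
warning rather than aborting a whole layer.

Proximal polygons are Voronoi cells clipped to the rectangular extent.
They partition the extent, so proximal areas sum exactly to the extent
area; the test suite enforces this to 1e-6 relative tolerance over random
point sets. Coincident sites (within 1e-9 m) are collapsed onto the first
id — Voronoi is undefined for duplicates — with the survivors keeping the
cell and the duplicates carrying zero area, which preserves the partition
property. Clipping to a non-rectangular study polygon is deliberately out
of scope at this scale.

Geographic (lon/lat) input is rejected with an explicit error rather than
reprojected: every distance and area in the package assumes meters, and a
silent reprojection would mask unit errors. Boundary points in geography
assignment go to the containing polygon with the lowest feature index — an
arbitrary but deterministic, order-stable rule.

## The big table and density estimation

Columns exist only with a metadata record (attribute id, source, native
level, vintage, ISO 19115 thematic category restricted to the standard
19-name topic list, tags, units, kind) tied to a registered source, so
catalog integrity — no orphan columns — holds on every mutation, and any
extract can be shipped with a complete source report. Metadata search is
case-insensitive substring match with union semantics over terms.

Counts at a geography level become per-km² densities by dividing by the
*sum of member points' proximal areas*, not the unit's cartographic area.
This choice makes the density → tally round trip exactly conservative:
selecting all points of a unit recovers the original count to floating
point. Unit areas and cartographic areas coincide only when the frame
samples the unit uniformly, which at 161 m spacing is a good approximation
everywhere except slivers; the centroid augmentation exists precisely to
cover the sliver case.

Nulls are never silently converted to zero: unmatched geography keys stay
null, estimates over selections with null densities report an area
coverage fraction, and no query predicate matches a null (an explicit
null test is available via the `in [null]` comparator — SQL-like
three-valued semantics reduced to two values at the boundary).

Surfaces are modeled as axis-aligned regular grids (origin, cell size,
value matrix). `surface_majority` attributes the modal value over the
cells intersecting a point's proximal polygon, weighted by intersection
area, with ties broken toward the larger area and then the smaller value
representation, deterministically. Multi-vintage data are distinct
columns; there is no temporal query algebra.

## Context measures

Distances are planar Euclidean (meters). Density grids tally feature
counts or clipped line lengths per cell and divide by the cell area in
km²; conservation (Σ value × area = total) holds by construction and is
tested. Queen contiguity (any shared boundary point) is the default
adjacency, rook (positive-length shared boundary) by flag; second order is
neighbours-of-neighbours minus self and first order, and the symmetry and
disjointness invariants are validated on construction.

Travel time snaps each point *and each facility* to its nearest network
node; both snap legs are charged as straight lines at the fallback speed
(default 50 km/h) and the network path at per-edge speeds. Charging the
facility leg too — the network gives no snapping rule either way — keeps
the Euclidean-distance / max-speed lower bound valid no matter how far a
facility sits from the network. Unreachable points get null with a logged
count. With no network at all, travel time degrades to straight-line time
at the fallback speed.

Aggregation to geographies is an unweighted statistic over non-null member
points (mean/sum/min/max/count); units with no points come back null. An
area-weighted variant was considered and rejected as the default because
the frame's approximately uniform point density makes the unweighted mean
already close to a spatial mean, and the unweighted form matches how
per-point summaries are usually read.

## Spatial statistics

Moran's I follows the standard definitions (see README). Inference for the
local statistic is by conditional permutation: unit i's value is held
fixed and the remaining n−1 values are reassigned without replacement to
its neighbour slots, 999 draws by default. The pseudo p-value is
two-sided on |I_i| with the +1 correction, α = 0.05; these are
conventional choices, stated here because nothing in the underlying
methods literature pins them down. Labels come from the sign of the
deviation and of the row-standardised spatial lag; exact-zero deviations
and islands are NS. The identity mean(I_i) = I holds for row-standardised,
island-free weights and is enforced to 1e-9 in tests. Type-I calibration
on an i.i.d. 10×10 rook grid lands within two Monte-Carlo standard errors
of α.

The permutation loop draws, per unit, a (n_perm × k_i) index matrix by
partial argsort of uniform variates — exact sampling without replacement,
vectorised; with a fixed seed results are bit-for-bit reproducible.

SKATER-style regionalization z-scales each attribute column, builds the
contiguity graph's minimum spanning tree under squared-Euclidean edge
dissimilarity (Kruskal with (weight, edge id) ordering), and greedily
removes k−1 tree edges, each chosen to maximise the decrease in total
within-cluster sum of squared deviations, ties again broken by smallest
edge id. This greedy edge-removal form is deterministic and guarantees
contiguous clusters; it does not guarantee the globally optimal partition
(the 4-unit oracle case, where exhaustive search is feasible, is recovered
exactly). Disconnected contiguity graphs are allowed when k is at least
the number of components.

## Scores

Quintile scores cut average ranks at fractions 0.2/0.4/0.6/0.8 into 1–5;
ties share a bin via average ranks, constant inputs collapse to a single
bin scored 1 with a warning, and `worse_is_high=False` reverses the scale
so protective variables still score 5 = worst. Category risk is the row
sum of its variables' quintiles (nulls excluded with a coverage fraction),
the composite the equally-weighted sum of category scores — equal
weighting is an assumption, exposed as configuration (category/variable
lists and direction flags live in the manifest, not in code).

Uniformity measures run the LISA over *all* units jointly — cross-region
neighbours contribute to lags — then count, per region, the share of units
labeled significant HH (u_high) and LL (u_low); u_any is their sum.
Spatial outliers (HL/LH) are excluded from numerator and are in the
denominator; defining the measures as significant-cluster shares, and
excluding outliers, is this package's reading of an otherwise unformalised
idea, stated here so it can be revisited.

Inequity scores quintile-standardise each measure (direction-adjusted),
average within the social and access domains, and average the two domain
scores; the 7-social / 4-access composition is the conventional default
and other counts are accepted with a warning. Cohort comparison reports
mean combined scores over all units, program-reach units, and rural units.

## Synthetic fixtures

The generators produce square-grid nested geographies (blocks → tracts →
counties → state, hierarchical codes by prefix; `blocks_per_county` must
be a perfect square s², counties tiling s×s blocks), uniform random
park/hospital points, a connected road skeleton along county boundaries at
one speed, and spatially autocorrelated county fields from a
simultaneous-autoregressive draw x = (I − ρW)⁻¹ε with row-standardised W
and standard normal ε (|ρ| < 1; ρ = 0 is i.i.d.). SAR was chosen over CAR
for its closed form and trivial stationarity check. Gini fixtures use
log-normal incomes (μ = 10.5, σ = 0.7 on the log scale, a realistic
right-skew for household income).

What the fixtures do *not* emulate: irregular polygon shapes and highly
variable unit sizes, realistic census marginal distributions, road
networks with heterogeneous speeds/one-ways, coastline-clipped extents,
and measurement error. Passing tests therefore establish correctness of
the algorithms and their invariants, not robustness of any substantive
conclusion drawn from real census or health data.

## Problem sizes and determinism

Default test and acceptance problem sizes — grids up to 12×12 units,
lattices of a few hundred points, 10⁴-point query fixtures, 999
permutations, 20–200 Monte-Carlo replicates — were chosen so the full
suite completes in well under a minute while leaving the Monte-Carlo
tolerances meaningful (type-I within 2 MC standard errors; planted-cluster
recovery in ≥19/20 replicates). Every stochastic path takes an explicit
seed; pipeline outputs are written atomically and are byte-identical
across runs with the same seed.

## Known limitations

* Voronoi cells are clipped to the rectangle, not to a study polygon.
* The greedy SKATER variant can miss the global within-SS optimum.
* No multiple-testing correction is applied to LISA p-values by default;
  with many units a fraction α of them will be flagged under the null
  (Bonferroni/FDR is a flagged option left to the caller).
* Travel time ignores turn restrictions, one-way streets, and congestion.
* The query engine scans columns; there are no secondary indexes, by
  design at this scale.
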