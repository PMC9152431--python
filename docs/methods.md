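# Methods

`endegrid` implements a grid-based diversity and conservation-gap analysis for
point occurrence records of a plant group across a two-country study area:
record cleaning, degree-grid endemism metrics, a margin-preserving
randomization test for centers of endemism, and protected-area/human-footprint
overlays. This note documents the models, conventions and numerical choices,
and what the synthetic validation does and does not show.

## Occurrence cleaning

Records carry provenance and identification-quality flags (introduced,
ex-situ/cultivated, hybrid, doubtful identification, incomplete
identification) derived from Darwin-Core-style columns
(`establishmentMeans`, `identificationQualifier`, `taxonRank`) or supplied as
explicit boolean columns. Cleaning applies exclusion rules in a fixed order —
provenance → hybrids → identification quality → coordinate validity →
per-species duplicate coordinates — so every removed record has exactly one
recorded cause and the report reconciles exactly
(`n_input = n_output + Σ removals`). The order itself is a convention: any
order yields the same retained set, only the per-rule attribution of
multiply-flagged records changes.

Duplicate coordinates are exact value matches of the `(species, longitude,
latitude)` triple at full stored precision, first record kept. No
distance-based thinning is applied: exact matching is reproducible and
order-independent up to the first-kept tie-break. Coordinate repair against
gazetteers and nomenclatural reconciliation are out of scope — both are
curatorial, not computational, steps; invalid coordinates are flagged and
counted, never corrected.

Endemism ("occurs nowhere outside the study area") is an *input attribute*
per species, not inferred from the records: a database restricted to the
study area cannot distinguish a country endemic from a species that simply
was not sampled elsewhere. Checklist summaries therefore take an external set
of endemic species and classify a species as endemic to one country only when
it is both in that set and recorded in a single country.

## Grid and metrics

The grid is the WGS84 graticule itself: cells of `cell_size` degrees (default
1°) anchored at (−180, −90), so 1° cells align with integer meridians and
parallels. No projection is applied; cells are graticule cells, with the
known latitude-dependent area distortion that entails. Cell membership is
half-open, `[edge, edge + size)` in both axes: a point exactly on a shared
edge belongs to the cell whose lower edge it touches, which makes binning
deterministic and refinement-consistent.

From the binary cells × species incidence matrix (rows and columns with at
least one presence; lexicographic orderings, so the matrix is independent of
record order):

- **SR**, species richness: the row sum.
- **WE**, weighted endemism: `WE_c = Σ_s n_{s,W(c)} / r_s` over species
  present in the window `W(c)`, where `n_{s,W}` is the number of window cells
  occupied by *s* and the range `r_s` is the number of occupied cells over
  the **whole** analysis extent (never per window).
- **CWE**, corrected weighted endemism: WE divided by the number of species
  in the window.

The default window is the focal cell alone, under which WE reduces to the
classic inverse-range-weighted sum `Σ 1/r_s` and CWE lies in (0, 1]. A square
window of configurable half-width is available for sensitivity analysis. Two
identities anchor the implementation and are asserted in tests: with the
single-cell window, `Σ_c WE_c` equals the number of species exactly (each
species contributes `r_s × 1/r_s`), and `CWE_c · SR_c = WE_c` per cell.

Percentile trimming of a score distribution (default 5–95%) uses the
linear-interpolation empirical percentile (numpy's default). Trimmed extrema
are descriptive output only; nothing downstream consumes them.

## Randomization test

The null model preserves both margins of the incidence matrix: each cell's
richness and each species' range. Replicates are generated by **curveball
trades**: pick two cells, keep their shared species, pool the non-shared
ones, and deal the pool back at random in the original per-cell counts. Each
trade preserves both margins exactly; iterated, the chain samples uniformly
from the fixed-fixed matrix set. A trade whose random split reproduces the
current state still counts as a performed move — counting only state changes
would bias the chain and can lock small systems into parity cycles.

Chain schedule: burn-in of 5× the matrix fill (number of presences) starting
from the observed matrix, then one saved replicate per 1× fill of further
trades. An attempt cap (default 50× the trade quota) guards against
degenerate matrices with few tradeable pairs; exhausting it records a warning
in the result metadata rather than failing. Matrices whose margins admit a
unique realization are returned unchanged.

The test statistic (CWE by default; WE available) is recomputed on every
replicate; the `1/r_s` terms are cached since ranges are invariant under the
null. SR is likewise invariant, so richness itself is never "significant" —
only range-weighted structure is. The test is one-tailed high (centers of
endemism), with add-one p-values `p = (k + 1)/(n + 1)` where `k` counts null
values ≥ observed; ties (within 1e-9, absorbing float summation-order noise)
count as exceedances, a conservative convention. Under this rule `p ≤ alpha`
is identical to "observed ranks in the top alpha fraction" of the combined
ranking. Defaults are 999 iterations at alpha = 0.05, so the smallest
attainable p is 0.001. No multiple-testing correction is applied across
cells; the per-cell 5% rule is the analysis's own convention.

## Gap analysis

"Spatial coincidence" and "species per reserve" are deliberately distinct
operations, because they answer different questions: coincidence is
polygon-intersects-occupied-cell (boundary touch counts), suitable for
counting reserves that touch the mapped distribution at all; species counts
use boundary-inclusive point-in-polygon on the cleaned records, the species
actually documented inside the reserve. Invalid polygons get one zero-width
buffer repair pass; still-invalid geometries are excluded with a logged
reason rather than poisoning the run.

The human-footprint index is a 0–100 composite surface at ~1 km resolution.
The zonal mean over a reserve is the unweighted arithmetic mean of pixels
whose **center** lies inside the polygon, ignoring nodata; a reserve covering
no pixel center gets an undefined marker (NaN), never 0 — an impact of zero
is a meaningful value. Cell-center inclusion was chosen over area-weighted
partial coverage as the simple, deterministic convention; for reserves large
relative to the pixel size the two agree closely.

Vector data are read and written as GeoJSON and rasters as ESRI ASCII grid
(`.asc`) — plain-text formats with full fidelity for this analysis; geometry
predicates are shapely's.

## Synthetic data

The generator emulates the statistical structure this pipeline is sensitive
to: a heavy-tailed range-size distribution (log-series by default, the
classic shape for range sizes; uniform and fixed available), spatially
cohesive ranges grown by randomized breadth-first accretion (the simplest
contiguity model adequate for testing spatial statistics) or uniform scatter,
planted clusters of single-cell endemics as known centers of endemism,
rectangular protected areas, and a bounded 0–100 impact raster (constant,
gradient, or Gaussian-bump models; bump width is a few percent of the extent
so the surface peaks locally instead of saturating).

Every species emits **at least one record per occupied cell**, plus extra
records to meet its per-species budget (fixed or Poisson, default Poisson
mean 8). The floor is what makes the generator an oracle: the gridded
presence matrix equals the generator's ground-truth occupancy exactly, so
every downstream quantity has a known expected value. It also means record
counts per species are bounded below by range size, unlike real collections.
Other features of real data deliberately not emulated: collection effort
bias (roads, herbaria), taxonomic error, niche-driven spatial structure.
Passing tests therefore demonstrate correctness of the computation and
calibration of the test under known structure — not robustness to sampling
bias in real occurrence databases.

All randomness flows from one explicitly passed seeded generator; there is
no global random state, and every pipeline stage is bitwise-reproducible
from its config plus seed (the run manifest records SHA-256 hashes of every
output to make this checkable).

## Validation studies

Two simulation studies characterize the randomization test
(`endegrid.validation`):

- **Type-I calibration**: 200 landscapes of 40 species scattered uniformly
  on an 8×8-cell box with ranges drawn uniformly from 3–15, tested at 199
  iterations. Uniform scatter conditional on realized richness margins is
  uniform over the fixed-fixed set, so p-values are valid by construction and
  the flagged fraction should sit at alpha (marginally below, from
  conservative tie handling). Note that *identical* ranges would make WE and
  CWE constants of the margins — invariant across all replicates — so
  calibration requires heterogeneous ranges.
- **Planted-center recovery**: 100 landscapes of 60 widespread species
  (ranges 10–30) on a 15×15-cell box with 5 single-cell endemics planted in
  one cell, tested at 199 iterations; the study reports how often the
  planted cell is flagged.

Study sizes (200/100 landscapes, 199 iterations) keep each study to a few
minutes on one core while holding the binomial standard error on the
estimated rates to a fraction of the effect being measured.

## Known limitations

- Graticule cells shrink with latitude; at subcontinental scale the original
  analysis accepts this, and so does this implementation.
- The curveball chain's burn-in (5× fill) is a heuristic with good empirical
  mixing, not a proven mixing time; the calibration study is the practical
  check. p-values from any other fixed-fixed sampler will agree in
  distribution, not replicate-by-replicate.
- The checklist's endemic counts are only as good as the supplied endemic
  species list; nothing validates it against external floras.
- Zonal means ignore partial pixel coverage; very small reserves relative to
  the raster resolution can be undefined (reported as such).
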