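# Methods

`ginet` reconstructs a green-infrastructure (GI) network from two rasters — a
categorical land-use map and a DEM on the same grid — and then stress-tests
that network with circuit theory.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic scenes
do and do not establish.

## Raster model

All stages share one grid: square cells of `cell_size` metres (default 30 m,
so one cell is 0.09 ha), row 0 at the north, map origin at the lower-left
corner, cells addressed `(row, col)`.  Rasters are exchanged as single-band
GeoTIFF (via `tifffile` with the standard ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags) or ESRI ASCII grid.  Slope is computed with the Horn 3×3
stencil (the common GIS default) and reported as a **fraction** (0.5 = 50 %),
because the terrain correction multiplies it directly; border cells use
edge-replicated neighbours, so gradients there are attenuated.

## MSPA classification

The binary foreground is forest ∪ farmland.  The segmentation is
Soille–Vogt-style (GuidosToolbox-inspired, not bit-identical), with edge
width `s` (default 1 cell) and 8-connectivity:

1. **core** — foreground whose chessboard distance to the nearest background
   cell exceeds `s`; the map border counts as background.
2. **islet** — foreground components with no core.
3. **edge / perforation** — non-core foreground within chessboard distance
   `s` of a core cell (the geodesic dilation of core).  A cell is
   perforation when its nearest background component is a hole (a
   4-connected background component not reaching the map border — the
   complementary connectivity of the foreground's 8), else edge.  Ties
   (a cell equally close to a hole and the outer background) go to edge.
4. **bridge / loop / branch** — the remaining connector cells, per
   8-connected component: ≥ 2 distinct core contacts → bridge; one core
   contacted in ≥ 2 disjoint cell-runs → loop; one contact → branch; zero →
   islet.  "Contact" means 8-adjacency to a core cell or to a boundary cell
   assigned (by nearest-core) to that core's patch.

A frequently quoted alternative statement of step 3 — "boundary is every
non-core cell within `s` of background" — is degenerate: *every* non-core
cell is within `s` of background by the definition of core, which would
leave no connectors at all.  Anchoring the boundary on the core instead
reproduces the expected behaviour of the hand-traceable fixtures (a solid
5×5 block, two blocks joined by a thin path, a block with an interior hole).

Nodata cells are background.  The seven classes exactly partition the
foreground (a tested invariant), and widening `s` can only shrink core.

## Patch graph and connectivity indices

Nodes are the 8-connected components of **core** and of **bridge**,
kept separate (their graded resistance values differ and importance is
reported per element type).  Patch attribute `a_i` is area in hectares.
Edge-to-edge distance is the minimum Euclidean distance between cell
centres; two patches link when `d_ij ≤ θ` (default θ = 2000 m).

With `A_L` the **total landscape area** (not the GI area):

* `IIC = Σ_i Σ_j a_i a_j / (1 + nl_ij) / A_L²`, `nl_ij` the minimum link
  count over the thresholded graph (∞, contributing 0, when disconnected;
  the `i = j` terms with `nl = 0` are included);
* `PC = Σ_i Σ_j a_i a_j p*_ij / A_L²`, where `p_ij = 0.5^(d_ij/θ)`
  (probability ½ at the threshold distance — the usual exponential-decay
  convention; both the half-distance probability and the option to run PC on
  the complete graph instead of the link graph are configurable) and
  `p*_ij` is the maximum product of step probabilities over any path,
  computed as a Dijkstra shortest path on `−log p` weights;
* patch importance `dI(%) = 100 (I − I_remove)/I`, with `I_remove` the index
  recomputed after deleting the patch and its links, `A_L` unchanged.

Because `p` is tied to θ, the threshold sweep's dPC curves keep drifting
slightly even after the link graph is complete; dIIC saturates exactly.
Hubs are the top-`k` patches (default 10) by dIIC — the ranking key is
configurable, but the published ranking is strictly descending in dIIC
while not in area — with ties broken by larger dA, then smaller id.
Non-hub patches split into "important" / "general" by 2-class Fisher–Jenks.

## Resistance surface

Base resistance is a single-value precedence overlay (highest first): hub
patch cells → 1; core/bridge cells → the value for their patch's importance
level (1 / 10 / 20); water cells → their sub-type value (river 200, lake
150, other water 100); non-water cells within 100 m (Euclidean, cell
centres, inclusive) of river or lake → 80 when that is lower than their
land-use value; otherwise the land-use value (forest 30, farmland 50,
bareland 70, road 250, construction 300).  A precedence overlay rather than
a weighted sum is used because the shipped factor table is a flat value
list; the table is a YAML-serialisable config.  MSPA classes without factor
rows (edge, branch, loop, islet, perforation) take their land-use value.

The terrain correction is `R′ = R × (1 + i)` with `i` the slope *fraction*:
read as a raw percent number a 50 % slope would inflate resistance 51-fold,
while the fraction reading keeps the corrected range consistent with values
observed on real surfaces (max ≈ 300 × 2 on extreme slopes).

## Least-cost corridors (MCR)

Cost distance is Dijkstra over the 8-connected cell graph; a move between
adjacent cells costs `step × (R_a + R_b)/2` with `step = cell_size`
(orthogonal) or `cell_size·√2` (diagonal) — the standard GIS cost-distance
convention (a geometric-mean variant would be a one-line change in
`build_cost_graph`).  Hub-to-hub cost is patch-to-patch: every source-patch
cell starts at 0 and the target cost is the minimum over target cells.
Determinism comes from the fixed graph construction and
`scipy.sparse.csgraph.dijkstra`'s deterministic predecessor choice; equal-
cost ties are therefore resolved reproducibly but not by an explicit
step-count rule.

All hub pairs get a least-cost path; the network then drops a pair when its
path crosses a third hub's patch, or when an indirect route over another
hub is strictly cheaper (both rules toggleable).  If pruning disconnects
hubs the full pair set connected, the cheapest dropped corridors are
restored.  Reported statistics: accumulated resistance (MCR), length
(Σ step distances), and average resistance = MCR/length rounded to an
integer; lengths print to the metre, network totals to the kilometre.

## Circuit analysis

Grid circuits use the same edge-resistance convention as the cost distance,
so effective resistance is always ≤ the least-cost path cost (parallel
routes only help — a tested invariant, alongside Kirchhoff conservation at
10⁻⁸ relative and source/ground reciprocity).  Laplacian systems are solved
sparsely with the ground set fixed at 0 V; multi-cell patches are contracted
to equipotential supernodes (internal branch currents are reported as 0).
Node current is half the sum of absolute incident branch currents plus half
the absolute injection.

* **Hub centrality** runs on the reduced hub–corridor graph (nodes = hubs,
  edge resistance = corridor MCR): 1 A is passed between every unordered
  hub pair and each hub's node current is accumulated, then divided by the
  number of pairs.  The pairwise accumulation symmetrises the
  "inject at one, ground another" description, which otherwise depends on an
  arbitrary configuration choice.  Grading is 3-class Fisher–Jenks.
* **Pinch points**: per corridor `(i, j)`, the circuit is restricted to the
  corridor swath — cells with `cd_i + cd_j ≤ MCR × (1 + cutoff)`, cutoff
  5 % of MCR — plus the two patches, and 1 A is passed between them.  By
  reciprocity this equals the many-to-one iteration up to a constant factor.
  Accumulated currents are ranked within the swath union (hub interiors
  excluded); the top quantile (default 5 %) is the pinch set, reported with
  each cell's MSPA class.  A pair whose swath disconnects is skipped with a
  warning.
* **Barriers**: a circular window of radius D (default 60 m ≥ one cell) is
  stepped at every cell of the dilated swaths.  Shorting the window to the
  landscape minimum resistance (1) would let a pair reroute through it; the
  score is `IS = ΔLCD / D` with `ΔLCD = Σ_pairs (LCD₀ − LCD₁) ≥ 0`.
  Exact per-window Dijkstra recomputation is quadratically expensive, so
  LCD₁ is evaluated as `min(LCD₀, min_window(cd_i) + min_window(cd_j))`
  from the hubs' precomputed cost-distance rasters — the best route entering
  the shorted window from either side, the standard fast window-scan
  approximation.  It ignores the (≤ one window diameter at resistance 1)
  crossing cost, so IS is a slight overestimate near strong barriers and
  exact far from them; ΔLCD ≥ 0 holds by construction.  Cells with IS > 0
  are graded by 4-class Fisher–Jenks (exact dynamic programming; above
  10,000 observations a seeded subsample locates the breaks): the lowest
  class is non-barrier, the upper three are improvement levels 3, 2, 1.
  The break values are data-dependent and recomputed per scene.

## Synthetic scenes

`generate_scene` builds the landscape the analysis assumes: Gaussian-hill
massifs (default 4, split between the north and south borders, amplitudes
220–380 m, σ ≈ scene/7) over a low basin with smoothed noise for slope
texture; land use from an elevation ranking (forest the top share, a
farmland fringe below it) steered to a GI target of 22 % ± 3 % by a
deterministic top-up/trim; a two-cell-wide sinusoidal river with a lake and
ponds; straight road strips; and Poisson-planted 1–5-cell green islets in
the basin.  All randomness flows through one `default_rng(seed)`; identical
parameters and seed give identical scenes.

Two fixtures support recovery testing.  `plant_bottleneck` cuts a forest
strip of known width between two massifs through a construction moat, so
the strip is the only low-resistance crossing; `plant_barrier` plugs the
strip's central cells with construction.  Both record their cells in
`scene.truth`.  On 10 consecutive seeds (120×130 scenes) the pinch-point
set hits the planted strip, and the maximum-IS window on the plugged pair's
corridor overlaps the plug.  The barrier recovery is deliberately assessed
on that corridor: on a mountainous scene the whole-network scan can
honestly rank a steep construction crossing on *another* corridor (slope-
corrected R ≈ 430) above the flat-basin plug (R ≈ 300) — the method working
as intended, not a localisation failure.

What a green synthetic run does **not** establish: the scenes have smooth
Gaussian terrain, far more consolidated cores and far fewer islets than a
real Landsat-classified city, no classification noise, and no meaningful
hydrology; absolute index values and class shares are not comparable to any
real landscape.  The published-arithmetic tests (structure shares, corridor
summaries, improvement shares) therefore run on the printed tables
themselves, not on synthetic output.

## Known limitations

* No reprojection or resampling; inputs must share one grid.
* MSPA is not bit-compatible with GuidosToolbox (transition-pixel and
  "intext" options are out of scope).
* The barrier scan's window approximation (above) trades exactness for a
  ~10³ speedup; `ΔLCD ≥ 0` and localisation behaviour are preserved.
* Natural-breaks grading of printed centrality values need not match
  published groupings produced by unspecified methods: for the regression
  fixture shipped in the tests, the exact Fisher–Jenks optimum puts only
  the top hub in the highest class, while the published grouping pairs the
  top two.  The tests assert the ranking, which is unambiguous.
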