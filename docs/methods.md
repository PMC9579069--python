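# Methods

## Stimulus model

A stimulus is a set of `n` points inside a circular aperture of radius `R`
(pixels, origin at the center, y up). Defaults follow the reference study
conditions: `n ∈ {22, 28, 34, 40}`, `R = 160` px (5° of visual angle at
57 cm viewing distance and 32 px/deg), minimum pairwise spacing
`δ = R/16 = 10` px, 1000 patterns per numerosity.

Generation is plain rejection sampling: candidates uniform on `[-R, R]²`,
kept when inside the aperture and at distance ≥ δ from every accepted point
(exact ties accepted — a measure-zero choice fixed for determinism). Under
these conditions the probability that two independent uniform points fall
within δ is ≈ 0.0038, so rejections are rare and the sampler is effectively
uniform-with-exclusion; `pair_proximity_probability` estimates this number
by Monte Carlo and `pair_proximity_exact` integrates the disk line-picking
density as a cross-check. A master seed spawns per-pattern generators via
`SeedSequence(master, spawn_key=(n, replicate))`, so any single pattern can
be regenerated without the rest. The rejection cap (`max_attempts`, default
10⁵ per pattern) exists only to terminate infeasible requests; it is
unreachable at study parameters.

## Geometric graph

`G_d` joins two points when their distance is **≤ d** (closed threshold).
One could equally use a strict inequality — for continuous coordinates the
boundary has probability zero — but the closed rule matches the occupancy
tangency convention (influence disks of radius d/2 touch exactly at
separation d) and makes tests deterministic. Graphs are dense boolean
matrices; at n ≤ 40 an O(n²) build per (pattern, d) cell is faster than any
spatial index would pay for. `G_d` is monotone in d, so the sweep reuses
one distance matrix per pattern.

## Index conventions

* **TD** is graph density `2|E| / (n(n-1))`. The raw total degree's maximum
  is twice the maximum edge count; the divisor is chosen so the complete
  graph scores exactly 1, which is the stated purpose of the
  normalization. Constant factors cannot affect any correlation or PCA
  result downstream.
* **TL** divides the summed edge lengths by the fixed ceiling
  `2d·n(n-1)/2` (complete graph with all pairs at distance d), giving a
  range of [0, 0.5]; the customary 0.5 ceiling is kept rather than
  rescaled. Dividing by the graph's own `|E|` instead would turn TL into a
  mean edge length: its across-pattern spread then peaks at a degenerate
  small d (a handful of edges whose mean length is noisy) rather than
  tracking total wiring cost, and its maximum-SD distance collapses from
  ≈ R to ≈ 1.5δ. The fixed divisor is the reconstruction consistent with
  the study-level behavior of the index; for complete graphs both
  conventions coincide.
* **RW** simulates simple random walks (uniform random start vertex, uniform
  neighbor steps, one step per edge traversal) until all vertices are
  visited; the index is `n ln n / T̄` over `walks` replicates (default
  1000). The normalizer is the asymptotic cover-time lower bound; natural
  log is used — any fixed constant rescales RW identically across graphs.
  Disconnected graphs score 0 (cover is impossible). Values above 1 occur
  for tiny n (a single edge covers in one step: RW = 2 ln 2) and are not
  clamped. The reported `mc_error` is the delta-method standard error.
* **EG** runs power iteration on the adjacency matrix from the degree
  sequence, renormalizing to unit Euclidean length each step; convergence
  is successive iterates within 10⁻⁶ in max-norm, up to 1000 iterations.
  The index is the mean component of the converged vector, and 0 when the
  iteration does not converge (edgeless graphs; bipartite-like graphs whose
  ±λ eigenvalue pair makes iterates oscillate). By default EG is also 0 for
  disconnected graphs, like RW: the dominant eigenvector of a disconnected
  graph lives on a single component, so its mean component measures which
  component happens to dominate — a component-size lottery whose
  across-pattern spread peaks at a degenerate small d and correlates with
  nothing. With the connected-only convention, EG's maximum-SD distance
  sits just below RW's and EG loads with the spread group in the PCA,
  matching the study-level behavior of the index. `connected_only=False`
  restores the whole-graph iteration.
* **CL, DN, IN** are exact, never heuristic. Clique and independence
  numbers use igraph's exact branch-and-bound (C); the domination number
  uses an in-package bitmask branch-and-bound over closed neighborhoods
  (solved per connected component; branching on an uncovered vertex with
  fewest dominators; greedy upper bound and a `⌈rem/maxcov⌉` lower bound).
  All three agree with exhaustive subset enumeration on hundreds of random
  graphs with n ≤ 12 in the test suite.
* **LC** uses the convention `lc_v = 0` when `deg v < 2` (the formula's
  denominator vanishes), matching the common library convention. **GC** is
  transitivity `3T/P₂`, 0 when there are no connected triplets.

## Occupancy

`occupancy_analytic` computes the exact area of the union of equal disks:
the union boundary is decomposed into circular arcs (for each circle, the
angular intervals strictly inside neighboring disks are removed) and
integrated with Green's theorem. Holes enclosed by rings of disks are
handled automatically because every boundary arc, traversed
counterclockwise about its own center, keeps the union on its left. Exactly
coincident centers are collapsed first. The test suite validates against
the two-circle lens closed form and against shapely polygonal-buffer unions
(including a hole case).

`occupancy_raster` mirrors the draw-and-count procedure: disks are painted
onto a shared grid with cell centers at integer multiples of the cell size
(resolution 1 reproduces integer-pixel sampling) and covered cells are
counted. Its error is bounded by perimeter × cell size; at 1 px it
correlates with the exact value at r ≥ 0.9997 for d ≥ 3δ and r ≈ 0.996 at
d = 2δ, where quantization noise is comparable to the small occupancy
variance (sub-pixel resolutions 2–4 give r > 0.999 everywhere; at d = δ
the spacing constraint forbids overlap, every exact value is 1, and the
correlation is undefined). Disks are
**not** clipped to the aperture in either method (the reference procedure
painted on a full canvas); a pattern with a dot near the rim contributes
area outside the aperture. Both values are normalized by `nπ(d/2)²`, so 1
means no overlap anywhere.

## Sweep and maximum-SD selection

The sweep evaluates every requested index on every (pattern, d) cell of the
grid `{δ, δ+5, …, 2R}` (63 distances). Stochastic cells draw from
`SeedSequence(master, spawn_key=(pattern_index, round(d·1000)))`, making
the whole table a pure function of (patterns, grid, settings). Failed
cells are flagged, never dropped silently.

`max_sd_distance` picks the smallest grid d attaining the maximal
across-pattern **sample** standard deviation (ddof = 1; ties toward smaller
d for determinism — with hundreds of patterns ties are measure-zero). An
index constant at every grid point raises a degenerate-variance error.
`connectivity_threshold` computes each pattern's critical connection
distance as the longest edge of its Euclidean minimum spanning tree (the
bottleneck characterization) and returns the smallest grid value covering
all patterns; `index_floor_distance` detects the smallest d from which an
index's variance stays zero (saturation), used to keep saturated indices
out of correlation analyses.

Scaled-down mode: 200 patterns per numerosity with the 5-px grid
reproduces every qualitative result and all the quantitative targets that
are checked; the package's tests and the acceptance script run at this
scale (the connectivity threshold, which is cheap, uses the full 1000).

## Correlations and PCA

Pearson matrices carry two-tailed p-values from the t distribution with
`n_obs − 2` df; entries with p > α (default 0.05) are masked, not deleted.
Zero-variance columns raise an error naming the index — the saturated-index
pathology must be handled explicitly, not silently correlated.

The PCA operates on the **correlation** matrix of the max-SD dataset
(RW excluded — it correlates with nothing). The variables have wildly
different scales, and the study-level eigenvalue pattern (λ₁ ≈ 4.6 of 10,
λ₃ just below 1, Kaiser-style retention) only arises for standardized
variables; covariance mode is available via `use_correlation=False`. Two
components are retained by default, with the full eigenvalue table always
reported. Rotation is varimax with Kaiser row normalization, implemented
as Kaiser's pairwise Jacobi sweeps with the closed-form per-pair angle
(the common SVD-fixed-point recipe converges too slowly on
near-degenerate leading eigenvalues to be trusted here; the test suite
cross-checks against statsmodels' rotation). Each component's sign is
oriented so its largest-magnitude loading is positive. The |loading| ≤ 0.3
display suppression is display-only; full-precision loadings are always
persisted.

## Known limitations and reproduction gaps

* The generator emulates the study conditions (uniform disk, hard
  spacing); it does not implement density-controlled or grid-based
  generators, so conclusions about index behavior apply to
  uniform-with-exclusion patterns only. Real experimental stimuli also
  carry element size, luminance and eccentricity structure that points do
  not capture — passing tests show the indices behave correctly on the
  geometry, not that they predict perception.
* The literal "smallest d with *every* pattern connected" is an extreme
  statistic: at n = 40 about 1.5% of patterns have a critical distance
  above 0.56R, so over 1000 patterns the all-connected threshold lands
  near 0.65–0.70R and is dominated by a single outlier pattern. A
  vanishing-variance (e.g. 99th-percentile) reading is the stable
  quantity; the package reports the literal definition.
* GC's maximum-SD distance falls at small d (20–30 px), where transitivity
  is bimodal (0 for triangle-free patterns, near 1 for patterns whose few
  triplets close); its study-level placement at 35–55 px is not
  reproduced under the printed definition. This affects only how strongly
  GC coheres with the clustering group in the PCA.
* RW and EG values are Monte-Carlo/iterative and carry `mc_error` /
  convergence caveats; both are bit-reproducible given the seed.
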