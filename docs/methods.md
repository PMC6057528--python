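# Methods

## The clustering-tree construction

A clustering tree summarises a family of hard clusterings of the same
$N$ samples at resolutions $k_1 < \dots < k_R$. The construction is purely
combinatorial:

1. **Nodes.** One node per observed (resolution, label) pair, identified as
   `{resolution}C{label}`. Labels are opaque strings — no assumption of
   consecutive or numeric labels (graph-clustering tools label from 0,
   k-means implementations from 1). Empty clusters do not exist: node sizes
   at each resolution always sum to $N$.
2. **Edges.** For each adjacent resolution pair, the overlap contingency
   table is computed (cell $(i, j)$ = samples in both clusters). Every
   nonzero cell is a candidate edge with weight
   $p = \text{count} / |\text{target cluster}|$ (the in-proportion).
   A raw-count threshold would favour low resolutions and large clusters;
   the in-proportion instead measures how much the edge matters *to the
   cluster it feeds*, independent of size.
3. **Filtering.** An edge is kept iff count > `count_filter` **and**
   $p$ > `prop_filter`. Both comparisons are strict, so the zero thresholds
   keep every nonzero edge — which is what makes the conservation laws
   testable: with zero filters, each node's in-edge counts sum to its size
   and its in-proportions sum to exactly 1. Defaults are
   `count_filter = 0`, `prop_filter = 0.1`: enough to drop the faint
   sample-swapping edges that clutter overclustered regions while leaving
   branch structure intact. Filtering is display-level pruning only; node
   membership, aggregation and stability always use the unfiltered
   assignments.
4. **Core edges.** Each node's single best in-edge (maximal $p$; ties to
   the larger count, then the smallest source label, so the choice is
   deterministic) is flagged as its *core* edge. The core subgraph is a
   forest rooted at the lowest resolution — the skeleton the tidy layout
   hangs from. Nodes whose in-edges were all filtered away become extra
   roots.

Edges only ever run from one resolution to the next, so the graph is
acyclic by construction, and the topological order is the resolution
order.

## Stability index

The per-cluster stability score rewards clusters whose sample set recurs
intact at other resolutions and penalises clusters smeared across many:

$$s(c) = \frac{1}{R-1} \sum_{k' \neq k} \frac{1}{N_{k'}^{2}}
         \sum_{j \in J_{k'}} \frac{|c \cap j|}{|j|}$$

with $J_{k'}$ the clusters at resolution $k'$ sharing at least one sample
with $c$ and $N_{k'} = |J_{k'}|$. Each per-resolution term lies in
$[0, 1/N_{k'}]$, so $s \in [0, 1]$, and $s = 1$ exactly when $c$'s sample
set appears as one whole cluster at every other resolution. The classical
SC3 formulation of this index assumes consecutive integer $k$; because
resolutions here may be arbitrary increasing numbers (0.1 … 1.0 for graph
clustering), the default normaliser is the number of other resolutions,
$R - 1$. `normalizer="span"` divides by $k_R - k_1$ instead, which
reproduces the integer-$k$ convention when resolutions are 1…R. Scores are
computed from the full assignments, never the filtered tree.

## Layouts

Both layouts fix $y = -(\text{resolution index})$: one horizontal layer
per resolution, lowest resolution on top, parents above children.

* **Tidy tree (Reingold–Tilford).** Runs on the core forest. Subtrees are
  placed post-order; sibling subtrees are packed using per-layer contours
  with a minimum separation of one unit; each parent is centred at the
  mean of its children's x positions; multiple roots are packed side by
  side. Core edges therefore never cross. Non-core edges are drawn on top
  of this placement but do not influence it — a tidy layout is only
  defined for a forest, which is why the "use all edges" option applies to
  the layered layout below rather than to this one.
* **Layered (Sugiyama-style).** Layer assignment is free (the resolution
  gives it); only within-layer ordering is optimised. Each sweep reorders
  layers top-down by the barycenter (mean position of neighbours in the
  layer above), then bottom-up, with stable sorts so ties keep their
  previous order; each sweep ends with the classic adjacent-transposition
  refinement (swap neighbouring nodes whenever that strictly reduces the
  crossing count). A sweep is accepted only if it strictly improves the
  total crossing count, so accepted sweeps are monotone; the default
  budget is 20 sweeps, far more than small trees need. Barycenter alone
  proved insufficient in testing (it can stall at twice the optimum or
  worse on dense 3-layer graphs); the transposition step is the standard
  remedy and is included in every mature layered-layout implementation.
  By default only core edges drive the ordering (matching what the tidy
  layout would show); `--all-edges` lets every retained edge participate.

Crossing counts are exact pair counts between adjacent layers and are
reported in the layout result; the test suite checks them against an
exhaustive-permutation optimum on small graphs.

## Aesthetic mappings

* Node **area** is proportional to cluster size (radius $\propto \sqrt{n}$,
  with a small floor so singleton clusters stay visible) — perceptually
  honest, since readers judge area, not radius.
* Node colour: resolution (categorical, one colour per layer), an
  aggregated metadata attribute (viridis for numeric, categorical palette
  otherwise), or the stability index (viridis, purple = low to
  yellow = high).
* Edge colour encodes the sample count (viridis over the observed range);
  edge transparency encodes the in-proportion via
  $\alpha = 0.1 + 0.9\,p$ — the floor keeps weak-but-retained edges
  faintly visible.
* Aggregation (mean/median/min/max/sum for numeric columns, mode for
  categorical, mode ties to the smallest value) is membership-exact over
  the unfiltered assignments, so every node gets a value even if filtering
  disconnected it.

Styling never alters topology; rendering is deterministic (fixed SVG hash
salt, no timestamps), so the same tree yields byte-identical figures.

## Synthetic benchmark scenarios

The generator reproduces a five-scenario study design for probing how
trees respond to true structure versus overclustering. All datasets are
100-dimensional:

| scenario | content | points |
|---|---|---|
| A | uniform noise on $[0, 10)$ per coordinate | 1,000 |
| B | one Gaussian cluster | 1,000 |
| C | clusters 1–2 | 2,000 |
| D | clusters 1–3 | 3,000 |
| E | clusters 1–4 | 4,000 |

Centers are built from each other so the scenarios share known structure:
center 1 $\sim \mathcal N(0, 10^2)$ per coordinate; center 2 = center 1 +
$v_2$ with $v_2 \sim \mathcal N(0, 2^2)$; center 3 = midpoint of centers
1–2 plus $\mathcal N(0, 5^2)$ noise; center 4 = center 3 + $v_2/2$ +
$\mathcal N(0, 2^2)$ — repeating the 1→2 relationship at half scale.
Points are $\mathcal N(\text{center}, 5^2)$ per coordinate, 1,000 per
cluster. A single seed drives separate substreams for the centers, each
cluster's points, and the uniform noise, so C ⊂ D ⊂ E share clusters 1–2
verbatim. The uniform draw is half-open $[0, 10)$ — immaterial at this
scale, fixed for determinism.

The companion sweep clusters each dataset with k-means for k = 1…8
(Lloyd's algorithm, 10 uniform-random restarts kept by within-cluster sum
of squares, at most 100 iterations; labels 1-based); the iris example uses
k = 1…5 with the same settings.

**What the generator does and does not emulate.** It produces the
geometry of the study design — isotropic Gaussian clusters with known,
partially overlapping centers — not the properties of real expression
data (counts, sparsity, library-size effects, correlated features).
Passing behaviour tests on these scenarios demonstrates the *tree
machinery* (multi-parent nodes appear under overclustering, stability
stays low without structure, distinct branches persist), not performance
on any particular biological dataset.

An important consequence of the stated center recipe: centers 1 and 2
differ by $\|v_2\| \approx 2\sqrt{100} = 20$ while points scatter with
sd 5 per coordinate, so along the separating direction the two clusters
sit only $4\sigma$ apart. Even the optimal nearest-center rule then
misassigns about $\Phi(-2) \approx 2.3\%$ of points in each such pair
(the same holds for clusters 3–4). Measured over ten seeds, k-means at
the true k reaches ARI ≈ 0.85–0.92 on scenario C and ≈ 0.93–0.96 on
scenario E — genuine cluster overlap, not an optimisation failure, and
the same overlap that keeps the stability index low on scenario C and
lets overclustered sub-branches trade samples.

## Problem sizes used in checks

The built-in verification (`scripts/acceptance.py` and the study-condition
tests) uses 200 random assignment sets of up to 500 samples and 6
resolutions for the conservation laws, ten replicate seeds per scenario
for the simulation behaviours, full k = 1…8 sweeps on scenarios A/B/C,
single-k fits for the recovery measurements, and the bundled 150-sample
iris sweep — sizes at which every quantity is recomputed from scratch in
seconds.

## Numerical and degenerate-input choices

* Missing assignments are rejected, never imputed — the conservation
  invariants require total assignment. Errors name the offending row and
  column.
* Duplicate sample IDs and duplicate (or non-increasing) resolution
  values are errors.
* Resolution columns are recognised by prefix + numeric suffix and sorted
  numerically (`res.0.5` before `res.1`); a prefix match with a
  non-numeric suffix is an error rather than silently treated as
  metadata.
* A single-resolution set builds a tree with nodes and no edges; the
  stability index requires $R \ge 2$ and says so.
* `in_proportion` with an empty target is an invariant violation (empty
  nodes cannot exist); count > target size is an input error.
* All tie-breaks (core-edge choice, barycenter ordering, label ordering)
  are deterministic, so identical inputs give byte-identical tables and
  figures.

## Known limitations

* Only hard clusterings: no soft/fuzzy memberships, and no direct
  ingestion of single-cell container formats (export the assignment
  columns to CSV first).
* The tree compares *adjacent* resolutions only; a cluster that dissolves
  and re-forms two layers apart appears as two unrelated branches.
* The stability index inherits the overlap structure of the clusterings
  it is given; it cannot distinguish "unstable data" from "unstable
  algorithm".
* The layered layout is a heuristic; crossing minimisation is NP-hard in
  general, and the reported crossing count is the achieved one, not a
  certified optimum.
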