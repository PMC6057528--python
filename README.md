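# clustertree

**Visualize how clusters split — and how samples flow — across clustering
resolutions.**

Choosing the number of clusters is one of the recurring headaches of
exploratory data analysis, and nowhere more so than in single-cell
RNA-sequencing, where the "right" number of cell types is rarely known in
advance. Rather than condensing the choice into a single score, a
*clustering tree* shows the relationships between all the clusterings at
once: cluster the same samples at several resolutions (k-means with
k = 1…8, graph clustering at resolutions 0.1…1.0, …), draw one node per
cluster per resolution, and connect clusters at adjacent resolutions that
share samples. Distinct, stable branches suggest real structure; clusters
assembled from pieces of many parents suggest overclustering.

This package builds, scores, lays out, exports, and renders such trees for
any hard clustering, plus the synthetic benchmark scenarios used to study
their behaviour.

## The model

Given assignments of $N$ samples at resolutions $k_1 < k_2 < \dots < k_R$,
each cluster $c_{k,i}$ becomes a node. For every pair of adjacent
resolutions, the overlap of $c_{k,i}$ and $c_{k+1,j}$ is the number of
samples assigned to both. Each nonzero overlap is a directed edge weighted
by the **in-proportion**

$$p = \frac{|c_{k,i} \cap c_{k+1,j}|}{|c_{k+1,j}|},$$

the fraction of the *destination* cluster that arrived along the edge —
the edge's importance to the new cluster, independent of cluster size.
Low-count and low-$p$ edges can be filtered out (defaults: keep every edge
with count > 0 and $p > 0.1$). Because a node may legitimately have
several parents, the result is a **polytree** (a DAG whose undirected
skeleton is a tree), not a strict tree.

Each node's single highest-$p$ in-edge is its **core edge**; the core
subgraph is a forest used for the tidy (Reingold–Tilford) layout, while a
Sugiyama-style layered layout with barycenter + transposition sweeps
minimizes edge crossings when all edges matter. Nodes can be coloured by
resolution, by any aggregated per-sample attribute (mean marker-gene
expression, mean petal length, …), or by an SC3-style **stability index**

$$s(c) = \frac{1}{R-1}\sum_{k' \ne k}\; \frac{1}{N_{k'}^2} \sum_{j \in J_{k'}} \frac{|c \cap j|}{|j|},$$

where $J_{k'}$ are the clusters at resolution $k'$ sharing samples with
$c$ and $N_{k'} = |J_{k'}|$: a cluster whose sample set recurs intact
everywhere scores 1, one smeared across many clusters scores near 0.

## Worked example: the iris flowers

The package bundles the classic iris table (150 flowers, 4 measurements,
3 species) with a k-means sweep for k = 1…5:

```python
from clustertree import load_iris_clusterings, build_tree, sc3_stability

cs, meta = load_iris_clusterings()
tree = build_tree(cs)          # count_filter=0, prop_filter=0.1
nodes, edges = tree.to_frames()
print(edges.to_string(index=False))
```

```
source target  count  in_proportion  is_core
   1C1    2C1     97       1.000000     True
   1C1    2C2     53       1.000000     True
   2C1    3C1     59       0.951613     True
   2C1    3C3     38       1.000000     True
   2C2    3C2     50       1.000000     True
   3C1    4C2     27       1.000000     True
   3C1    4C3     35       0.853659     True
   3C2    4C1     50       1.000000     True
   3C3    4C3      6       0.146341    False
   3C3    4C4     32       1.000000     True
   4C1    5C4     50       1.000000     True
   4C2    5C2     27       0.964286     True
   4C3    5C1     36       1.000000     True
   4C3    5C5      4       0.166667    False
   4C4    5C3     12       1.000000     True
   4C4    5C5     20       0.833333     True
```

Read the `2C2` row downward: one k = 2 cluster passes 50 samples to `3C2`
with in-proportion 1.0, then to `4C1` and `5C4`, always whole — a branch
that never changes as resolution increases. That branch is *Iris setosa*:
colouring nodes by mean petal length
(`aggregate_node_attribute(cs, meta, "petal_length", "mean")`) gives it the
smallest value at k = 3 (1.462 cm vs. longer petals elsewhere), exactly the
feature known to separate the species. Meanwhile `4C3` receives samples
from two parents (35 + 6) — the first sign of overclustering on the other
side of the tree. The stability index agrees:

```python
print({k: round(v, 3) for k, v in sc3_stability(cs).items() if k.startswith("3C")})
# {'3C1': 0.315, '3C2': 0.819, '3C3': 0.29}
```

The setosa cluster `3C2` is far more stable than its neighbours.

The same workflow runs from the shell, including on the built-in benchmark
scenarios (uniform noise, and 1–4 Gaussian clusters in 100 dimensions):

```bash
clustertree simulate E --seed 1 --out - \
  | clustertree cluster - --ks 1..8 --seed 1 --out assignments.csv
clustertree build assignments.csv --out-dir tree_out --graphml tree.graphml
clustertree stability assignments.csv --out scores.tsv
clustertree plot assignments.csv --node-color-by sc3_stability --out tree.svg
```

`build` writes `nodes.tsv` / `edges.tsv` (round-trippable), GraphML and
DOT; `plot` renders deterministic SVG/PNG figures with legends for every
mapped channel.

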