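"""Layered layouts for clustering trees.

Both algorithms place every node of one resolution on one horizontal layer,
with the lowest resolution at the top (y = -resolution_index, so y decreases
as resolution increases):

* ``layout_tree`` — classic Reingold-Tilford tidy-tree placement run on the
  core-edge forest (each node hangs under its single highest in-proportion
  parent); non-core edges are still drawn but do not influence placement.
* ``layout_sugiyama`` — a layered DAG layout: layers are fixed by resolution,
  and within-layer orderings are improved by iterative barycenter sweeps to
  reduce edge crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ClusteringTree, label_sort_key
from .errors import ClusterTreeError

__all__ = ["LayoutResult", "layout_tree", "layout_sugiyama", "count_crossings"]


@dataclass
class LayoutResult:
    """Node coordinates in abstract plot units plus the achieved crossing count."""

    positions: dict[str, tuple[float, float]]
    algorithm: str
    crossings: int


def _layers(tree: ClusteringTree) -> list[list[str]]:
    """Node ids grouped by resolution index, in tree (label-sorted) order."""
    layers: list[list[str]] = [[] for _ in tree.resolutions]
    for n in tree.nodes:
        layers[tree.resolutions.index(n.resolution)].append(n.node_id)
    return layers


def count_crossings(
    orders: Sequence[Sequence[str]], edges: Iterable[tuple[str, str]]
) -> int:
    """Number of crossing edge pairs given per-layer left-to-right orderings.

    Two edges between the same pair of adjacent layers cross when their
    endpoints appear in opposite relative order on the two layers.
    """
    pos: dict[str, tuple[int, int]] = {}
    for layer_idx, layer in enumerate(orders):
        for x, node in enumerate(layer):
            pos[node] = (layer_idx, x)
    placed: dict[int, list[tuple[int, int]]] = {}
    for src, tgt in edges:
        if src not in pos:
            raise ClusterTreeError(f"unknown node {src!r} in edge list")
        if tgt not in pos:
            raise ClusterTreeError(f"unknown node {tgt!r} in edge list")
        (l_src, x_src), (l_tgt, x_tgt) = pos[src], pos[tgt]
        placed.setdefault(min(l_src, l_tgt), []).append(
            (x_src, x_tgt) if l_src <= l_tgt else (x_tgt, x_src)
        )
    crossings = 0
    for pairs in placed.values():
        for i in range(len(pairs)):
            a1, b1 = pairs[i]
            for j in range(i + 1, len(pairs)):
                a2, b2 = pairs[j]
                if (a1 - a2) * (b1 - b2) < 0:
                    crossings += 1
    return crossings


# ---------------------------------------------------------------------------
# Reingold-Tilford on the core forest
# ---------------------------------------------------------------------------


def layout_tree(tree: ClusteringTree) -> LayoutResult:
    """Tidy-tree placement of the core forest.

    Subtrees are placed post-order with per-layer contours keeping sibling
    subtrees at least one unit apart; each parent is centred over its
    children.  Roots (lowest-resolution nodes and nodes whose in-edges were
    all filtered out) are packed side by side.  The reported crossing count
    is over all drawn (filtered) edges.
    """
    children: dict[str, list[str]] = {}
    has_core_parent: set[str] = set()
    for e in tree.core_edge_list():
        children.setdefault(e.source, []).append(e.target)
        has_core_parent.add(e.target)
    for kids in children.values():
        kids.sort(key=lambda nid: label_sort_key(tree.node(nid).label))

    depth = {n.node_id: tree.resolutions.index(n.resolution) for n in tree.nodes}
    roots = sorted(
        (n.node_id for n in tree.nodes if n.node_id not in has_core_parent),
        key=lambda nid: (depth[nid], label_sort_key(tree.node(nid).label)),
    )

    def place(node: str) -> tuple[dict[str, float], dict[int, tuple[float, float]]]:
        """Return subtree x-positions and per-layer (min, max) contour."""
        kids = children.get(node, [])
        if not kids:
            return {node: 0.0}, {depth[node]: (0.0, 0.0)}
        xs: dict[str, float] = {}
        contour: dict[int, tuple[float, float]] = {}
        kid_xs: list[float] = []
        for kid in kids:
            kxs, kcont = place(kid)
            shared = [d for d in kcont if d in contour]
            shift = max((contour[d][1] - kcont[d][0] + 1.0 for d in shared), default=0.0)
            for nid, x in kxs.items():
                xs[nid] = x + shift
            for d, (lo, hi) in kcont.items():
                if d in contour:
                    contour[d] = (min(contour[d][0], lo + shift), max(contour[d][1], hi + shift))
                else:
                    contour[d] = (lo + shift, hi + shift)
            kid_xs.append(xs[kid])
        px = sum(kid_xs) / len(kid_xs)
        xs[node] = px
        d0 = depth[node]
        lo, hi = contour.get(d0, (px, px))
        contour[d0] = (min(lo, px), max(hi, px))
        return xs, contour

    positions: dict[str, tuple[float, float]] = {}
    forest_contour: dict[int, tuple[float, float]] = {}
    for root in roots:
        rxs, rcont = place(root)
        shared = [d for d in rcont if d in forest_contour]
        shift = max(
            (forest_contour[d][1] - rcont[d][0] + 1.0 for d in shared), default=0.0
        )
        for nid, x in rxs.items():
            positions[nid] = (x + shift, -float(depth[nid]))
        for d, (lo, hi) in rcont.items():
            if d in forest_contour:
                forest_contour[d] = (
                    min(forest_contour[d][0], lo + shift),
                    max(forest_contour[d][1], hi + shift),
                )
            else:
                forest_contour[d] = (lo + shift, hi + shift)

    orders = [
        [nid for nid in sorted(layer, key=lambda n: positions[n][0])]
        for layer in _layers(tree)
    ]
    crossings = count_crossings(orders, [(e.source, e.target) for e in tree.edges])
    return LayoutResult(positions=positions, algorithm="tree", crossings=crossings)


# ---------------------------------------------------------------------------
# Sugiyama-style layered layout (barycenter heuristic)
# ---------------------------------------------------------------------------


def layout_sugiyama(
    tree: ClusteringTree, sweeps: int = 20, core_only: bool = False
) -> LayoutResult:
    """Layered layout with barycenter crossing reduction.

    Each sweep reorders every layer top-down by the mean position of
    neighbours in the layer above, then bottom-up by neighbours below
    (stable sorts, so ties keep the previous order), followed by the classic
    adjacent-transposition refinement (swaps of neighbouring nodes kept only
    when they reduce crossings).  A sweep is accepted only if it strictly
    reduces the crossing count; otherwise the previous ordering is kept and
    the sweeps stop.  ``core_only`` restricts the edges driving the ordering
    (and the reported count) to core edges.
    """
    if sweeps < 1:
        raise ClusterTreeError(f"sweeps must be >= 1, got {sweeps}")
    edges = [
        (e.source, e.target)
        for e in (tree.core_edge_list() if core_only else tree.edges)
    ]
    orders = _layers(tree)
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for src, tgt in edges:
        up.setdefault(tgt, []).append(src)
        down.setdefault(src, []).append(tgt)

    def barycenter_pass(orders: list[list[str]], downward: bool) -> list[list[str]]:
        orders = [list(layer) for layer in orders]
        rng = range(1, len(orders)) if downward else range(len(orders) - 2, -1, -1)
        neighbours = up if downward else down
        for li in rng:
            ref = orders[li - 1] if downward else orders[li + 1]
            ref_pos = {nid: x for x, nid in enumerate(ref)}
            cur_pos = {nid: x for x, nid in enumerate(orders[li])}

            def key(nid: str) -> float:
                nbrs = [ref_pos[m] for m in neighbours.get(nid, []) if m in ref_pos]
                return sum(nbrs) / len(nbrs) if nbrs else float(cur_pos[nid])

            orders[li] = sorted(orders[li], key=key)  # stable: ties keep order
        return orders

    def transpose_pass(orders: list[list[str]]) -> list[list[str]]:
        """Adjacent-swap hill climbing, the classic refinement after barycenter."""
        orders = [list(layer) for layer in orders]
        current = count_crossings(orders, edges)
        improved = True
        while improved:
            improved = False
            for layer in orders:
                for i in range(len(layer) - 1):
                    layer[i], layer[i + 1] = layer[i + 1], layer[i]
                    score = count_crossings(orders, edges)
                    if score < current:
                        current = score
                        improved = True
                    else:
                        layer[i], layer[i + 1] = layer[i + 1], layer[i]
        return orders

    best = count_crossings(orders, edges)
    for _ in range(sweeps):
        candidate = barycenter_pass(barycenter_pass(orders, downward=True), downward=False)
        candidate = transpose_pass(candidate)
        score = count_crossings(candidate, edges)
        if score < best:
            orders, best = candidate, score
        else:
            break

    positions: dict[str, tuple[float, float]] = {}
    for li, layer in enumerate(orders):
        offset = (len(layer) - 1) / 2.0
        for x, nid in enumerate(layer):
            positions[nid] = (x - offset, -float(li))
    return LayoutResult(positions=positions, algorithm="sugiyama", crossings=best)
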