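"""Build clustering trees from multi-resolution hard cluster assignments.

A clustering tree summarises how a set of samples is partitioned at a series
of increasing clustering resolutions (e.g. k-means with k = 1..8, or graph
clustering at several resolution parameters).  Each cluster at each
resolution becomes a node; an edge connects a cluster at one resolution to a
cluster at the next whenever they share samples.  Edges are weighted by the
*in-proportion*: the fraction of the higher-resolution cluster's samples that
arrive along that edge.  Because samples can flow into a cluster from several
lower-resolution clusters, the resulting graph is a polytree (a DAG whose
undirected skeleton is a tree) rather than a strict tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ClusterTreeError, InvariantError

__all__ = [
    "ClusteringSet",
    "ClusterNode",
    "ClusterEdge",
    "ClusteringTree",
    "compute_overlaps",
    "in_proportion",
    "build_tree",
    "core_edges",
    "label_sort_key",
    "format_resolution",
]


def format_resolution(value: float) -> str:
    """Render a resolution value compactly (``1`` not ``1.0``, ``0.1`` as is)."""
    return f"{value:g}"


def node_id_for(resolution: float, label: str) -> str:
    """Canonical node identifier ``{resolution}C{label}``."""
    return f"{format_resolution(resolution)}C{label}"


def label_sort_key(label: str) -> tuple[int, float, str]:
    """Sort key ordering labels numerically when possible, else lexicographically.

    Numeric labels sort before non-numeric ones so that k-means style labels
    (``1``, ``2``, ... or ``0``, ``1``, ...) order naturally while arbitrary
    string labels remain deterministic.
    """
    try:
        return (0, float(label), str(label))
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


@dataclass(frozen=True)
class ClusteringSet:
    """Hard cluster assignments of one sample set at several resolutions.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers, length ``n_samples``.
    resolutions
        Strictly increasing resolution values, one per assignment column.
    assignments
        ``n_samples x R`` array of cluster labels (stored as strings; labels
        are opaque tokens and need not be consecutive or numeric).
    prefix
        Column-name prefix the resolutions were parsed from (``"K"`` for
        ``K1..K8``); purely provenance.
    """

    sample_ids: tuple[str, ...]
    resolutions: tuple[float, ...]
    assignments: np.ndarray
    prefix: str = "K"

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        if len(set(ids)) != len(ids):
            raise ClusterTreeError("duplicate sample IDs in ClusteringSet")
        res = tuple(float(r) for r in self.resolutions)
        object.__setattr__(self, "resolutions", res)
        if len(res) < 1:
            raise ClusterTreeError("a ClusteringSet needs at least one resolution")
        if any(not np.isfinite(r) for r in res):
            raise ClusterTreeError("resolutions must be finite numbers")
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ClusterTreeError(f"resolutions must be strictly increasing, got {res}")
        arr = np.asarray(self.assignments, dtype=object)
        if arr.ndim != 2 or arr.shape != (len(ids), len(res)):
            raise ClusterTreeError(
                f"assignments must be {len(ids)} x {len(res)}, got shape {arr.shape}"
            )
        for col in range(arr.shape[1]):
            for row in range(arr.shape[0]):
                v = arr[row, col]
                if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
                    raise ClusterTreeError(
                        f"missing assignment for sample {ids[row]!r} "
                        f"at resolution {format_resolution(res[col])}"
                    )
        arr = arr.astype(str)
        arr.flags.writeable = False
        object.__setattr__(self, "assignments", arr)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_resolutions(self) -> int:
        return len(self.resolutions)

    def labels_at(self, index: int) -> np.ndarray:
        """Label vector (length ``n_samples``) at resolution index ``index``."""
        return self.assignments[:, index]

    def to_frame(self) -> pd.DataFrame:
        """Assignments as a DataFrame indexed by sample ID, one column per resolution."""
        cols = [f"{self.prefix}{format_resolution(r)}" for r in self.resolutions]
        return pd.DataFrame(
            self.assignments, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, resolutions: Sequence[float], prefix: str = "K"
    ) -> "ClusteringSet":
        """Build from a DataFrame whose columns are already ordered by resolution."""
        return cls(
            sample_ids=tuple(str(i) for i in frame.index),
            resolutions=tuple(resolutions),
            assignments=frame.to_numpy(dtype=object),
            prefix=prefix,
        )


@dataclass
class ClusterNode:
    """One cluster at one resolution: ``c_(k,i)`` with its size and overlays."""

    resolution: float
    label: str
    size: int
    attributes: dict[str, Any] = field(default_factory=dict)

    @property
    def node_id(self) -> str:
        return node_id_for(self.resolution, self.label)


@dataclass
class ClusterEdge:
    """Sample flow between clusters at adjacent resolutions.

    ``in_proportion = count / size(target)`` measures how important the edge
    is to the cluster it points at, independent of cluster size.
    ``is_core`` marks the single highest in-proportion in-edge of the target,
    used for tree layout.
    """

    source: str
    target: str
    count: int
    in_proportion: float
    is_core: bool = False


@dataclass
class ClusteringTree:
    """The filtered polytree of cluster nodes and overlap edges."""

    nodes: list[ClusterNode]
    edges: list[ClusterEdge]
    filters: tuple[int, float]
    resolutions: tuple[float, ...]
    n_samples: int
    prefix: str = "K"

    def __post_init__(self) -> None:
        self._by_id = {n.node_id: n for n in self.nodes}

    def node(self, node_id: str) -> ClusterNode:
        return self._by_id[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._by_id

    def in_edges(self, node_id: str) -> list[ClusterEdge]:
        return [e for e in self.edges if e.target == node_id]

    def out_edges(self, node_id: str) -> list[ClusterEdge]:
        return [e for e in self.edges if e.source == node_id]

    def nodes_at(self, resolution: float) -> list[ClusterNode]:
        return [n for n in self.nodes if n.resolution == resolution]

    def resolution_index(self, node_id: str) -> int:
        return self.resolutions.index(self.node(node_id).resolution)

    def core_edge_list(self) -> list[ClusterEdge]:
        return [e for e in self.edges if e.is_core]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node and edge tables with a fixed, documented column order."""
        attr_cols = sorted({k for n in self.nodes for k in n.attributes})
        node_rows = []
        for n in self.nodes:
            row: dict[str, Any] = {
                "node_id": n.node_id,
                "resolution": n.resolution,
                "label": n.label,
                "size": n.size,
            }
            for a in attr_cols:
                row[a] = n.attributes.get(a)
            node_rows.append(row)
        nodes_df = pd.DataFrame(
            node_rows, columns=["node_id", "resolution", "label", "size", *attr_cols]
        )
        edges_df = pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "count": e.count,
                    "in_proportion": e.in_proportion,
                    "is_core": e.is_core,
                }
                for e in self.edges
            ],
            columns=["source", "target", "count", "in_proportion", "is_core"],
        )
        return nodes_df, edges_df


def compute_overlaps(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> pd.DataFrame:
    """Contingency table of shared-sample counts between two clusterings.

    Rows are the clusters of ``labels_a`` (lower resolution), columns the
    clusters of ``labels_b`` (higher resolution); cell ``(i, j)`` counts the
    samples assigned to both cluster ``i`` and cluster ``j``.  Row sums are
    the cluster sizes at the lower resolution, column sums the sizes at the
    higher one, and the grand total is the number of samples.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ClusterTreeError(
            f"label vectors must have equal length, got {len(a)} and {len(b)}"
        )
    for pos, (va, vb) in enumerate(zip(a, b)):
        for name, v in (("first", va), ("second", vb)):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ClusterTreeError(f"missing label for sample {pos} in {name} vector")
    a = [str(v) for v in a]
    b = [str(v) for v in b]
    rows = sorted(set(a), key=label_sort_key)
    cols = sorted(set(b), key=label_sort_key)
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    return table.reindex(index=rows, columns=cols, fill_value=0)


def in_proportion(count: int, target_size: int) -> float:
    """Edge weight: overlap count divided by the size of the target cluster."""
    if target_size <= 0:
        raise InvariantError("target cluster is empty; empty nodes must not exist")
    if count < 0 or count > target_size:
        raise ClusterTreeError(
            f"overlap count {count} outside [0, target size {target_size}]"
        )
    return count / target_size


def _validate_filters(count_filter: int, prop_filter: float) -> tuple[int, float]:
    if count_filter < 0 or int(count_filter) != count_filter:
        raise ClusterTreeError(f"count_filter must be a non-negative integer, got {count_filter}")
    if not (0.0 <= prop_filter <= 1.0):
        raise ClusterTreeError(f"prop_filter must be in [0, 1], got {prop_filter}")
    return int(count_filter), float(prop_filter)


def build_tree(
    cs: ClusteringSet, count_filter: int = 0, prop_filter: float = 0.1
) -> ClusteringTree:
    """Assemble the clustering tree from a set of assignments.

    One node is created per observed (resolution, label) pair.  For each pair
    of adjacent resolutions, an edge is kept for every nonzero overlap whose
    count is strictly greater than ``count_filter`` *and* whose in-proportion
    is strictly greater than ``prop_filter`` (so the zero thresholds keep all
    nonzero edges).  Core in-edges are marked for layout.
    """
    count_filter, prop_filter = _validate_filters(count_filter, prop_filter)
    nodes: list[ClusterNode] = []
    for r_idx, res in enumerate(cs.resolutions):
        labels, counts = np.unique(cs.labels_at(r_idx), return_counts=True)
        order = sorted(range(len(labels)), key=lambda i: label_sort_key(labels[i]))
        for i in order:
            nodes.append(ClusterNode(resolution=res, label=str(labels[i]), size=int(counts[i])))

    edges: list[ClusterEdge] = []
    for r_idx in range(cs.n_resolutions - 1):
        table = compute_overlaps(cs.labels_at(r_idx), cs.labels_at(r_idx + 1))
        col_sizes = table.sum(axis=0)
        for src_label in table.index:
            for tgt_label in table.columns:
                count = int(table.at[src_label, tgt_label])
                if count == 0:
                    continue
                prop = in_proportion(count, int(col_sizes[tgt_label]))
                if count > count_filter and prop > prop_filter:
                    edges.append(
                        ClusterEdge(
                            source=node_id_for(cs.resolutions[r_idx], src_label),
                            target=node_id_for(cs.resolutions[r_idx + 1], tgt_label),
                            count=count,
                            in_proportion=prop,
                        )
                    )

    tree = ClusteringTree(
        nodes=nodes,
        edges=edges,
        filters=(count_filter, prop_filter),
        resolutions=cs.resolutions,
        n_samples=cs.n_samples,
        prefix=cs.prefix,
    )
    return core_edges(tree)


def core_edges(tree: ClusteringTree) -> ClusteringTree:
    """Mark, for every node with in-edges, its single core in-edge.

    The core edge is the in-edge with maximal in-proportion; ties are broken
    by larger count, then by the smallest source label (numeric labels
    compare numerically).  The core subgraph is therefore a forest whose
    roots are the lowest-resolution nodes plus any node all of whose in-edges
    were filtered away.
    """
    for e in tree.edges:
        e.is_core = False
    by_target: dict[str, list[ClusterEdge]] = {}
    for e in tree.edges:
        by_target.setdefault(e.target, []).append(e)
    for target, in_list in by_target.items():
        best = min(
            in_list,
            key=lambda e: (
                -e.in_proportion,
                -e.count,
                label_sort_key(tree.node(e.source).label),
            ),
        )
        best.is_core = True
    return tree
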