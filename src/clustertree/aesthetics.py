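"""Map node and edge statistics, and per-sample metadata, to visual channels.

Nodes are sized by cluster membership (area proportional to the number of
samples, so radius grows with the square root) and coloured either by
resolution (categorical, one colour per layer), by a per-cluster aggregate of
a sample-level attribute (mean marker-gene expression, mean petal length,
...), or by a stability score.  Edges are coloured by the number of samples
they carry and faded by in-proportion, so edges that matter to their
destination cluster stand out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize, to_hex

from .core import ClusteringSet, ClusteringTree, node_id_for
from .errors import ClusterTreeError
from .layout import LayoutResult

__all__ = ["AestheticSpec", "StyledGraph", "aggregate_node_attribute", "style_graph"]

NUMERIC_AGGREGATES = {"mean", "median", "min", "max", "sum"}
CATEGORICAL_AGGREGATES = {"mode"}

# Edge transparency transfer: in-proportion 0 -> 0.1 (still faintly visible),
# 1 -> fully opaque.
EDGE_ALPHA_FLOOR = 0.1


@dataclass
class AestheticSpec:
    """Which statistic feeds each visual channel."""

    node_size_by: str = "size"
    node_color_by: str = "resolution"  # "resolution", "sc3_stability" or a metadata column
    node_aggregate: str = "mean"
    edge_color_by: str = "count"
    edge_alpha_by: str = "in_proportion"
    continuous_cmap: str = "viridis"  # purple (low) -> yellow (high)
    categorical_cmap: str = "tab10"


@dataclass
class StyledGraph:
    """Render-ready per-node and per-edge style attributes plus legend entries."""

    node_style: dict[str, dict[str, Any]]
    edge_style: dict[tuple[str, str], dict[str, Any]]
    legends: list[dict[str, Any]] = field(default_factory=list)


def aggregate_node_attribute(
    cs: ClusteringSet,
    metadata: pd.DataFrame,
    attribute: str,
    aggregate: str = "mean",
) -> dict[str, float]:
    """Aggregate a per-sample metadata column onto every cluster node.

    Membership is taken from the unfiltered assignments, so every node of the
    full tree receives a value.  Numeric aggregates (mean, median, min, max,
    sum) require a numeric column; ``mode`` requires a categorical one and
    breaks ties by the smallest value.
    """
    if attribute not in metadata.columns:
        raise ClusterTreeError(
            f"unknown attribute {attribute!r}; available columns: "
            + ", ".join(map(str, metadata.columns))
        )
    missing = [s for s in cs.sample_ids if s not in metadata.index]
    if missing:
        raise ClusterTreeError(
            f"metadata missing {len(missing)} sample(s), e.g. {missing[0]!r}"
        )
    col = metadata.loc[list(cs.sample_ids), attribute]
    numeric = pd.api.types.is_numeric_dtype(col)
    if aggregate in NUMERIC_AGGREGATES:
        if not numeric:
            raise ClusterTreeError(
                f"aggregate {aggregate!r} needs a numeric column, but "
                f"{attribute!r} is {col.dtype}"
            )
    elif aggregate in CATEGORICAL_AGGREGATES:
        if numeric:
            raise ClusterTreeError(
                f"aggregate 'mode' is for categorical columns, but {attribute!r} is numeric"
            )
    else:
        raise ClusterTreeError(
            f"unknown aggregate {aggregate!r}; choose from "
            + ", ".join(sorted(NUMERIC_AGGREGATES | CATEGORICAL_AGGREGATES))
        )

    values: dict[str, Any] = {}
    for r_idx, res in enumerate(cs.resolutions):
        groups = col.groupby(cs.labels_at(r_idx))
        if aggregate == "mode":
            agg = groups.agg(lambda s: s.mode().sort_values().iloc[0])
        else:
            agg = groups.agg(aggregate)
        for label, value in agg.items():
            values[node_id_for(res, str(label))] = value
    return values


def _continuous_colors(
    values: Mapping[str, float], cmap_name: str
) -> tuple[dict[str, str], tuple[float, float]]:
    vals = np.asarray(list(values.values()), dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    norm = Normalize(vmin=lo, vmax=hi) if hi > lo else (lambda v: 0.5)
    cmap = colormaps[cmap_name]
    return {k: to_hex(cmap(norm(v))) for k, v in values.items()}, (lo, hi)


def style_graph(
    tree: ClusteringTree,
    layout: LayoutResult,
    spec: AestheticSpec | None = None,
    metadata: pd.DataFrame | None = None,
    cs: ClusteringSet | None = None,
    stability: Mapping[str, float] | None = None,
) -> StyledGraph:
    """Attach size/colour/alpha attributes to a laid-out tree.

    Styling never changes topology: the node and edge sets of the result are
    exactly those of ``tree``.  ``cs`` and ``metadata`` are needed only when
    colouring by a metadata attribute; ``stability`` only for
    ``node_color_by="sc3_stability"``.
    """
    spec = spec or AestheticSpec()
    for n in tree.nodes:
        if n.node_id not in layout.positions:
            raise ClusterTreeError(f"layout is missing node {n.node_id!r}")

    legends: list[dict[str, Any]] = []

    # Node colours
    if spec.node_color_by == "resolution":
        cmap = colormaps[spec.categorical_cmap]
        res_color = {
            res: to_hex(cmap(i % cmap.N)) for i, res in enumerate(tree.resolutions)
        }
        node_color = {n.node_id: res_color[n.resolution] for n in tree.nodes}
        legends.append(
            {"channel": "node_color", "title": "resolution", "kind": "categorical",
             "entries": {f"{r:g}": c for r, c in res_color.items()}}
        )
    elif spec.node_color_by == "sc3_stability":
        if stability is None:
            raise ClusterTreeError(
                "node_color_by='sc3_stability' requires stability scores"
            )
        vals = {n.node_id: float(stability[n.node_id]) for n in tree.nodes}
        node_color, (lo, hi) = _continuous_colors(vals, spec.continuous_cmap)
        legends.append(
            {"channel": "node_color", "title": "SC3 stability", "kind": "continuous",
             "cmap": spec.continuous_cmap, "range": (lo, hi)}
        )
    else:
        if metadata is None or cs is None:
            raise ClusterTreeError(
                f"node_color_by={spec.node_color_by!r} requires metadata and assignments"
            )
        agg = aggregate_node_attribute(cs, metadata, spec.node_color_by, spec.node_aggregate)
        sample = next(iter(agg.values()))
        if isinstance(sample, (int, float, np.integer, np.floating)):
            node_color, (lo, hi) = _continuous_colors(agg, spec.continuous_cmap)
            legends.append(
                {"channel": "node_color",
                 "title": f"{spec.node_aggregate} {spec.node_color_by}",
                 "kind": "continuous", "cmap": spec.continuous_cmap, "range": (lo, hi)}
            )
        else:
            cmap = colormaps[spec.categorical_cmap]
            cats = sorted({str(v) for v in agg.values()})
            cat_color = {c: to_hex(cmap(i % cmap.N)) for i, c in enumerate(cats)}
            node_color = {k: cat_color[str(v)] for k, v in agg.items()}
            legends.append(
                {"channel": "node_color",
                 "title": f"{spec.node_aggregate} {spec.node_color_by}",
                 "kind": "categorical", "entries": cat_color}
            )
        for n in tree.nodes:
            n.attributes[spec.node_color_by] = agg[n.node_id]

    # Node sizes: area proportional to membership -> radius ~ sqrt(size),
    # with a floor so tiny clusters stay visible.
    max_size = max(n.size for n in tree.nodes)
    node_style: dict[str, dict[str, Any]] = {}
    for n in tree.nodes:
        radius = max(0.12, 0.45 * math.sqrt(n.size / max_size))
        x, y = layout.positions[n.node_id]
        node_style[n.node_id] = {
            "x": x, "y": y, "radius": radius, "color": node_color[n.node_id],
            "label": n.label, "size": n.size,
        }
    legends.append(
        {"channel": "node_size", "title": "cluster size", "kind": "size",
         "max_size": max_size}
    )

    # Edge colours by count, alpha by in-proportion.
    edge_style: dict[tuple[str, str], dict[str, Any]] = {}
    if tree.edges:
        counts = {(e.source, e.target): float(e.count) for e in tree.edges}
        edge_color, (clo, chi) = _continuous_colors(counts, spec.continuous_cmap)
        for e in tree.edges:
            key = (e.source, e.target)
            edge_style[key] = {
                "color": edge_color[key],
                "alpha": EDGE_ALPHA_FLOOR + (1.0 - EDGE_ALPHA_FLOOR) * e.in_proportion,
                "is_core": e.is_core,
                "count": e.count,
                "in_proportion": e.in_proportion,
            }
        legends.append(
            {"channel": "edge_color", "title": "sample count", "kind": "continuous",
             "cmap": spec.continuous_cmap, "range": (clo, chi)}
        )
        legends.append(
            {"channel": "edge_alpha", "title": "in-proportion", "kind": "alpha",
             "range": (0.0, 1.0)}
        )
    return StyledGraph(node_style=node_style, edge_style=edge_style, legends=legends)
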