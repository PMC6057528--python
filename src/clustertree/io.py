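"""Readers and writers: assignment tables, node/edge tables, GraphML, DOT.

Assignment tables are delimited text (comma for ``.csv``, tab for ``.tsv`` /
``.tab``) with a header.  Resolution columns share a user-given prefix
followed by a numeric suffix (``K1..K8``, ``res.0.1`` ... ``res.5``); all
other columns are returned as per-sample metadata.  Sample identifiers come
from a ``sample_id`` column when present, otherwise from 0-based row order.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core import ClusterEdge, ClusteringSet, ClusteringTree, ClusterNode, format_resolution
from .errors import ClusterTreeError

__all__ = [
    "read_assignments",
    "read_table",
    "write_assignments",
    "export_graph",
    "read_tree_tables",
    "tree_to_networkx",
]

ID_COLUMN = "sample_id"


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table (comma or tab by extension) with header.

    ``"-"`` reads comma-separated text from standard input, so commands can
    be chained in a shell pipeline.
    """
    import sys

    try:
        if str(path) == "-":
            return pd.read_csv(sys.stdin)
        return pd.read_csv(path, sep=_sep_for(path))
    except FileNotFoundError:
        raise ClusterTreeError(f"input file not found: {path}")
    except pd.errors.EmptyDataError:
        raise ClusterTreeError(f"input is empty: {path}")
    except pd.errors.ParserError as exc:
        raise ClusterTreeError(f"could not parse {path}: {exc}")


def parse_resolution_columns(columns: list[str], prefix: str) -> list[tuple[float, str]]:
    """Map header names to (resolution, column) pairs, sorted numerically.

    Every column starting with ``prefix`` must have a numeric suffix;
    ``res.0.1`` parses as 0.1 (a single leading separator ``.`` or ``_``
    after the prefix is tolerated).
    """
    pairs: list[tuple[float, str]] = []
    for col in columns:
        if col == ID_COLUMN or not col.startswith(prefix):
            continue
        suffix = col[len(prefix):]
        trimmed = re.sub(r"^[._]", "", suffix)
        try:
            value = float(trimmed)
        except ValueError:
            raise ClusterTreeError(
                f"column {col!r} matches prefix {prefix!r} but its suffix "
                f"{suffix!r} is not numeric"
            )
        pairs.append((value, col))
    if not pairs:
        raise ClusterTreeError(
            f"no assignment columns found for prefix {prefix!r} "
            f"(available columns: {', '.join(columns)})"
        )
    pairs.sort(key=lambda p: p[0])
    values = [v for v, _ in pairs]
    if len(set(values)) != len(values):
        raise ClusterTreeError(f"duplicate resolution values parsed: {values}")
    return pairs


def read_assignments(
    path: str | Path, prefix: str
) -> tuple[ClusteringSet, pd.DataFrame]:
    """Load a wide assignment table; return the ClusteringSet plus metadata.

    Leftover (non-resolution, non-ID) columns are returned as a metadata
    DataFrame indexed by sample ID, ready for node-attribute overlays.
    """
    df = read_table(path)
    pairs = parse_resolution_columns(list(df.columns), prefix)
    res_cols = [c for _, c in pairs]
    resolutions = [v for v, _ in pairs]

    if ID_COLUMN in df.columns:
        ids = [str(v) for v in df[ID_COLUMN]]
    else:
        ids = [str(i) for i in range(len(df))]
    if len(set(ids)) != len(ids):
        raise ClusterTreeError("duplicate sample IDs in input")

    for col in res_cols:
        na = df[col].isna()
        if na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise ClusterTreeError(f"missing assignment at row {row}, column {col}")

    assignments = df[res_cols].astype(str).to_numpy(dtype=object)
    cs = ClusteringSet(
        sample_ids=tuple(ids),
        resolutions=tuple(resolutions),
        assignments=assignments,
        prefix=prefix,
    )
    meta_cols = [c for c in df.columns if c not in res_cols and c != ID_COLUMN]
    metadata = df[meta_cols].copy()
    metadata.index = pd.Index(ids, name=ID_COLUMN)
    return cs, metadata


def write_assignments(
    cs: ClusteringSet, path: str | Path, metadata: pd.DataFrame | None = None
) -> None:
    """Write a ClusteringSet (plus optional metadata columns) back to disk.

    ``"-"`` writes comma-separated text to standard output.
    """
    import sys

    frame = cs.to_frame().reset_index()
    if metadata is not None:
        extra = metadata.reset_index(drop=True)
        frame = pd.concat([frame, extra], axis=1)
    if str(path) == "-":
        frame.to_csv(sys.stdout, index=False)
    else:
        frame.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Graph export
# ---------------------------------------------------------------------------


def tree_to_networkx(
    tree: ClusteringTree,
    layout: Mapping[str, tuple[float, float]] | None = None,
    stability: Mapping[str, float] | None = None,
) -> nx.DiGraph:
    """Convert a clustering tree to a networkx DiGraph with full attributes."""
    g = nx.DiGraph()
    for n in tree.nodes:
        attrs = {"resolution": float(n.resolution), "label": n.label, "size": n.size}
        for k, v in n.attributes.items():
            attrs[k] = v if not isinstance(v, (np.generic,)) else v.item()
        if stability is not None:
            attrs["sc3_stability"] = float(stability[n.node_id])
        if layout is not None:
            attrs["x"], attrs["y"] = map(float, layout[n.node_id])
        g.add_node(n.node_id, **attrs)
    for e in tree.edges:
        g.add_edge(
            e.source, e.target,
            count=e.count, in_proportion=e.in_proportion, is_core=e.is_core,
        )
    return g


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    def esc(s: str) -> str:
        return '"' + str(s).replace('"', '\\"') + '"'

    lines = ["digraph clustertree {"]
    for nid, attrs in g.nodes(data=True):
        kv = ", ".join(f"{k}={esc(v)}" for k, v in attrs.items())
        lines.append(f"  {esc(nid)} [{kv}];")
    for src, tgt, attrs in g.edges(data=True):
        kv = ", ".join(f"{k}={esc(v)}" for k, v in attrs.items())
        lines.append(f"  {esc(src)} -> {esc(tgt)} [{kv}];")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def export_graph(
    tree: ClusteringTree,
    out: str | Path,
    format: str = "tsv",
    layout: Mapping[str, tuple[float, float]] | None = None,
    stability: Mapping[str, float] | None = None,
) -> list[Path]:
    """Write the tree as node/edge TSVs, GraphML, or Graphviz DOT.

    ``out`` is a directory for ``format="tsv"`` (producing ``nodes.tsv`` and
    ``edges.tsv``) and a file path otherwise.  The TSV pair round-trips: see
    :func:`read_tree_tables`.
    """
    out = Path(out)
    if format == "tsv":
        out.mkdir(parents=True, exist_ok=True)
        nodes_df, edges_df = tree.to_frames()
        if stability is not None:
            nodes_df["sc3_stability"] = [stability[n] for n in nodes_df["node_id"]]
        if layout is not None:
            nodes_df["x"] = [layout[n][0] for n in nodes_df["node_id"]]
            nodes_df["y"] = [layout[n][1] for n in nodes_df["node_id"]]
        header = (
            f"# clustertree; prefix={tree.prefix}; n_samples={tree.n_samples}; "
            f"count_filter={tree.filters[0]}; prop_filter={tree.filters[1]!r}; "
            f"resolutions={','.join(format_resolution(r) for r in tree.resolutions)}\n"
        )
        paths = [out / "nodes.tsv", out / "edges.tsv"]
        for path, df in zip(paths, (nodes_df, edges_df)):
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        return paths
    if format == "graphml":
        g = tree_to_networkx(tree, layout=layout, stability=stability)
        nx.write_graphml(g, out)
        return [out]
    if format == "dot":
        g = tree_to_networkx(tree, layout=layout, stability=stability)
        _write_dot(g, out)
        return [out]
    raise ClusterTreeError(f"unknown export format {format!r} (use tsv, graphml or dot)")


def read_tree_tables(nodes_path: str | Path, edges_path: str | Path) -> ClusteringTree:
    """Rebuild a ClusteringTree from an exported nodes.tsv / edges.tsv pair."""
    with open(nodes_path) as fh:
        header = fh.readline()
    if not header.startswith("# clustertree;"):
        raise ClusterTreeError(f"{nodes_path} is not a clustertree node table")
    meta = dict(
        part.strip().split("=", 1)
        for part in header.removeprefix("# clustertree;").strip().split(";")
    )
    nodes_df = pd.read_csv(nodes_path, sep="\t", comment=None, skiprows=1)
    edges_df = pd.read_csv(edges_path, sep="\t", skiprows=1)

    reserved = {"node_id", "resolution", "label", "size", "x", "y"}
    attr_cols = [c for c in nodes_df.columns if c not in reserved]
    nodes = [
        ClusterNode(
            resolution=float(rec["resolution"]),
            label=str(rec["label"]),
            size=int(rec["size"]),
            attributes={a: rec[a] for a in attr_cols},
        )
        for rec in nodes_df.to_dict("records")
    ]
    edges = [
        ClusterEdge(
            source=str(rec["source"]), target=str(rec["target"]),
            count=int(rec["count"]),
            in_proportion=float(rec["in_proportion"]), is_core=bool(rec["is_core"]),
        )
        for rec in edges_df.to_dict("records")
    ]
    return ClusteringTree(
        nodes=nodes,
        edges=edges,
        filters=(int(meta["count_filter"]), float(meta["prop_filter"])),
        resolutions=tuple(float(v) for v in meta["resolutions"].split(",")),
        n_samples=int(meta["n_samples"]),
        prefix=meta["prefix"],
    )
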