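"""Render a styled clustering tree to SVG or PNG with matplotlib.

The figure follows the conventions of the method's reference figures:
resolutions form horizontal layers (lowest resolution on top), node size
encodes cluster membership, edge colour encodes sample count and edge
transparency the in-proportion.  Output is deterministic: a fixed SVG hash
salt and stripped timestamps make repeated renders byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, FancyArrowPatch
from matplotlib import colormaps
from matplotlib.colors import Normalize
from matplotlib.cm import ScalarMappable

from .aesthetics import StyledGraph
from .core import ClusteringTree, format_resolution
from .errors import ClusterTreeError
from .layout import LayoutResult

__all__ = ["render"]

_SVG_SALT = "clustertree"


def render(
    tree: ClusteringTree,
    layout: LayoutResult,
    styled: StyledGraph,
    out: str | Path,
    show_labels: bool = True,
) -> Path:
    """Draw the tree and write it to ``out`` (.svg or .png by extension)."""
    if not tree.nodes:
        raise ClusterTreeError("cannot render an empty tree")
    out = Path(out)

    with matplotlib.rc_context({"svg.hashsalt": _SVG_SALT}):
        fig, ax = plt.subplots(figsize=(8, 6))
        # Edges first so nodes sit on top; sorted for deterministic z-order.
        for key in sorted(styled.edge_style):
            es = styled.edge_style[key]
            src, tgt = key
            x0, y0 = styled.node_style[src]["x"], styled.node_style[src]["y"]
            x1, y1 = styled.node_style[tgt]["x"], styled.node_style[tgt]["y"]
            ax.add_patch(
                FancyArrowPatch(
                    (x0, y0), (x1, y1),
                    arrowstyle="-|>", mutation_scale=10,
                    color=es["color"], alpha=es["alpha"],
                    linewidth=2.0 if es["is_core"] else 1.2,
                    shrinkA=8, shrinkB=8, zorder=1,
                )
            )
        for nid in sorted(styled.node_style):
            ns = styled.node_style[nid]
            ax.add_patch(
                Circle((ns["x"], ns["y"]), radius=ns["radius"],
                       facecolor=ns["color"], edgecolor="black",
                       linewidth=0.5, zorder=2)
            )
            if show_labels:
                ax.text(ns["x"], ns["y"], str(ns["label"]),
                        ha="center", va="center", fontsize=8, zorder=3)

        # Layer labels on the left margin.
        xs = [ns["x"] for ns in styled.node_style.values()]
        x_min = min(xs) - 1.0
        for li, res in enumerate(tree.resolutions):
            ax.text(x_min, -float(li), f"{tree.prefix}{format_resolution(res)}",
                    ha="right", va="center", fontsize=9, fontweight="bold")

        _draw_legends(fig, ax, styled)
        ax.set_xlim(x_min - 0.5, max(xs) + 1.0)
        ax.set_ylim(-(len(tree.resolutions) - 0.5), 0.75)
        ax.set_aspect("auto")
        ax.axis("off")

        metadata = {"Date": None} if out.suffix.lower() == ".svg" else {}
        fig.savefig(out, metadata=metadata, bbox_inches="tight")
        plt.close(fig)
    return out


def _draw_legends(fig, ax, styled: StyledGraph) -> None:
    handles, labels = [], []
    for legend in styled.legends:
        kind = legend["kind"]
        if kind == "categorical":
            for name, color in legend["entries"].items():
                handles.append(Line2D([], [], marker="o", linestyle="",
                                      markerfacecolor=color, markeredgecolor="black",
                                      markersize=8))
                labels.append(f"{legend['title']} {name}")
        elif kind == "continuous":
            lo, hi = legend["range"]
            sm = ScalarMappable(norm=Normalize(lo, hi), cmap=colormaps[legend["cmap"]])
            cbar = fig.colorbar(sm, ax=ax, fraction=0.04, pad=0.02)
            cbar.set_label(legend["title"], fontsize=8)
            cbar.ax.tick_params(labelsize=7)
        elif kind == "size":
            handles.append(Line2D([], [], marker="o", linestyle="",
                                  markerfacecolor="lightgray", markeredgecolor="black",
                                  markersize=10))
            labels.append(f"size (max {legend['max_size']})")
        elif kind == "alpha":
            handles.append(Line2D([], [], color="gray", alpha=0.4))
            labels.append(legend["title"])
    if handles:
        ax.legend(handles, labels, loc="upper right", fontsize=7, framealpha=0.8)
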