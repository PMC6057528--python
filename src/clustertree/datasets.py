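"""Bundled example data: Fisher's iris measurements with a k-means sweep.

The iris table (150 flowers, 4 measurements, 3 species with 50 flowers each)
is the classic small clustering benchmark: *Iris setosa* is linearly
separable from the other two species, which makes it ideal for illustrating
a branch of the clustering tree that stays intact across resolutions.  The
bundled file also carries pre-computed k-means assignments for k = 1..5
(Lloyd's algorithm, 10 random starts, at most 100 iterations) so examples
and tests need no clustering step.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import ClusteringSet
from .io import read_assignments

__all__ = ["load_iris_clusterings", "iris_path"]

_FIXTURE = "iris_kmeans.csv"


def iris_path():
    """Path-like handle to the bundled iris CSV (for CLI examples)."""
    return resources.files("clustertree") / "data" / _FIXTURE


def load_iris_clusterings() -> tuple[ClusteringSet, pd.DataFrame]:
    """Load the iris fixture.

    Returns the 150-sample ClusteringSet over k = 1..5 plus a metadata table
    with the four measurements (cm) and the species of each flower.
    """
    with resources.as_file(iris_path()) as path:
        return read_assignments(path, prefix="K")
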