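"""Synthetic benchmark datasets for exercising clustering trees.

Five scenarios of 100-dimensional point clouds illustrate how a clustering
tree behaves as true structure is added and as a dataset is overclustered:

* **A** — 1,000 points of pure uniform noise on [0, 10) per coordinate.
* **B** — one Gaussian cluster of 1,000 points.
* **C** — two clusters (clusters 1 and 2).
* **D** — three clusters (1, 2 and 3).
* **E** — four clusters (1-4).

Cluster centers are built from each other so the scenarios share known
structure: center 1 is drawn from N(0, 10^2) per coordinate; center 2 adds a
displacement v2 ~ N(0, 2^2); center 3 is the midpoint of centers 1 and 2
plus N(0, 5^2) noise; and center 4 repeats the 1->2 relationship at half
scale, adding v2/2 plus N(0, 2^2) noise to center 3.  Points are drawn
N(center, 5^2) per coordinate, 1,000 per cluster.

A single integer seed drives independent substreams for the centers and for
each cluster's points, so scenarios C ⊂ D ⊂ E literally share clusters 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import ClusteringSet
from .errors import ClusterTreeError

__all__ = ["Centers", "SimulatedDataset", "make_centers", "simulate_scenario", "kmeans_sweep"]

N_DIMS = 100
POINTS_PER_CLUSTER = 1000
POINT_SD = 5.0
SCENARIO_CLUSTERS = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}

# Fixed substream indices under the user seed: 0 = centers, 1..4 = cluster
# points, 5 = scenario-A uniform noise.
_STREAM_CENTERS = 0
_STREAM_CLUSTER = {1: 1, 2: 2, 3: 3, 4: 4}
_STREAM_UNIFORM = 5


@dataclass(frozen=True)
class Centers:
    """The four cluster centers and the displacement vector reused for center 4."""

    center1: np.ndarray
    center2: np.ndarray
    center3: np.ndarray
    center4: np.ndarray
    v2: np.ndarray

    def as_array(self, n: int) -> np.ndarray:
        return np.vstack([self.center1, self.center2, self.center3, self.center4][:n])


@dataclass(frozen=True)
class SimulatedDataset:
    """Points, generating labels, and the parameters that produced them."""

    points: np.ndarray  # n_points x 100
    true_labels: np.ndarray  # "noise" for scenario A, else "1".."4"
    scenario: str
    seed: int
    centers: Centers | None  # None for the pure-noise scenario


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def make_centers(
    seed: int,
    center_sd: float = 10.0,
    offset_sd: float = 2.0,
    midpoint_sd: float = 5.0,
) -> Centers:
    """Generate the four related cluster centers.

    The standard deviations are exposed mainly as a test hook: with all
    noise scales at zero the construction degenerates to
    center2 = center3 = center4 = center1.
    """
    rng = _rng(seed, _STREAM_CENTERS)
    center1 = rng.normal(0.0, center_sd, N_DIMS)
    v2 = rng.normal(0.0, offset_sd, N_DIMS)
    center2 = center1 + v2
    center3 = (center1 + center2) / 2.0 + rng.normal(0.0, midpoint_sd, N_DIMS)
    center4 = center3 + v2 / 2.0 + rng.normal(0.0, offset_sd, N_DIMS)
    return Centers(center1=center1, center2=center2, center3=center3, center4=center4, v2=v2)


def simulate_scenario(scenario: str, seed: int = 0) -> SimulatedDataset:
    """Generate one of the five benchmark datasets.

    Scenario A is 1,000 x 100 uniform noise on [0, 10); scenarios B-E stack
    1,000-point Gaussian clusters (sd 5 per coordinate) around centers 1..n.
    A fixed (scenario, seed) pair always yields the identical matrix.
    """
    scenario = str(scenario).upper()
    if scenario not in SCENARIO_CLUSTERS:
        raise ClusterTreeError(
            f"unknown scenario {scenario!r}; choose one of A, B, C, D, E"
        )
    if scenario == "A":
        rng = _rng(seed, _STREAM_UNIFORM)
        points = rng.uniform(0.0, 10.0, (POINTS_PER_CLUSTER, N_DIMS))
        labels = np.array(["noise"] * POINTS_PER_CLUSTER)
        return SimulatedDataset(points, labels, scenario, seed, centers=None)

    centers = make_centers(seed)
    n_clusters = SCENARIO_CLUSTERS[scenario]
    blocks, labels = [], []
    for c in range(1, n_clusters + 1):
        rng = _rng(seed, _STREAM_CLUSTER[c])
        center = getattr(centers, f"center{c}")
        blocks.append(rng.normal(center, POINT_SD, (POINTS_PER_CLUSTER, N_DIMS)))
        labels.extend([str(c)] * POINTS_PER_CLUSTER)
    return SimulatedDataset(
        np.vstack(blocks), np.array(labels), scenario, seed, centers=centers
    )


def kmeans_sweep(
    points: np.ndarray,
    ks: list[int] | range = range(1, 9),
    n_starts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
    prefix: str = "K",
) -> ClusteringSet:
    """Cluster a point matrix with k-means over a range of k.

    Lloyd's algorithm with ``n_starts`` uniform-random restarts per k (best
    run by within-cluster sum of squares) and at most ``max_iter``
    iterations.  Cluster labels are 1-based; resolutions are the k values.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ClusterTreeError("points must be a non-empty 2-D matrix")
    ks = sorted(int(k) for k in ks)
    if not ks or ks[0] < 1:
        raise ClusterTreeError("ks must be positive integers")
    if ks[-1] > points.shape[0]:
        raise ClusterTreeError(
            f"k={ks[-1]} exceeds the number of points ({points.shape[0]})"
        )
    columns = []
    child_seeds = np.random.SeedSequence(seed, spawn_key=(6,)).generate_state(len(ks))
    for i, k in enumerate(ks):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=n_starts,
            max_iter=max_iter,
            algorithm="lloyd",
            random_state=int(child_seeds[i]) % (2**31),
        )
        columns.append(km.fit_predict(points) + 1)  # 1-based labels
    assignments = np.stack([c.astype(str) for c in columns], axis=1)
    return ClusteringSet(
        sample_ids=tuple(str(i) for i in range(points.shape[0])),
        resolutions=tuple(float(k) for k in ks),
        assignments=assignments,
        prefix=prefix,
    )
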