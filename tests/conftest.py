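"""Shared fixtures: random assignment sets and cached simulation sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from clustertree.core import ClusteringSet
from clustertree.simulate import kmeans_sweep, simulate_scenario

N_BEHAVIOR_SEEDS = 10  # seeds per scenario for figure-level behaviour checks


def random_clustering_set(
    rng: np.random.Generator,
    n_samples: int | None = None,
    n_resolutions: int | None = None,
    max_clusters: int = 8,
) -> ClusteringSet:
    """A random ClusteringSet with roughly increasing cluster counts."""
    n = n_samples or int(rng.integers(5, 501))
    R = n_resolutions or int(rng.integers(1, 7))
    cols = []
    for r in range(R):
        k = int(rng.integers(1, min(max_clusters, n) + 1))
        labels = rng.integers(0, k, n).astype(str)
        cols.append(labels)
    return ClusteringSet(
        sample_ids=tuple(str(i) for i in range(n)),
        resolutions=tuple(float(r + 1) for r in range(R)),
        assignments=np.stack(cols, axis=1),
    )


@pytest.fixture(scope="session")
def noise_sweeps():
    """k-means sweeps (k=1..8) of scenarios A and B over ten seeds.

    Shared by the stability and overclustering-behaviour tests, which probe
    the same study conditions from two angles.
    """
    sweeps = {}
    for scenario in ("A", "B"):
        for seed in range(N_BEHAVIOR_SEEDS):
            ds = simulate_scenario(scenario, seed=seed)
            sweeps[(scenario, seed)] = kmeans_sweep(
                ds.points, ks=range(1, 9), n_starts=10, max_iter=100, seed=seed
            )
    return sweeps
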