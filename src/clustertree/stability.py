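"""Per-cluster stability index in the style of the SC3 consensus-clustering score.

A cluster is stable if its sample set recurs (largely intact) as a cluster at
the other resolutions; it is penalised when its samples are spread over many
clusters elsewhere.  For cluster ``c`` at resolution ``k``, let ``J(k')`` be
the clusters at another resolution ``k'`` that share at least one sample with
``c`` and ``N = |J(k')|``.  The score is

    s(c) = (1 / (R - 1)) * sum_{k' != k} sum_{j in J(k')} |c ∩ j| / (|j| * N^2)

which lies in [0, 1] and equals 1 exactly when ``c``'s sample set appears as
one whole cluster at every other resolution.  The original SC3 index is
defined for consecutive integer k; here resolutions may be arbitrary numbers
(e.g. graph-clustering resolutions 0.1 ... 1.0), so the default normaliser is
the number of *other* resolutions, R - 1.  ``normalizer="span"`` divides by
the resolution range ``max - min`` instead, mirroring the integer-k
convention.
"""

from __future__ import annotations

import numpy as np

from .core import ClusteringSet, node_id_for
from .errors import ClusterTreeError

__all__ = ["sc3_stability"]


def sc3_stability(cs: ClusteringSet, normalizer: str = "count") -> dict[str, float]:
    """Score every cluster node of a ClusteringSet.

    Parameters
    ----------
    cs
        The (unfiltered) multi-resolution assignments; needs R >= 2.
    normalizer
        ``"count"`` divides by R - 1 (default, resolution-scale free);
        ``"span"`` divides by ``max(resolutions) - min(resolutions)``.

    Returns
    -------
    dict
        ``node_id -> score`` with scores in [0, 1].
    """
    R = cs.n_resolutions
    if R < 2:
        raise ClusterTreeError("stability undefined for a single resolution")
    if normalizer == "count":
        norm = R - 1
    elif normalizer == "span":
        norm = cs.resolutions[-1] - cs.resolutions[0]
    else:
        raise ClusterTreeError(f"unknown normalizer {normalizer!r}")

    # Pre-index sample memberships per resolution.
    members: list[dict[str, np.ndarray]] = []
    for r in range(R):
        labels = cs.labels_at(r)
        idx: dict[str, list[int]] = {}
        for pos, lab in enumerate(labels):
            idx.setdefault(lab, []).append(pos)
        members.append({lab: np.asarray(pos_list) for lab, pos_list in idx.items()})

    scores: dict[str, float] = {}
    for k in range(R):
        for lab, member_idx in members[k].items():
            member_set = set(member_idx.tolist())
            total = 0.0
            for kp in range(R):
                if kp == k:
                    continue
                overlaps: list[tuple[int, int]] = []  # (|c ∩ j|, |j|)
                for jlab, jidx in members[kp].items():
                    shared = sum(1 for p in jidx.tolist() if p in member_set)
                    if shared:
                        overlaps.append((shared, len(jidx)))
                n_shared = len(overlaps)
                total += sum(sh / jsz for sh, jsz in overlaps) / (n_shared**2)
            scores[node_id_for(cs.resolutions[k], lab)] = total / norm
    return scores
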