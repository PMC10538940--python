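"""Taylor-Butina leader clustering and cluster-based diversity statistics.

Taylor-Butina clustering takes a Tanimoto distance threshold and groups
compounds so that every cluster member lies within that threshold of its
cluster centroid.  The algorithm is order-dependent in general; here the
candidate order is fixed canonically (descending neighbor count, ties by id
ascending) so the partition is deterministic and invariant to input order.

The diversity statistics quantify how chemically varied a hit list is:
*unique cluster hits* counts clusters touched by at least one hit, *novel
cluster hits* counts clusters touched by hits but by no previously known
active, i.e. genuinely new chemotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprints import Fingerprint, bulk_tanimoto_similarity, to_dense_matrix

__all__ = [
    "ClusterAssignment",
    "taylor_butina",
    "unique_cluster_hits",
    "novel_cluster_hits",
    "DEFAULT_ACTIVITY_CATEGORIES",
    "category_cluster_table",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of a compound set at a stated Tanimoto distance threshold."""

    cluster_of: Mapping[str, int]
    centroid_of: Mapping[int, str]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_of)

    def members_of(self, cluster: int) -> list[str]:
        return [cid for cid, c in self.cluster_of.items() if c == cluster]

    def clusters_of(self, ids) -> set[int]:
        missing = [cid for cid in ids if cid not in self.cluster_of]
        if missing:
            raise ValueError(f"{len(missing)} ids not in the clustering (e.g. {missing[0]!r})")
        return {self.cluster_of[cid] for cid in ids}


def taylor_butina(
    fingerprints: Sequence[tuple[str, Fingerprint]],
    threshold: float,
    block: int = 1024,
) -> ClusterAssignment:
    """Cluster fingerprints with the canonical Taylor-Butina procedure.

    Neighbor relation: Tanimoto distance <= threshold (inclusive).
    Candidates are ordered by descending neighbor count (ties: id
    ascending); each unassigned candidate in turn becomes a centroid and
    absorbs its still-unassigned neighbors.  Compounds never absorbed end
    up as singleton clusters (their own centroids).
    """
    if not fingerprints:
        raise ValueError("empty input")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ids = [cid for cid, _ in fingerprints]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    mat = to_dense_matrix([fp for _, fp in fingerprints])
    n = len(ids)
    sim_cut = 1.0 - threshold

    neighbors: list[np.ndarray] = []
    for start in range(0, n, block):
        stop = min(start + block, n)
        sim = bulk_tanimoto_similarity(mat[start:stop], mat)
        # guard against float rounding at the threshold boundary
        hit = sim >= sim_cut - 1e-9
        for i in range(stop - start):
            row = np.flatnonzero(hit[i])
            neighbors.append(row[row != start + i])

    candidate_order = sorted(range(n), key=lambda i: (-len(neighbors[i]), ids[i]))
    cluster_of: dict[str, int] = {}
    centroid_of: dict[int, str] = {}
    assigned = np.zeros(n, dtype=bool)
    next_cluster = 0
    for i in candidate_order:
        if assigned[i]:
            continue
        centroid_of[next_cluster] = ids[i]
        cluster_of[ids[i]] = next_cluster
        assigned[i] = True
        for j in neighbors[i]:
            if not assigned[j]:
                cluster_of[ids[j]] = next_cluster
                assigned[j] = True
        next_cluster += 1
    return ClusterAssignment(cluster_of=cluster_of, centroid_of=centroid_of, threshold=threshold)


def unique_cluster_hits(clusters: ClusterAssignment, hits: set) -> int:
    """Number of clusters containing at least one hit."""
    return len(clusters.clusters_of(hits))


def novel_cluster_hits(clusters: ClusterAssignment, hits: set, known_actives: set) -> int:
    """Number of clusters containing hits but no previously known active."""
    hit_clusters = clusters.clusters_of(hits)
    known_clusters = clusters.clusters_of(known_actives)
    return len(hit_clusters - known_clusters)


# (label, lower bound inclusive, upper bound exclusive) on median % inhibition
DEFAULT_ACTIVITY_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("weak", 35.0, 50.0),
    ("moderate", 50.0, 75.0),
    ("strong", 75.0, math.inf),
)


def category_cluster_table(
    clusters: ClusterAssignment,
    inhibition_by_id: Mapping[str, float],
    categories: Sequence[tuple[str, float, float]] = DEFAULT_ACTIVITY_CATEGORIES,
) -> pd.DataFrame:
    """Cluster-by-potency-category contingency table of active compounds.

    ``inhibition_by_id`` maps each active compound to its median
    % inhibition.  Cell (c, g) counts category-g actives in cluster c; the
    grand total equals the number of actives.  The returned frame is ready
    for a standard exact association test.
    """
    labels = [lab for lab, _, _ in categories]
    lows = [lo for _, lo, _ in categories]
    for i in range(1, len(categories)):
        if categories[i][1] != categories[i - 1][2]:
            raise ValueError("category bins must be contiguous and ordered")
    counts: dict[int, dict[str, int]] = {}
    for cid, inhib in inhibition_by_id.items():
        if cid not in clusters.cluster_of:
            raise ValueError(f"active {cid!r} is not clustered")
        if inhib < lows[0]:
            raise ValueError(f"active {cid!r} has % inhibition {inhib} below the lowest bin")
        cat = None
        for lab, lo, hi in categories:
            if lo <= inhib < hi:
                cat = lab
                break
        assert cat is not None
        row = counts.setdefault(clusters.cluster_of[cid], {lab: 0 for lab in labels})
        row[cat] += 1
    table = pd.DataFrame.from_dict(counts, orient="index", columns=labels).fillna(0).astype(int)
    table.index.name = "cluster"
    return table.sort_index()
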