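"""Lek clustering: group sampling locations by complete-linkage clustering.

Sage-grouse samples are collected at breeding leks; spatially proximate leks
behave as one genetic unit, so locations are agglomerated with complete
linkage (the Lance-Williams recurrence with alpha_i = alpha_j = 0.5, beta = 0,
gamma = 0.5) and the dendrogram is cut so that two locations end up in
different clusters when their cluster-to-cluster distance exceeds the cut
(default 25 km, a dispersal-scale movement distance).  Clusters retaining
fewer than a minimum number of genotyped individuals (default 8) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .matrices import PairwiseMatrix

log = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterSet:
    """Disjoint clusters of locations/individuals with centroids."""

    members: dict = field(default_factory=dict)  # cluster_id -> list of point ids
    centroids: dict = field(default_factory=dict)  # cluster_id -> (x, y)
    n_individuals: dict = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.members)

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def assignment(self) -> dict:
        """point id -> cluster id."""
        out = {}
        for cid, ids in self.members.items():
            for pid in ids:
                out[pid] = cid
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.cluster_ids:
            for pid in self.members[cid]:
                rows.append(
                    {
                        "cluster_id": cid,
                        "member_id": pid,
                        "centroid_x": self.centroids[cid][0],
                        "centroid_y": self.centroids[cid][1],
                    }
                )
        return pd.DataFrame(rows)


def geographic_distances(
    ids, x: np.ndarray, y: np.ndarray
) -> PairwiseMatrix:
    """Pairwise Euclidean distances on projected planar coordinates."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ClusteringError("duplicated location ids")
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    return PairwiseMatrix(ids, squareform(pdist(pts)), "geo_distance")


def cluster_locations(
    distances: PairwiseMatrix,
    cut: float = 25_000.0,
    coords: dict | None = None,
) -> ClusterSet:
    """Complete-linkage clustering cut at ``cut``.

    Two clusters are merged only while the merge height (their complete-
    linkage diameter) stays <= ``cut``; a separation strictly greater than
    the cut splits them.  ``coords`` optionally maps point id -> (x, y) for
    centroid computation.
    """
    n = distances.n
    cs = ClusterSet()
    if n == 0:
        return cs
    if n == 1:
        flat = np.array([1])
    else:
        z = linkage(distances.condensed(), method="complete")
        flat = fcluster(z, t=cut, criterion="distance")
    for raw in np.unique(flat):
        member_idx = np.flatnonzero(flat == raw)
        ids = [distances.labels[i] for i in member_idx]
        cid = f"C{raw:03d}"
        cs.members[cid] = ids
        if coords:
            xy = np.array([coords[i] for i in ids], dtype=float)
            cs.centroids[cid] = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        else:
            cs.centroids[cid] = (float("nan"), float("nan"))
        cs.n_individuals[cid] = len(ids)
    return cs


def count_individuals(clusters: ClusterSet, location_of: dict) -> ClusterSet:
    """Recount ``n_individuals`` when cluster members are *locations* and
    individuals map to locations via ``location_of`` (individual -> location)."""
    loc_to_cluster = clusters.assignment()
    counts = dict.fromkeys(clusters.members, 0)
    for _ind, loc in location_of.items():
        cid = loc_to_cluster.get(str(loc))
        if cid is not None:
            counts[cid] += 1
    clusters.n_individuals = counts
    return clusters


def filter_clusters(clusters: ClusterSet, min_individuals: int = 8) -> ClusterSet:
    """Drop clusters with fewer than ``min_individuals`` genotyped members."""
    keep = {
        cid
        for cid in clusters.members
        if clusters.n_individuals.get(cid, 0) >= min_individuals
    }
    if not keep:
        log.warning("all %d clusters fall below the minimum of %d individuals",
                    clusters.n_clusters, min_individuals)
    return ClusterSet(
        members={c: clusters.members[c] for c in keep},
        centroids={c: clusters.centroids[c] for c in keep},
        n_individuals={c: clusters.n_individuals[c] for c in keep},
    )
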