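"""Cluster stability analysis.

Each leave-one-out ("cross-validated") cluster map is matched against the
group-level cluster map with a greedy assignment: cross-validated
clusters are taken in descending size order and each claims the nearest
(center-of-mass Euclidean distance) group cluster that is still
unclaimed.  Each group cluster can be matched at most once per subject.
Summaries report, per group cluster, the fraction of subjects with a
match and the mean/sd of matched cluster size and match distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .univariate import ClusterSet


def match_clusters(cv_clusters: ClusterSet, group_clusters: ClusterSet) -> pd.DataFrame:
    """Greedily assign cross-validated clusters to group clusters.

    Returns a table with one row per group cluster:
    ``group_cluster_id, matched, cv_cluster_id, cv_cluster_size,
    com_distance_mm``.

    The assignment order is descending cross-validated cluster size, with
    ties broken by larger mean |t| then lower cluster id; distance ties
    resolve to the lower group cluster id.  No distance cap is applied.
    """
    if cv_clusters.geometry != group_clusters.geometry:
        raise ValueError("cluster sets must share a geometry")
    order = sorted(
        cv_clusters.clusters,
        key=lambda c: (-c.size, -c.mean_abs_t, c.cluster_id),
    )
    unassigned = {g.cluster_id: g for g in group_clusters.clusters}
    rows = {
        g.cluster_id: {
            "group_cluster_id": g.cluster_id,
            "matched": False,
            "cv_cluster_id": pd.NA,
            "cv_cluster_size": np.nan,
            "com_distance_mm": np.nan,
        }
        for g in group_clusters.clusters
    }
    for cv in order:
        if not unassigned:
            break
        com = np.asarray(cv.center_of_mass_mm)
        best_id = min(
            unassigned,
            key=lambda gid: (
                float(np.linalg.norm(com - np.asarray(unassigned[gid].center_of_mass_mm))),
                gid,
            ),
        )
        dist = float(np.linalg.norm(com - np.asarray(unassigned[best_id].center_of_mass_mm)))
        rows[best_id].update(
            matched=True,
            cv_cluster_id=cv.cluster_id,
            cv_cluster_size=cv.size,
            com_distance_mm=dist,
        )
        del unassigned[best_id]
    return pd.DataFrame(list(rows.values()))


def summarize_stability(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-subject match tables per group cluster.

    ``fraction_matched`` is computed over all subjects; size and distance
    statistics over matched subjects only (NaN when no subject matched).
    """
    if len(tables) == 0:
        raise ValueError("need >= 1 match table")
    stacked = pd.concat(tables, ignore_index=True)
    grouped = stacked.groupby("group_cluster_id")
    out = pd.DataFrame(
        {
            "fraction_matched": grouped["matched"].mean(),
            "size_mean": grouped["cv_cluster_size"].mean(),
            "size_sd": grouped["cv_cluster_size"].std(),
            "dist_mean": grouped["com_distance_mm"].mean(),
            "dist_sd": grouped["com_distance_mm"].std(),
        }
    ).reset_index()
    return out
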