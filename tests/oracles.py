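"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def dbscan_oracle(points, eps: float, min_pts: int):
    """Brute-force DBSCAN by first-principles density reachability.

    Returns (core_clusters, border_choices, noise):
      * core_clusters — list of frozensets of core-point indices, one per
        cluster (connected components of core points at distance <= eps);
      * border_choices — dict mapping each non-core, non-noise index to the
        set of cluster indices it is directly reachable from (DBSCAN may
        assign it to any of these);
      * noise — frozenset of indices reachable from no core point.
    """
    x = np.asarray(points, dtype=float)
    n = len(x)
    dist = np.abs(x[:, None] - x[None, :])
    within = dist <= eps
    is_core = within.sum(axis=1) >= min_pts  # includes self

    # connected components of core points
    unvisited = set(np.flatnonzero(is_core))
    core_clusters = []
    while unvisited:
        seed_pt = unvisited.pop()
        component = {seed_pt}
        frontier = [seed_pt]
        while frontier:
            i = frontier.pop()
            for j in np.flatnonzero(within[i] & is_core):
                if j in unvisited:
                    unvisited.remove(j)
                    component.add(int(j))
                    frontier.append(int(j))
        core_clusters.append(frozenset(component))

    border_choices = {}
    noise = set()
    for i in range(n):
        if is_core[i]:
            continue
        reachable = {
            ci
            for ci, cluster in enumerate(core_clusters)
            if any(within[i, j] for j in cluster)
        }
        if reachable:
            border_choices[i] = reachable
        else:
            noise.add(i)
    return core_clusters, border_choices, frozenset(noise)


def check_dbscan_against_oracle(freqs, cluster_ids, eps, min_pts, unclassified=-1):
    """Assert a DBSCAN labeling is consistent with the brute-force oracle."""
    core_clusters, border_choices, noise = dbscan_oracle(freqs, eps, min_pts)
    cluster_ids = np.asarray(cluster_ids)

    assert set(np.flatnonzero(cluster_ids == unclassified)) == set(noise), (
        "noise sets differ"
    )
    # each oracle core cluster must map onto exactly one emitted cluster id
    core_to_emitted = {}
    for ci, cluster in enumerate(core_clusters):
        ids = {int(cluster_ids[i]) for i in cluster}
        assert len(ids) == 1, f"oracle cluster {ci} split across ids {ids}"
        emitted = ids.pop()
        assert emitted != unclassified
        assert emitted not in core_to_emitted.values(), "oracle clusters merged"
        core_to_emitted[ci] = emitted
    # border points must carry the id of one of their reachable clusters
    for i, choices in border_choices.items():
        allowed = {core_to_emitted[ci] for ci in choices}
        assert int(cluster_ids[i]) in allowed, (
            f"border point {i} assigned outside its reachable clusters"
        )
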