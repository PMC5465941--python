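"""Walktrap community detection on weighted undirected networks.

Short random walks tend to stay inside densely connected groups of nodes,
so the similarity of two nodes can be measured by comparing where t-step
walks starting from them end up.  Communities are grown agglomeratively
from singletons by repeatedly merging the pair of adjacent communities
whose merge least increases the mean squared walk distance (a Ward-style
criterion), and the merge tree is cut at the partition of maximal weighted
modularity.  The procedure is fully deterministic.

Disconnected parts of the graph are never merged (only adjacent
communities are candidates), and zero-strength nodes remain singleton
communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CommunityPartition", "walktrap_partition", "modularity"]


@dataclass(frozen=True)
class CommunityPartition:
    """Node-to-community assignment with its merge history.

    ``membership`` holds contiguous integer labels starting at 1, numbered
    by first appearance.  ``merge_sequence`` records (community_a,
    community_b, height) tuples in merge order, heights being the Ward
    cost of each merge.
    """

    membership: np.ndarray
    n_communities: int
    modularity: float
    merge_sequence: tuple[tuple[int, int, float], ...]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership)[1:]


def modularity(weights: np.ndarray, membership: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of a partition.

    Q = sum_c [ W_c / W - (s_c / 2W)^2 ] with W the total edge weight,
    W_c the intra-community edge weight and s_c the total strength of
    community c.  An empty graph (W = 0) has Q defined as 0, with a
    warning.
    """
    A = np.asarray(weights, dtype=float)
    member = np.asarray(membership)
    if A.shape[0] != A.shape[1] or member.shape[0] != A.shape[0]:
        raise ValueError("weights and membership shapes disagree")
    total = A.sum() / 2.0
    if total == 0:
        warnings.warn("empty graph: modularity defined as 0", stacklevel=2)
        return 0.0
    strength = A.sum(axis=1)
    q = 0.0
    for c in np.unique(member):
        idx = member == c
        w_c = A[np.ix_(idx, idx)].sum() / 2.0
        s_c = strength[idx].sum()
        q += w_c / total - (s_c / (2.0 * total)) ** 2
    return float(q)


def _relabel(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 1..k by order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(raw.shape[0], dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def walktrap_partition(weights: np.ndarray, steps: int = 4) -> CommunityPartition:
    """Detect communities by the walktrap algorithm.

    Parameters
    ----------
    weights : (p, p) array
        Symmetric nonnegative edge weights with a zero diagonal.  Callers
        working with partial-correlation networks should pass absolute
        values.
    steps : int
        Random-walk length t (default 4).

    Returns
    -------
    CommunityPartition
        The merge-tree cut of maximal weighted modularity; the number of
        communities is the dimension estimate in the EGA pipeline.
    """
    A = np.asarray(weights, dtype=float)
    p = A.shape[0]
    if A.ndim != 2 or A.shape[1] != p:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("weights must have a zero diagonal")
    if np.any(A < 0):
        raise ValueError(
            "negative edge weights: pass absolute partial correlations"
        )

    strength = A.sum(axis=1)
    if np.all(strength == 0):
        warnings.warn("empty network: every node is its own community",
                      stacklevel=2)
        membership = np.arange(1, p + 1)
        return CommunityPartition(membership, p, 0.0, ())

    active = strength > 0
    idx = np.flatnonzero(active)
    sub = A[np.ix_(idx, idx)]
    m = idx.size
    # each node gets a self-loop equal to its mean incident edge weight:
    # this makes the short random walk aperiodic (a node can stay put),
    # without which bipartite-ish structures distort the walk distances
    degree = (sub > 0).sum(axis=1)
    loops = sub.sum(axis=1) / np.maximum(degree, 1)
    walk = sub + np.diag(loops)
    d = walk.sum(axis=1)
    P = walk / d[:, None]
    Pt = np.linalg.matrix_power(P, steps)

    # community state: walk-profile sums, sizes, adjacency
    profiles = {i: Pt[i].copy() for i in range(m)}
    sizes = {i: 1 for i in range(m)}
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    adjacency: dict[int, set[int]] = {
        i: set(np.flatnonzero(sub[i] > 0)) - {i} for i in range(m)
    }

    inv_d = 1.0 / d

    def ward_cost(a: int, b: int) -> float:
        diff = profiles[a] / sizes[a] - profiles[b] / sizes[b]
        r2 = float(np.sum(diff * diff * inv_d))
        return sizes[a] * sizes[b] / (sizes[a] + sizes[b]) * r2 / m

    labels = np.arange(m)
    merge_sequence: list[tuple[int, int, float]] = []
    best_labels = labels.copy()
    best_q = modularity(sub, labels + 1)

    costs: dict[tuple[int, int], float] = {}
    for a in range(m):
        for b in adjacency[a]:
            if a < b:
                costs[(a, int(b))] = ward_cost(a, int(b))

    while costs:
        (a, b) = min(costs, key=lambda k: (costs[k], k))
        height = costs[(a, b)]
        merge_sequence.append((int(a), int(b), height))
        # merge b into a
        profiles[a] = profiles[a] + profiles[b]
        sizes[a] += sizes[b]
        members[a].extend(members[b])
        adjacency[a] = (adjacency[a] | adjacency[b]) - {a, b}
        for c in adjacency[b]:
            adjacency[c].discard(b)
            adjacency[c].add(a)
        adjacency[a].discard(a)
        del profiles[b], sizes[b], members[b], adjacency[b]
        costs = {k: v for k, v in costs.items() if b not in k and a not in k}
        for c in adjacency[a]:
            key = (min(a, c), max(a, c))
            costs[key] = ward_cost(a, c)
        for i in members[a]:
            labels[i] = a
        q = modularity(sub, labels + 1)
        if q > best_q + 1e-12:
            best_q = q
            best_labels = labels.copy()

    full = np.full(p, -1, dtype=int)
    full[idx] = best_labels
    isolated = np.flatnonzero(~active)
    for off, node in enumerate(isolated):
        full[node] = m + off  # unique labels for zero-strength singletons
    membership = _relabel(full)
    n_comm = int(membership.max())
    q_full = modularity(A, membership)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} isolated node(s) kept as singleton communities",
            stacklevel=2,
        )
    return CommunityPartition(
        membership=membership,
        n_communities=n_comm,
        modularity=float(q_full),
        merge_sequence=tuple(merge_sequence),
    )
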