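"""Supervoxel region-adjacency graph and signed-graph partitioners.

After over-segmentation the volume is abstracted as a region adjacency
graph (RAG): one node per supervoxel, one edge per pair of face-adjacent
supervoxels, each edge carrying the mean boundary probability over its
interface.  Probabilities are mapped to *signed* weights

    w(p, β) = log((1 − p)/p) + log((1 − β)/β)

so that low boundary evidence gives attractive (positive) weights and high
evidence repulsive (negative) ones.  The bias β ∈ (0, 1) steers the
under/over-segmentation trade-off: at β = 0.5 the mapping is the plain
log-odds, higher β shifts all weights down and thus favours splitting.

Three partitioners operate on the signed graph:

* :func:`gasp_average` — hierarchical agglomeration, contracting the most
  attractive edge and averaging parallel edges (interface-size weighted)
  until no attractive edge remains;
* :func:`mutex_watershed` — greedy union-find over edges in decreasing
  absolute weight, merging on attractive edges and adding cannot-link
  constraints on repulsive ones;
* :func:`multicut_greedy` — approximate minimiser of the multicut
  objective Σ_{e cut} w_e (greedy sum-contraction plus single-node move
  refinement), with :func:`multicut_exact` as a small-instance
  enumeration oracle.

All partitioners are deterministic: ties are broken by the edge's
``(min node id, max node id)`` pair.
"""

from __future__ import annotations

import heapq

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionAdjacencyGraph",
    "PartitionParams",
    "build_rag",
    "to_signed_weight",
    "gasp_average",
    "mutex_watershed",
    "multicut_greedy",
    "multicut_exact",
    "multicut_objective",
    "project_partition",
    "partition_volume",
]

_P_EPS = 1e-5  # probability clamp before log-odds


@dataclass(frozen=True)
class PartitionParams:
    """Partitioner selection and bias.

    ``algorithm`` is one of ``gasp``, ``mutex``, ``multicut``,
    ``multicut_exact``; ``beta_bias`` ∈ (0, 1) (default 0.6) balances
    over- vs under-segmentation, higher values over-segmenting more.
    """

    algorithm: str = "gasp"
    beta_bias: float = 0.6
    rng_seed: int = 0  # reserved; all tie-breaking is deterministic

    def __post_init__(self) -> None:
        if self.algorithm not in ("gasp", "mutex", "multicut", "multicut_exact"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0.0 < self.beta_bias < 1.0:
            raise ValueError("beta_bias must lie strictly inside (0, 1)")


@dataclass
class RegionAdjacencyGraph:
    """Supervoxel adjacency graph with boundary-derived edge attributes.

    ``edges`` is an (E, 2) array of node-id pairs (min id first), with one
    row per adjacent region pair.  ``mean_probability`` is the arithmetic
    mean of the boundary map over the edge's interface voxels (every voxel
    of either region that touches the other across a face, each counted
    once).  ``contact_area`` counts the shared voxel faces.
    ``signed_weight`` is filled by :meth:`compute_signed_weights`.
    """

    node_ids: np.ndarray
    node_sizes: np.ndarray
    edges: np.ndarray
    mean_probability: np.ndarray
    contact_area: np.ndarray
    signed_weight: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def compute_signed_weights(self, beta_bias: float = 0.6) -> np.ndarray:
        self.signed_weight = to_signed_weight(self.mean_probability, beta_bias)
        return self.signed_weight

    def _require_weights(self) -> np.ndarray:
        if self.signed_weight is None:
            raise ValueError("signed weights not computed; call compute_signed_weights first")
        return np.asarray(self.signed_weight, dtype=np.float64)


def to_signed_weight(p: "float | np.ndarray", beta_bias: float = 0.6) -> "float | np.ndarray":
    """Signed edge weight ``log((1−p)/p) + log((1−β)/β)``.

    Positive = attractive (merge evidence), negative = repulsive.
    Strictly decreasing in both the boundary probability ``p`` and the bias
    ``β``; the sign flips at ``p = 1 − β``, so raising β shrinks the
    attractive range.  ``p`` is clamped to ``[1e-5, 1−1e-5]``.
    """
    if not 0.0 < beta_bias < 1.0:
        raise ValueError("beta_bias must lie strictly inside (0, 1)")
    p_arr = np.clip(np.asarray(p, dtype=np.float64), _P_EPS, 1.0 - _P_EPS)
    w = np.log((1.0 - p_arr) / p_arr) + np.log((1.0 - beta_bias) / beta_bias)
    return w if isinstance(p, np.ndarray) else float(w)


def build_rag(supervoxels: np.ndarray, bmap: np.ndarray) -> RegionAdjacencyGraph:
    """Region adjacency graph of a supervoxel partition.

    Edges connect exactly the 6-adjacent (face-sharing) region pairs.  For
    each edge the interface voxel set is every voxel of either region with
    a face neighbour in the other region; the edge's ``mean_probability``
    averages the boundary map over that set (each voxel once, even if it
    touches across several faces).
    """
    supervoxels = np.asarray(supervoxels)
    bmap = np.asarray(bmap, dtype=np.float64)
    if supervoxels.shape != bmap.shape:
        raise ValueError("supervoxels and boundary map shapes differ")
    if supervoxels.min() <= 0:
        raise ValueError("supervoxels must be a complete partition (all labels positive)")

    node_ids, node_sizes = np.unique(supervoxels, return_counts=True)
    flat = supervoxels.ravel().astype(np.int64)
    n_vox = flat.size

    pair_edges = []  # per-face (lo, hi) label pairs
    pair_voxels = []  # per-face the two flat voxel indices
    idx = np.arange(n_vox, dtype=np.int64).reshape(supervoxels.shape)
    for axis in range(supervoxels.ndim):
        a = [slice(None)] * supervoxels.ndim
        b = [slice(None)] * supervoxels.ndim
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        la = supervoxels[tuple(a)].ravel().astype(np.int64)
        lb = supervoxels[tuple(b)].ravel().astype(np.int64)
        ia = idx[tuple(a)].ravel()
        ib = idx[tuple(b)].ravel()
        diff = la != lb
        lo = np.minimum(la[diff], lb[diff])
        hi = np.maximum(la[diff], lb[diff])
        pair_edges.append(np.stack([lo, hi], axis=1))
        pair_voxels.append(np.stack([ia[diff], ib[diff]], axis=1))

    if not pair_edges or sum(p.shape[0] for p in pair_edges) == 0:
        return RegionAdjacencyGraph(
            node_ids=node_ids,
            node_sizes=node_sizes,
            edges=np.empty((0, 2), dtype=np.int64),
            mean_probability=np.empty(0),
            contact_area=np.empty(0, dtype=np.int64),
        )

    face_pairs = np.concatenate(pair_edges)  # (F, 2)
    face_vox = np.concatenate(pair_voxels)  # (F, 2)

    edges, edge_of_face, contact_area = np.unique(
        face_pairs, axis=0, return_inverse=True, return_counts=True
    )
    edge_of_face = edge_of_face.ravel()

    # interface voxel SET per edge: unique (edge, voxel) pairs over both sides
    eid = np.concatenate([edge_of_face, edge_of_face])
    vox = np.concatenate([face_vox[:, 0], face_vox[:, 1]])
    key = np.unique(eid.astype(np.int64) * n_vox + vox)
    uniq_eid = key // n_vox
    uniq_vox = key % n_vox
    prob_sum = np.bincount(uniq_eid, weights=bmap.ravel()[uniq_vox], minlength=edges.shape[0])
    vox_count = np.bincount(uniq_eid, minlength=edges.shape[0])
    mean_probability = prob_sum / vox_count

    return RegionAdjacencyGraph(
        node_ids=node_ids,
        node_sizes=node_sizes,
        edges=edges,
        mean_probability=mean_probability,
        contact_area=contact_area.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# partitioners
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, ids):
        self.parent = {int(i): int(i) for i in ids}

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)
        return min(ra, rb)


def _finalize_partition(uf: _UnionFind, node_ids: np.ndarray) -> dict[int, int]:
    """Map node id → dense cluster id 1..K (ordered by lowest member id)."""
    roots = {}
    out = {}
    for i in sorted(int(v) for v in node_ids):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        out[i] = roots[r]
    return out


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u <= v else (v, u)


def gasp_average(graph: RegionAdjacencyGraph) -> dict[int, int]:
    """Average-linkage agglomeration on the signed graph (GASP, average).

    Repeatedly contracts the currently most attractive edge (highest
    positive signed weight; ties by lowest ``(min id, max id)``); after a
    contraction, parallel edges are merged with an interface-size-weighted
    average of their signed weights.  Stops when every remaining edge is
    repulsive (≤ 0).  Returns node id → cluster id (dense 1..K).
    """
    w = graph._require_weights()
    uf = _UnionFind(graph.node_ids)
    # adjacency: cluster → {neighbour: [sum(w·area), sum(area)]}
    adj: dict[int, dict[int, list[float]]] = {int(i): {} for i in graph.node_ids}
    for (u, v), wi, area in zip(graph.edges.tolist(), w.tolist(), graph.contact_area.tolist()):
        adj[u][v] = [wi * area, float(area)]
        adj[v][u] = [wi * area, float(area)]

    heap: list[tuple[float, int, int]] = []
    for (u, v), wi in zip(graph.edges.tolist(), w.tolist()):
        if wi > 0:
            heapq.heappush(heap, (-wi, *_edge_key(u, v)))

    while heap:
        neg_w, u, v = heapq.heappop(heap)
        ru, rv = uf.find(u), uf.find(v)
        if ru == rv or ru != u or rv != v or v not in adj.get(u, {}):
            continue  # stale entry
        ws, area = adj[u][v]
        if ws / area != -neg_w:
            continue  # weight has been updated since queued
        if ws / area <= 0:
            continue
        keep = uf.union(u, v)
        drop = v if keep == u else u
        # merge adjacency of drop into keep, weight-averaging parallel edges
        adj[keep].pop(drop, None)
        adj[drop].pop(keep, None)
        for nbr, (ws2, a2) in adj[drop].items():
            adj[nbr].pop(drop, None)
            if nbr in adj[keep]:
                entry = adj[keep][nbr]
                entry[0] += ws2
                entry[1] += a2
            else:
                adj[keep][nbr] = [ws2, a2]
            adj[nbr][keep] = adj[keep][nbr]
            new_w = adj[keep][nbr][0] / adj[keep][nbr][1]
            if new_w > 0:
                heapq.heappush(heap, (-new_w, *_edge_key(keep, nbr)))
        del adj[drop]
    return _finalize_partition(uf, graph.node_ids)


def _sorted_edges_by_magnitude(edges: np.ndarray, w: np.ndarray):
    order = sorted(
        range(len(w)),
        key=lambda i: (-abs(w[i]), int(edges[i, 0]), int(edges[i, 1])),
    )
    return order


def mutex_watershed(graph: RegionAdjacencyGraph) -> dict[int, int]:
    """Mutex watershed on the signed region graph.

    Edges are visited in decreasing absolute signed weight.  An attractive
    edge merges its two clusters unless a mutual-exclusion constraint
    already separates them; a repulsive edge installs such a constraint
    unless the clusters are already merged.  Invariant to any positive
    rescaling of the weights.  Returns node id → cluster id.
    """
    w = graph._require_weights()
    uf = _UnionFind(graph.node_ids)
    mutex: dict[int, set[int]] = {int(i): set() for i in graph.node_ids}
    for i in _sorted_edges_by_magnitude(graph.edges, w):
        u, v = int(graph.edges[i, 0]), int(graph.edges[i, 1])
        wi = w[i]
        ru, rv = uf.find(u), uf.find(v)
        if ru == rv:
            continue
        if wi > 0:
            if rv in mutex[ru]:
                continue
            keep = uf.union(ru, rv)
            drop = rv if keep == ru else ru
            merged = mutex[drop] | mutex[keep]
            for other in mutex[drop]:
                mutex[other].discard(drop)
                mutex[other].add(keep)
            mutex[keep] = merged
            mutex.pop(drop, None)
        elif wi < 0:
            mutex[ru].add(rv)
            mutex[rv].add(ru)
    return _finalize_partition(uf, graph.node_ids)


def multicut_objective(
    graph: RegionAdjacencyGraph, partition: dict[int, int], normalized: bool = True
) -> float:
    """Multicut objective of a partition.

    The raw objective is Σ of signed weights over cut edges (endpoints in
    different clusters).  By default the constant Σ_e min(w_e, 0) is
    subtracted, giving the equivalent correlation-clustering *disagreement*
    form — Σ of attractive weight cut plus repulsive weight left uncut —
    which is 0 exactly when every attractive edge is inside a cluster and
    every repulsive edge is cut, and non-negative always.  Both forms have
    the same minimiser.
    """
    w = graph._require_weights()
    cut = 0.0
    for (u, v), wi in zip(graph.edges.tolist(), w.tolist()):
        if partition[u] != partition[v]:
            cut += wi
    if normalized:
        cut -= float(np.minimum(w, 0.0).sum())
    return cut


def _greedy_contraction(graph: RegionAdjacencyGraph) -> _UnionFind:
    """Phase 1: greedily contract the max-aggregated-weight attractive edge,
    summing parallel edges (additive aggregation, as the multicut objective
    is additive over cut edges)."""
    w = graph._require_weights()
    uf = _UnionFind(graph.node_ids)
    adj: dict[int, dict[int, float]] = {int(i): {} for i in graph.node_ids}
    for (u, v), wi in zip(graph.edges.tolist(), w.tolist()):
        adj[u][v] = adj[u].get(v, 0.0) + wi
        adj[v][u] = adj[v].get(u, 0.0) + wi
    heap: list[tuple[float, int, int]] = []
    for u in adj:
        for v, wi in adj[u].items():
            if u < v and wi > 0:
                heapq.heappush(heap, (-wi, u, v))
    while heap:
        neg_w, u, v = heapq.heappop(heap)
        if u not in adj or v not in adj or v not in adj[u]:
            continue
        if adj[u][v] != -neg_w or adj[u][v] <= 0:
            continue
        keep = uf.union(u, v)
        drop = v if keep == u else u
        adj[keep].pop(drop)
        adj[drop].pop(keep)
        for nbr, wi2 in adj[drop].items():
            adj[nbr].pop(drop)
            new_w = adj[keep].get(nbr, 0.0) + wi2
            adj[keep][nbr] = new_w
            adj[nbr][keep] = new_w
            if new_w > 0:
                heapq.heappush(heap, (-new_w, *_edge_key(keep, nbr)))
        del adj[drop]
    return uf


def _node_moves(part, nodes, nbrs) -> bool:
    """One sweep of single-node relocations; returns True if any improved."""
    improved = False
    for node in nodes:
        current = part[node]
        # attachment weight of `node` towards each adjacent cluster
        attach: dict[int, float] = {}
        for v, wi in nbrs[node]:
            attach[part[v]] = attach.get(part[v], 0.0) + wi
        base = attach.get(current, 0.0)  # weight kept uncut now
        # moving to cluster c changes the objective by (base - attach[c])
        best_c, best_gain = current, 0.0
        for c, a in sorted(attach.items()):
            gain = base - a  # negative = improvement
            if c != current and gain < best_gain - 1e-12:
                best_c, best_gain = c, gain
        # moving to a fresh singleton cuts everything: gain = base
        if base < best_gain - 1e-12:
            best_c = max(part.values()) + 1
        if best_c != current:
            part[node] = best_c
            improved = True
    return improved


def _cluster_merges(part, nodes, edges, w) -> bool:
    """Greedily merge cluster pairs whose total inter-cluster weight is
    positive (each merge lowers the objective by that total)."""
    improved = False
    while True:
        inter: dict[tuple[int, int], float] = {}
        for (u, v), wi in zip(edges.tolist(), w.tolist()):
            cu, cv = part[u], part[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                inter[key] = inter.get(key, 0.0) + wi
        best = max(sorted(inter), key=lambda k: inter[k], default=None)
        if best is None or inter[best] <= 1e-12:
            return improved
        a, b = best
        for node in nodes:
            if part[node] == b:
                part[node] = a
        improved = True


def _pair_moves(part, nodes, nbrs, edges, w) -> bool:
    """Joint relocation of an adjacent node pair (escapes local optima where
    two mutually attractive nodes are pinned in separate clusters)."""
    improved = False
    for (u, v), wuv in zip(edges.tolist(), w.tolist()):
        cu, cv = part[u], part[v]
        # objective change of moving {u, v} jointly into cluster c:
        # lose attachments to current clusters, gain attachments to c,
        # and the u-v edge becomes internal.
        attach_u: dict[int, float] = {}
        for x, wi in nbrs[u]:
            if x != v:
                attach_u[part[x]] = attach_u.get(part[x], 0.0) + wi
        attach_v: dict[int, float] = {}
        for x, wi in nbrs[v]:
            if x != u:
                attach_v[part[x]] = attach_v.get(part[x], 0.0) + wi
        base = attach_u.get(cu, 0.0) + attach_v.get(cv, 0.0) + (wuv if cu == cv else 0.0)
        targets = sorted(set(attach_u) | set(attach_v) | {max(part.values()) + 1})
        best_c, best_gain = None, -1e-12
        for c in targets:
            if c == cu and c == cv:
                continue
            new_kept = attach_u.get(c, 0.0) + attach_v.get(c, 0.0) + wuv
            gain = base - new_kept  # negative = improvement
            if gain < best_gain - 1e-12:
                best_c, best_gain = c, gain
        if best_c is not None and best_gain < -1e-12:
            part[u] = best_c
            part[v] = best_c
            improved = True
    return improved


def _kl_improve_pair(part, members_a, members_b, nbrs, new_cluster_id) -> bool:
    """Kernighan–Lin pass between two clusters (B may be empty = split-off).

    Nodes are tentatively transferred one at a time to the other side,
    always picking the currently best transfer even if its gain is
    negative; the best prefix of the transfer sequence is kept if it
    strictly lowers the objective.
    """
    side = {x: 0 for x in members_a}
    side.update({x: 1 for x in members_b})
    in_play = set(side)
    # delta[x]: objective change of moving x to the other side now
    delta = {}
    for x in in_play:
        same = other = 0.0
        for y, wi in nbrs[x]:
            if y in side:
                if side[y] == side[x]:
                    same += wi
                else:
                    other += wi
        delta[x] = same - other
    moved: list[int] = []
    cumulative = []
    total = 0.0
    frozen = set()
    while len(frozen) < len(in_play):
        x = min(
            (n for n in in_play if n not in frozen),
            key=lambda n: (delta[n], n),
        )
        total += delta[x]
        moved.append(x)
        cumulative.append(total)
        frozen.add(x)
        side[x] ^= 1
        for y, wi in nbrs[x]:
            if y in side and y not in frozen:
                delta[y] += 2.0 * wi if side[y] == side[x] else -2.0 * wi
        delta[x] = -delta[x]
    best_k = int(np.argmin(cumulative)) + 1
    if cumulative[best_k - 1] < -1e-12:
        a_id = part[members_a[0]]
        b_id = part[members_b[0]] if members_b else new_cluster_id
        set_a = set(members_a)
        for x in moved[:best_k]:
            part[x] = b_id if x in set_a else a_id
        return True
    return False


def _kl_sweep(part, nodes, nbrs, edges, w) -> bool:
    """KL refinement over all adjacent cluster pairs plus split-offs."""
    improved = False
    clusters_of: dict[int, list[int]] = {}
    for n in nodes:
        clusters_of.setdefault(part[n], []).append(n)
    pairs = set()
    for (u, v) in edges.tolist():
        cu, cv = part[u], part[v]
        if cu != cv:
            pairs.add((min(cu, cv), max(cu, cv)))
    next_id = max(part.values()) + 1
    for a, b in sorted(pairs):
        ma = [n for n in nodes if part[n] == a]
        mb = [n for n in nodes if part[n] == b]
        if ma and mb and _kl_improve_pair(part, ma, mb, nbrs, next_id):
            improved = True
            next_id = max(part.values()) + 1
    # split-off attempts: each cluster vs an empty one
    for c in sorted(set(part.values())):
        mc = [n for n in nodes if part[n] == c]
        if len(mc) > 1 and _kl_improve_pair(part, mc, [], nbrs, next_id):
            improved = True
            next_id = max(part.values()) + 1
    return improved


def _refine(part, nodes, nbrs, edges, w) -> None:
    while True:
        any_improvement = False
        while _node_moves(part, nodes, nbrs):
            any_improvement = True
        if _pair_moves(part, nodes, nbrs, edges, w):
            any_improvement = True
        if _cluster_merges(part, nodes, edges, w):
            any_improvement = True
        if _kl_sweep(part, nodes, nbrs, edges, w):
            any_improvement = True
        if not any_improvement:
            return


def multicut_greedy(graph: RegionAdjacencyGraph) -> dict[int, int]:
    """Approximate multicut: greedy contraction + local move refinement.

    Phase 1 contracts attractive edges greedily (sum aggregation of parallel
    edges).  Phase 2 hill-climbs until no move improves the objective
    Σ_{e cut} w_e: single-node relocations (to a neighbouring cluster or a
    fresh singleton) alternated with whole-cluster merges.  The refinement
    also runs from an all-singleton start and the better of the two local
    optima is returned.  Deterministic.  Returns node id → cluster id.
    """
    w = graph._require_weights()
    nbrs: dict[int, list[tuple[int, float]]] = {int(i): [] for i in graph.node_ids}
    for (u, v), wi in zip(graph.edges.tolist(), w.tolist()):
        nbrs[u].append((v, wi))
        nbrs[v].append((u, wi))
    nodes = sorted(int(i) for i in graph.node_ids)

    uf = _greedy_contraction(graph)
    candidates = [
        _finalize_partition(uf, graph.node_ids),
        {n: i + 1 for i, n in enumerate(nodes)},  # all-singleton start
        mutex_watershed(graph),  # constraint-aware start
    ]
    best_part, best_obj = None, np.inf
    for part in candidates:
        _refine(part, nodes, nbrs, graph.edges, w)
        obj = multicut_objective(graph, part, normalized=False)
        if obj < best_obj - 1e-12:
            best_part, best_obj = part, obj
    # densify cluster ids by lowest member node
    remap: dict[int, int] = {}
    for node in nodes:
        remap.setdefault(best_part[node], len(remap) + 1)
    return {node: remap[best_part[node]] for node in nodes}


def _partitions_rgs(n: int):
    """All set partitions of range(n) as restricted-growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])
    while True:
        yield tuple(a)
        # next RGS in lexicographic order
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def multicut_exact(graph: RegionAdjacencyGraph) -> dict[int, int]:
    """Exact multicut by exhaustive set-partition enumeration (≤ 12 nodes).

    Returns the partition minimising Σ_{e cut} w_e; ties broken by fewer
    clusters, then lexicographically on the assignment vector.  Intended as
    a test oracle for :func:`multicut_greedy`, not for production volumes.
    """
    w = graph._require_weights()
    n = graph.n_nodes
    if n > 12:
        raise ValueError(f"multicut_exact enumerates all partitions; {n} nodes > 12 refused")
    ids = sorted(int(i) for i in graph.node_ids)
    pos = {v: i for i, v in enumerate(ids)}
    eu = np.array([pos[int(u)] for u in graph.edges[:, 0]], dtype=np.int64)
    ev = np.array([pos[int(v)] for v in graph.edges[:, 1]], dtype=np.int64)

    best: tuple[float, int, tuple[int, ...]] | None = None
    for assignment in _partitions_rgs(n):
        arr = np.asarray(assignment)
        obj = float(w[arr[eu] != arr[ev]].sum())
        key = (obj, int(arr.max()) + 1, assignment)
        if best is None or key < best:
            best = key
    assert best is not None
    return {ids[i]: int(c) + 1 for i, c in enumerate(best[2])}


def project_partition(supervoxels: np.ndarray, partition: dict[int, int]) -> np.ndarray:
    """Relabel every voxel by its supervoxel's cluster id (dense 1..K)."""
    supervoxels = np.asarray(supervoxels)
    ids = np.unique(supervoxels)
    missing = [int(i) for i in ids if int(i) not in partition]
    if missing:
        raise ValueError(f"partition lacks supervoxel ids {missing[:5]}")
    lut = np.zeros(int(ids.max()) + 1, dtype=np.uint32)
    for i in ids:
        lut[int(i)] = partition[int(i)]
    return lut[supervoxels.astype(np.int64)]


_PARTITIONERS = {
    "gasp": gasp_average,
    "mutex": mutex_watershed,
    "multicut": multicut_greedy,
    "multicut_exact": multicut_exact,
}


def partition_volume(
    supervoxels: np.ndarray,
    bmap: np.ndarray,
    params: PartitionParams | None = None,
) -> tuple[np.ndarray, RegionAdjacencyGraph]:
    """Full second stage: RAG construction, signed weights, partitioning,
    and projection back to a label volume."""
    params = params or PartitionParams()
    rag = build_rag(supervoxels, bmap)
    rag.compute_signed_weights(params.beta_bias)
    partition = _PARTITIONERS[params.algorithm](rag)
    return project_partition(supervoxels, partition), rag
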