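"""Region adjacency graph construction and signed-graph partitioners."""

import numpy as np
import pytest

from tissueseg.graph import (
    PartitionParams,
    RegionAdjacencyGraph,
    build_rag,
    gasp_average,
    multicut_exact,
    multicut_greedy,
    multicut_objective,
    mutex_watershed,
    partition_volume,
    project_partition,
    to_signed_weight,
)


def make_graph(n_nodes, edges_with_weights, areas=None):
    """RAG from explicit (u, v, signed_weight) triples (node ids 1..n)."""
    edges = np.array([(min(u, v), max(u, v)) for u, v, _ in edges_with_weights], dtype=np.int64)
    w = np.array([wi for _, _, wi in edges_with_weights], dtype=np.float64)
    areas = np.ones(len(w), dtype=np.int64) if areas is None else np.asarray(areas)
    g = RegionAdjacencyGraph(
        node_ids=np.arange(1, n_nodes + 1),
        node_sizes=np.ones(n_nodes, dtype=np.int64),
        edges=edges,
        mean_probability=np.full(len(w), 0.5),
        contact_area=areas,
        signed_weight=w,
    )
    return g


def clusters(partition):
    """Frozenset-of-frozensets view, independent of cluster numbering."""
    out = {}
    for node, c in partition.items():
        out.setdefault(c, set()).add(node)
    return {frozenset(s) for s in out.values()}


def random_signed_graph(rng, n, p_edge=0.7):
    triples = []
    for u in range(1, n + 1):
        for v in range(u + 1, n + 1):
            if rng.random() < p_edge:
                triples.append((u, v, float(rng.normal())))
    if not triples:
        triples = [(1, 2, float(rng.normal()))]
    return make_graph(n, triples)


class TestBuildRag:
    def test_two_half_volumes_single_edge_constant_interface(self, two_half_volumes):
        bmap = np.zeros((16, 16, 16))
        bmap[7:9] = 0.9  # boundary band probabilities
        rag = build_rag(two_half_volumes, bmap)
        assert rag.n_nodes == 2 and rag.n_edges == 1
        assert rag.mean_probability[0] == pytest.approx(0.9)
        assert rag.contact_area[0] == 16 * 16

    def test_quadrant_grid_has_no_diagonal_edges(self):
        labels = np.ones((4, 8, 8), dtype=np.int32)
        labels[:, 4:, :4] = 2
        labels[:, :4, 4:] = 3
        labels[:, 4:, 4:] = 4
        rag = build_rag(labels, np.zeros(labels.shape))
        got = {tuple(e) for e in rag.edges.tolist()}
        assert got == {(1, 2), (1, 3), (2, 4), (3, 4)}  # no (1,4) or (2,3)

    def test_mean_matches_exhaustive_interface_enumeration(self):
        rng = np.random.default_rng(0)
        labels = np.ones((6, 6, 6), dtype=np.int32)
        labels[:, 3:, :] = 2
        labels[3:, :, 3:] = 3
        bmap = rng.random((6, 6, 6))
        rag = build_rag(labels, bmap)
        for (u, v), mean in zip(rag.edges.tolist(), rag.mean_probability):
            interface = set()
            for idx in np.ndindex(labels.shape):
                for axis in range(3):
                    nbr = list(idx)
                    nbr[axis] += 1
                    if nbr[axis] < labels.shape[axis]:
                        pair = {labels[idx], labels[tuple(nbr)]}
                        if pair == {u, v}:
                            interface.add(idx)
                            interface.add(tuple(nbr))
            oracle = np.mean([bmap[i] for i in sorted(interface)])
            assert mean == pytest.approx(oracle, abs=1e-12)

    def test_single_region_graph_has_no_edges(self):
        rag = build_rag(np.ones((4, 4, 4), dtype=np.int32), np.zeros((4, 4, 4)))
        assert rag.n_nodes == 1 and rag.n_edges == 0


class TestSignedWeight:
    def test_symmetry_point_is_zero(self):
        assert to_signed_weight(0.5, 0.5) == pytest.approx(0.0)

    def test_bias_at_half_probability_is_negative(self):
        w = to_signed_weight(0.5, 0.6)
        assert w == pytest.approx(np.log(0.4 / 0.6))
        assert w < 0

    def test_strictly_decreasing_in_p_and_beta(self):
        ps = np.linspace(0.05, 0.95, 19)
        w = to_signed_weight(ps, 0.5)
        assert np.all(np.diff(w) < 0)
        betas = np.linspace(0.1, 0.9, 9)
        ws = [to_signed_weight(0.3, b) for b in betas]
        assert np.all(np.diff(ws) < 0)

    def test_probability_clamped(self):
        assert np.isfinite(to_signed_weight(0.0, 0.6))
        assert np.isfinite(to_signed_weight(1.0, 0.6))


class TestGasp:
    def test_all_attractive_single_cluster(self):
        g = make_graph(4, [(1, 2, 1.0), (2, 3, 2.0), (3, 4, 0.5)])
        assert clusters(gasp_average(g)) == {frozenset({1, 2, 3, 4})}

    def test_all_repulsive_singletons(self):
        g = make_graph(3, [(1, 2, -1.0), (2, 3, -2.0), (1, 3, -0.5)])
        assert clusters(gasp_average(g)) == {frozenset({1}), frozenset({2}), frozenset({3})}

    def test_path_with_negative_middle_edge(self):
        # hand-executed agglomeration: merge the two +2 edges, never cross −1
        g = make_graph(4, [(1, 2, 2.0), (2, 3, -1.0), (3, 4, 2.0)])
        assert clusters(gasp_average(g)) == {frozenset({1, 2}), frozenset({3, 4})}

    def test_average_linkage_blocks_weakly_attractive_merge(self):
        # after merging (1,2), parallel edges to 3 average to (3·1 + (−5)·1)/2 = −1
        g = make_graph(3, [(1, 2, 5.0), (1, 3, 3.0), (2, 3, -5.0)])
        assert clusters(gasp_average(g)) == {frozenset({1, 2}), frozenset({3})}

    def test_interface_weighted_averaging_can_flip_sign(self):
        # same weights, but the attractive parallel edge has 4× the area:
        # average = (3·4 + (−5)·1)/5 = +1.4 ⇒ everything merges
        g = make_graph(
            3, [(1, 2, 5.0), (1, 3, 3.0), (2, 3, -5.0)], areas=[1, 4, 1]
        )
        assert clusters(gasp_average(g)) == {frozenset({1, 2, 3})}


class TestMutexWatershed:
    def test_all_attractive_one_cluster(self):
        g = make_graph(4, [(1, 2, 1.0), (2, 3, 0.5), (3, 4, 2.0)])
        assert clusters(mutex_watershed(g)) == {frozenset({1, 2, 3, 4})}

    def test_strong_repulsion_wins_triangle(self):
        # |−5| processed first: 1 and 3 can never merge; exhaustive check of
        # the 3-node instance confirms {1,2},{3} (edge +3 merges 1-2; +2 blocked)
        g = make_graph(3, [(1, 2, 3.0), (2, 3, 2.0), (1, 3, -5.0)])
        assert clusters(mutex_watershed(g)) == {frozenset({1, 2}), frozenset({3})}

    def test_sign_flip_gives_singletons(self):
        g = make_graph(3, [(1, 2, -1.0), (2, 3, -0.5), (1, 3, -2.0)])
        assert clusters(mutex_watershed(g)) == {frozenset({1}), frozenset({2}), frozenset({3})}

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_signed_graph(rng, 7)
            base = clusters(mutex_watershed(g))
            for scale in (0.1, 3.7, 100.0):
                g2 = make_graph(
                    7, [(int(u), int(v), float(w) * scale)
                        for (u, v), w in zip(g.edges, g.signed_weight)],
                )
                assert clusters(mutex_watershed(g2)) == base


class TestMulticut:
    def test_all_attractive_single_cluster_zero_objective(self):
        g = make_graph(4, [(1, 2, 1.0), (2, 3, 2.0), (3, 4, 0.5), (1, 4, 1.5)])
        part = multicut_greedy(g)
        assert clusters(part) == {frozenset({1, 2, 3, 4})}
        assert multicut_objective(g, part) == 0.0

    def test_all_repulsive_singletons_zero_objective(self):
        g = make_graph(3, [(1, 2, -1.0), (2, 3, -2.0), (1, 3, -0.5)])
        part = multicut_greedy(g)
        assert clusters(part) == {frozenset({1}), frozenset({2}), frozenset({3})}
        assert multicut_objective(g, part) == 0.0

    def test_exact_two_node_instances(self):
        g = make_graph(2, [(1, 2, 1.0)])
        assert clusters(multicut_exact(g)) == {frozenset({1, 2})}
        g = make_graph(2, [(1, 2, -1.0)])
        assert clusters(multicut_exact(g)) == {frozenset({1}), frozenset({2})}

    def test_exact_triangle_cuts_one_attractive_edge(self):
        # (+1, +1, −3): all 5 partitions enumerated; optimum cuts the −3 edge
        # and exactly one +1 edge, objective −3 + 1 = −2
        g = make_graph(3, [(1, 2, 1.0), (2, 3, 1.0), (1, 3, -3.0)])
        part = multicut_exact(g)
        assert multicut_objective(g, part, normalized=False) == pytest.approx(-2.0)
        # disagreement form: one attractive unit weight cut, nothing else
        assert multicut_objective(g, part) == pytest.approx(1.0)
        assert len(clusters(part)) == 2

    def test_exact_refuses_large_instances(self):
        g = random_signed_graph(np.random.default_rng(0), 13)
        with pytest.raises(ValueError):
            multicut_exact(g)

    def test_exact_never_worse_than_greedy(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            g = random_signed_graph(rng, 7)
            exact = multicut_objective(g, multicut_exact(g))
            greedy = multicut_objective(g, multicut_greedy(g))
            assert exact <= greedy + 1e-12

    def test_greedy_close_to_optimum_on_random_graphs(self):
        rng = np.random.default_rng(23)
        ok = 0
        n_graphs = 100
        for _ in range(n_graphs):
            g = random_signed_graph(rng, 8)
            exact = multicut_objective(g, multicut_exact(g))
            greedy = multicut_objective(g, multicut_greedy(g))
            scale = max(abs(exact), 1e-9)
            if greedy <= exact + 0.05 * scale:
                ok += 1
        assert ok >= 95


class TestProjectPartition:
    def test_identity_and_all_in_one(self, two_half_volumes):
        ident = {1: 1, 2: 2}
        assert np.array_equal(project_partition(two_half_volumes, ident), two_half_volumes)
        merged = project_partition(two_half_volumes, {1: 1, 2: 1})
        assert np.array_equal(merged, np.ones_like(two_half_volumes, dtype=np.uint32))

    def test_voxel_counts_are_summed_supervoxel_sizes(self, voronoi_10):
        labels, _ = voronoi_10
        partition = {i: 1 + (i - 1) % 3 for i in range(1, 11)}
        out = project_partition(labels, partition)
        for c in (1, 2, 3):
            expected = sum(
                np.count_nonzero(labels == i) for i, ci in partition.items() if ci == c
            )
            assert np.count_nonzero(out == c) == expected

    def test_missing_id_rejected(self, two_half_volumes):
        with pytest.raises(ValueError):
            project_partition(two_half_volumes, {1: 1})


class TestInvariants:
    def test_separation_soundness_all_partitioners(self):
        # clean synthetic RAG: p=0 within objects, p=1 between objects
        rng = np.random.default_rng(31)
        for trial in range(10):
            n_objects = int(rng.integers(2, 5))
            nodes_per = [int(rng.integers(1, 4)) for _ in range(n_objects)]
            node = 1
            membership = {}
            for obj, k in enumerate(nodes_per):
                for _ in range(k):
                    membership[node] = obj
                    node += 1
            n = node - 1
            triples = []
            # spanning chain within each object (p=0), all cross pairs p=1
            for u in range(1, n + 1):
                for v in range(u + 1, n + 1):
                    if membership[u] == membership[v]:
                        triples.append((u, v, 0.0))
                    elif rng.random() < 0.8:
                        triples.append((u, v, 1.0))
            g_edges = np.array([(u, v) for u, v, _ in triples], dtype=np.int64)
            probs = np.array([p for _, _, p in triples])
            g = RegionAdjacencyGraph(
                node_ids=np.arange(1, n + 1),
                node_sizes=np.ones(n, dtype=np.int64),
                edges=g_edges,
                mean_probability=probs,
                contact_area=np.ones(len(probs), dtype=np.int64),
            )
            g.compute_signed_weights(0.6)
            truth = {
                frozenset(u for u in range(1, n + 1) if membership[u] == obj)
                for obj in range(n_objects)
            }
            for algo in (gasp_average, mutex_watershed, multicut_greedy):
                assert clusters(algo(g)) == truth, algo.__name__

    def test_gasp_cluster_count_nondecreasing_in_beta(self):
        rng = np.random.default_rng(47)
        for _ in range(5):
            n = 10
            triples = []
            for u in range(1, n + 1):
                for v in range(u + 1, n + 1):
                    if rng.random() < 0.5:
                        triples.append((u, v, float(rng.random())))
            edges = np.array([(u, v) for u, v, _ in triples], dtype=np.int64)
            probs = np.array([p for _, _, p in triples])
            counts = []
            for beta in (0.3, 0.4, 0.5, 0.6, 0.7):
                g = RegionAdjacencyGraph(
                    node_ids=np.arange(1, n + 1),
                    node_sizes=np.ones(n, dtype=np.int64),
                    edges=edges,
                    mean_probability=probs,
                    contact_area=np.ones(len(probs), dtype=np.int64),
                )
                g.compute_signed_weights(beta)
                counts.append(len(clusters(gasp_average(g))))
            assert counts == sorted(counts)

    def test_partitioners_deterministic_and_permutation_equivariant(self):
        rng = np.random.default_rng(53)
        g = random_signed_graph(rng, 8)
        for algo in (gasp_average, mutex_watershed, multicut_greedy):
            assert algo(g) == algo(g)

    def test_partition_volume_end_to_end(self, voronoi_10):
        labels, bmap = voronoi_10
        from tissueseg.watershed import dt_watershed

        sv = dt_watershed(bmap)
        seg, rag = partition_volume(sv, bmap, PartitionParams("gasp", 0.6))
        assert seg.shape == labels.shape
        assert seg.min() >= 1
        assert rag.n_nodes == int(sv.max())
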