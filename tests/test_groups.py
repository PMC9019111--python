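"""Distances, hierarchical groups, median-joining networks, concordance."""

import itertools

import networkx as nx
import numpy as np
import pytest

from kdrhap.groups import (
    concordance,
    hierarchical_groups,
    label_clusters,
    median_joining_network,
    annotate_nonsynonymous_edges,
    pairwise_hamming,
    group_frequency_table,
)
from kdrhap.genemodel import CodonEffect

from conftest import make_haps


class TestPairwiseHamming:
    def test_identical_and_simple(self):
        codes = np.array([[0, 0], [0, 1], [0, 0], [0, 1]])
        d = pairwise_hamming(make_haps(codes))
        assert d[0, 0] == 0
        assert d[0, 1] == 2

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 2, size=(25, 12))
        haps = make_haps(codes)
        d = pairwise_hamming(haps)
        for i in range(12):
            for j in range(12):
                naive = sum(codes[s, i] != codes[s, j] for s in range(25))
                assert d[i, j] == naive

    def test_window_and_biallelic_filter(self):
        codes = np.array([[0, 1], [0, 2], [0, 1]])
        haps = make_haps(codes, positions=[10, 20, 30])
        # site at pos 20 is tri-allelic -> excluded
        d = pairwise_hamming(haps, window=(10, 31), biallelic_only=True)
        assert d[0, 1] == 2


class TestHierarchicalGroups:
    def test_all_identical_one_group(self):
        dist = np.zeros((6, 6), dtype=int)
        carriage = {"F": np.ones(6, dtype=bool)}
        labels = hierarchical_groups(dist, carriage, cut_height=5, min_group_size=1)
        assert set(labels) == {"F1"}

    def test_two_blocks_well_separated(self):
        # two internally identical blocks 50 SNPs apart, cut at 5
        dist = np.zeros((8, 8), dtype=int)
        dist[:4, 4:] = 50
        dist[4:, :4] = 50
        carriage = {"F": np.ones(8, dtype=bool)}
        labels = hierarchical_groups(dist, carriage, cut_height=5, min_group_size=1)
        assert len(set(labels)) == 2
        assert set(labels) == {"F1", "F2"}
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_negative_cut_height_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_groups(np.zeros((3, 3)), {}, cut_height=-1)

    def test_small_clusters_dissolve_to_or_and_wt(self):
        dist = np.zeros((5, 5), dtype=int) + 50
        np.fill_diagonal(dist, 0)
        dist[:3, :3] = 0
        carriage = {"F": np.array([True, True, True, True, False])}
        labels = hierarchical_groups(dist, carriage, cut_height=5, min_group_size=3)
        assert labels[:3] == ["F1"] * 3
        assert labels[3] == "OR"  # carrier in a sub-threshold cluster
        assert labels[4] == "wt"


def _net_from_strings(strings, multiplicities=None, **kwargs):
    """Build a network from explicit binary haplotype strings."""
    arrs = [[int(c) for c in s] for s in strings]
    if multiplicities is None:
        multiplicities = [1] * len(strings)
    cols = []
    for arr, m in zip(arrs, multiplicities):
        cols.extend([arr] * m)
    codes = np.array(cols).T
    if codes.shape[1] % 2:  # pad to an even haplotype count
        codes = np.hstack([codes, codes[:, -1:]])
    haps = make_haps(codes)
    return median_joining_network(haps, **kwargs), haps


class TestMedianJoiningNetwork:
    def test_single_haplotype(self):
        net, _ = _net_from_strings(["0000"], multiplicities=[2])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_steiner_star_example(self):
        """{000, 011, 110}: the majority median 010 gives a 3-edge star of
        total length 3, beating the 4-step spanning alternative."""
        net, _ = _net_from_strings(["000", "011", "110"], multiplicities=[2, 1, 1])
        nodes = set(net.graph.nodes)
        assert (0, 1, 0) in nodes
        assert not net.graph.nodes[(0, 1, 0)]["observed"]
        assert net.graph.number_of_edges() == 3
        assert all(d["distance"] == 1 for _, _, d in net.graph.edges(data=True))
        # exhaustive Steiner check: 010 is the best possible extra vertex
        observed = [(0, 0, 0), (0, 1, 1), (1, 1, 0)]
        def star_cost(m):
            return sum(sum(a != b for a, b in zip(m, o)) for o in observed)
        best = min(itertools.product((0, 1), repeat=3), key=star_cost)
        assert star_cost((0, 1, 0)) == star_cost(best) == 3

    def test_pruning_splits_components(self):
        # {0000, 0001, 1110}: distances 1, 3, 4 -> pruning at 2 leaves
        # {0000, 0001} and {1110}
        net, haps = _net_from_strings(["0000", "0001", "1110"], [2, 1, 1])
        comps = [set(c) for c in net.components]
        as_sets = [
            {tuple(n) for n in comp} for comp in comps
        ]
        assert {(0, 0, 0, 0), (0, 0, 0, 1)} in as_sets
        assert {(1, 1, 1, 0)} in as_sets

    def test_non_binary_site_rejected(self):
        codes = np.array([[0, 1], [2, 0]])
        haps = make_haps(codes)
        with pytest.raises(ValueError, match="biallelic"):
            median_joining_network(haps)

    def test_unpruned_network_single_component(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 2, size=(8, 10))
        haps = make_haps(codes)
        net = median_joining_network(haps, max_edge_dist=np.inf)
        assert len(net.components) == 1

    def test_steiner_points_never_hurt_spanning_cost(self):
        """MST over the final node set (with medians) is no longer than the
        MST over the observed haplotypes alone."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            codes = rng.integers(0, 2, size=(10, 8))
            haps = make_haps(codes)
            net = median_joining_network(haps, max_edge_dist=np.inf)

            def mst_length(vectors):
                g = nx.Graph()
                vs = list(vectors)
                for i, u in enumerate(vs):
                    for j in range(i + 1, len(vs)):
                        w = sum(a != b for a, b in zip(u, vs[j]))
                        g.add_edge(i, j, weight=w)
                if g.number_of_nodes() < 2:
                    return 0
                return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))

            observed = net.observed_nodes()
            assert mst_length(net.graph.nodes) <= mst_length(observed)

    def test_mutation_only_history_yields_spanning_tree(self):
        """With every site mutating once (no homoplasy), the network is a
        tree over the observed haplotypes."""
        rng = np.random.default_rng(17)
        n_sites = 12
        haps_list = [[0] * n_sites]
        for s in range(n_sites):
            parent = list(haps_list[rng.integers(0, len(haps_list))])
            parent[s] = 1
            haps_list.append(parent)
        codes = np.array(haps_list).T
        haps = make_haps(codes[:, : (codes.shape[1] // 2) * 2])
        net = median_joining_network(haps, max_edge_dist=np.inf)
        g = net.graph
        assert nx.is_connected(g)
        assert g.number_of_edges() == g.number_of_nodes() - 1
        observed = {n for n, d in g.nodes(data=True) if d["observed"]}
        assert observed <= set(g.nodes)

    def test_components_invariant_to_haplotype_order(self):
        rng = np.random.default_rng(23)
        codes = rng.integers(0, 2, size=(10, 12))
        haps = make_haps(codes)
        net1 = median_joining_network(haps)
        perm = rng.permutation(12)
        haps2 = make_haps(codes[:, perm])
        net2 = median_joining_network(haps2)
        # map components back to original haplotype ids
        comp1 = net1.component_ids()
        comp2_perm = net2.component_ids()
        comp2 = np.empty_like(comp2_perm)
        comp2[perm] = comp2_perm

        def partition(c):
            groups = {}
            for h, k in enumerate(c):
                groups.setdefault(k, set()).add(h)
            return {frozenset(v) for v in groups.values()}

        assert partition(comp1) == partition(comp2)


class TestEdgeAnnotation:
    def test_nonsynonymous_edges_flagged_and_labelled(self):
        net, haps = _net_from_strings(["00", "01", "11"], [2, 1, 1])
        effects = {
            1: CodonEffect("tx", 995, "L", "F", "missense"),
        }
        annotate_nonsynonymous_edges(net, effects)
        flagged = [
            d for _, _, d in net.graph.edges(data=True) if d["nonsynonymous"]
        ]
        unflagged = [
            d for _, _, d in net.graph.edges(data=True) if not d["nonsynonymous"]
        ]
        assert len(flagged) == 1
        assert flagged[0]["labels"] == ("L995F",)
        # derived-allele direction: the head carries the alt
        assert flagged[0]["direction_to"][1] == 1
        assert all(d["labels"] == () for d in unflagged)


class TestConcordance:
    def test_identical_assignments(self):
        a = ["F1", "F1", "wt", "S1"]
        assert concordance(a, list(a)) == 1.0

    def test_label_permutation_absorbed(self):
        a = ["F1", "F1", "wt", "S1"]
        b = ["x", "x", "y", "z"]
        assert concordance(a, b) == 1.0

    def test_partial_agreement(self):
        # 90 of 100 haplotypes co-assigned under the best matching
        a = ["g1"] * 50 + ["g2"] * 50
        b = ["a"] * 45 + ["b"] * 5 + ["b"] * 45 + ["a"] * 5
        assert concordance(a, b) == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance(["a"], ["a", "b"])


class TestLabelClusters:
    def test_focal_labels_only_on_carriers(self):
        cluster_ids = np.array([1, 1, 1, 2, 2])
        carriage = {"F": np.array([True, True, False, False, False])}
        labels = label_clusters(cluster_ids, carriage, min_group_size=1)
        assert labels[0] == labels[1] == "F1"
        assert labels[2] == "wt"  # in the F cluster but not a carrier
        assert labels[3] == labels[4] == "wt"

    def test_multi_letter_base_names_single_group(self):
        cluster_ids = np.array([1, 1, 2, 2])
        carriage = {"L1": np.array([True, True, True, True])}
        labels = label_clusters(cluster_ids, carriage, min_group_size=1)
        # the largest (tied -> lowest id) cluster takes the L1 name
        assert labels[:2] == ["L1", "L1"]
        assert labels[2:] == ["OR", "OR"]


def test_group_frequency_table_rows_sum_to_one():
    codes = np.zeros((1, 8))
    haps = make_haps(codes, populations=["p1"] * 4 + ["p2"] * 4)
    assignment = ["F1", "F1", "wt", "wt", "S1", "S1", "S1", "wt"]
    table = group_frequency_table(haps, assignment)
    assert np.allclose(table.sum(axis=1), 1.0)
    assert table.loc["p1", "F1"] == pytest.approx(0.5)
    assert table.loc["p2", "S1"] == pytest.approx(0.75)
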