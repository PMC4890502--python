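"""Network construction, degree statistics, power-law fit, hub calling."""

from __future__ import annotations

import io
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from litmine import (
    DegreeDistribution,
    InteractionEdge,
    Network,
    build_network,
    degree_distribution,
    detect_hubs,
    fit_power_law,
    induced_subgraph,
    load_interactions,
)
from tests.oracles import hub_call_exact


def _net(pairs):
    return build_network(InteractionEdge.make(a, b) for a, b in pairs)


MITAB_ROW = (
    "uniprotkb:P02649\tuniprotkb:P04114\t-\t-\t-\t-\t-\t-\t-\t"
    "taxid:9606(human)\ttaxid:9606(human)\t-\tpsi-mi:intact\t-\t-\n"
)
MITAB_FLY = MITAB_ROW.replace("taxid:9606(human)\ttaxid:9606", "taxid:7227(fly)\ttaxid:7227")


class TestLoadInteractions:
    def test_mitab_row_mapped(self):
        edges = load_interactions(
            io.StringIO(MITAB_ROW),
            allowed_taxa={9606, 10090},
            id_map={"P02649": 348, "P04114": 338},
        )
        assert len(edges) == 1
        assert (edges[0].gene_a, edges[0].gene_b) == (338, 348)
        assert edges[0].species_pair == (9606, 9606)

    def test_disallowed_taxon_dropped(self):
        edges = load_interactions(
            io.StringIO(MITAB_FLY),
            allowed_taxa={9606, 10090},
            id_map={"P02649": 348, "P04114": 338},
        )
        assert edges == []

    def test_two_column_tsv_with_map(self):
        edges = load_interactions(io.StringIO("A\tB\n"), id_map={"A": 1, "B": 2})
        assert [(e.gene_a, e.gene_b) for e in edges] == [(1, 2)]

    def test_two_column_integer_ids_without_map(self):
        edges = load_interactions(io.StringIO("#gene_a\tgene_b\n5\t3\n"))
        assert [(e.gene_a, e.gene_b) for e in edges] == [(3, 5)]

    def test_unmappable_row_skipped_and_logged(self, caplog):
        with caplog.at_level("INFO"):
            edges = load_interactions(io.StringIO("A\tB\nC\tD\n"), id_map={"A": 1, "B": 2})
        assert len(edges) == 1
        assert any("unmappable" in r.message for r in caplog.records)

    def test_strict_mode_raises_on_malformed_line(self):
        with pytest.raises(ValueError):
            load_interactions(io.StringIO("loner\n"), strict=True)


class TestBuildNetwork:
    def test_dedupe_and_self_loop_removal(self):
        net = _net([(1, 2), (2, 1), (2, 2)])
        assert net.nodes == {1, 2}
        assert net.n_edges == 1
        assert net.node_degrees == {1: 1, 2: 1}

    def test_triangle_degrees(self):
        net = _net([(1, 2), (2, 3), (3, 1)])
        assert set(net.node_degrees.values()) == {2}

    def test_star_degrees(self):
        net = _net([(0, leaf) for leaf in range(1, 6)])
        assert net.degree(0) == 5
        assert all(net.degree(leaf) == 1 for leaf in range(1, 6))

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)),
            max_size=120,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_handshake_lemma_always_holds(self, pairs):
        net = _net(pairs)
        assert sum(net.node_degrees.values()) == 2 * net.n_edges


class TestInducedSubgraph:
    def test_square_to_path(self):
        net = _net([(1, 2), (2, 3), (3, 4), (4, 1)])
        sub = induced_subgraph(net, {1, 2, 3})
        assert sub.n_edges == 2
        assert sub.nodes == {1, 2, 3}

    def test_disjoint_genes_all_isolated(self):
        net = _net([(1, 2)])
        sub = induced_subgraph(net, {10, 11})
        assert sub.n_nodes == 0
        assert sub.isolated_mapped == frozenset({10, 11})

    def test_full_node_set_is_identity(self):
        net = _net([(1, 2), (2, 3)])
        sub = induced_subgraph(net, net.nodes)
        assert sub.edges == net.edges

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_gene_set(self, data):
        pairs = data.draw(
            st.lists(st.tuples(st.integers(0, 15), st.integers(0, 15)), max_size=40)
        )
        net = _net(pairs)
        nodes = sorted(net.nodes)
        s2 = set(data.draw(st.lists(st.sampled_from(nodes or [0]), max_size=15)))
        s1 = set(data.draw(st.lists(st.sampled_from(sorted(s2) or [0]), max_size=15)))
        assert induced_subgraph(net, s1).edges <= induced_subgraph(net, s2).edges


class TestDegreeDistribution:
    def test_star_histogram_mean_and_sample_sd(self):
        # star, center degree 11: degrees are one 11 and eleven 1s
        net = _net([(0, leaf) for leaf in range(1, 12)])
        dist = degree_distribution(net)
        assert dist.histogram == {1: 11, 11: 1}
        assert sum(dist.histogram.values()) == net.n_nodes
        assert dist.mean == pytest.approx(22 / 12)
        assert dist.sd == pytest.approx(np.std([11] + [1] * 11, ddof=1), abs=1e-12)

    def test_constant_degrees_have_zero_sd(self):
        net = _net([(1, 2), (3, 4)])
        dist = degree_distribution(net)
        assert dist.sd == 0.0
        assert dist.mean == 1.0

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node(1)
        with pytest.raises(ValueError):
            degree_distribution(Network(g))


class TestFitPowerLaw:
    def test_exact_k_minus_2_histogram(self):
        dist = DegreeDistribution(histogram={1: 64, 2: 16, 4: 4, 8: 1}, mean=0, sd=0)
        fit = fit_power_law(dist)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.fit_range == (1, 8)

    def test_too_few_distinct_degrees_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(DegreeDistribution(histogram={1: 5, 2: 3}, mean=0, sd=0))

    def test_preferential_attachment_beats_uniform_random_r2(self):
        from litmine import generate_ppi

        for seed in (0, 1):
            edges, _ = generate_ppi(1000, 3, seed=seed)
            pa_net = _net(edges)
            pa_fit = fit_power_law(degree_distribution(pa_net))
            gnm = nx.gnm_random_graph(pa_net.n_nodes, pa_net.n_edges, seed=seed)
            uniform_fit = fit_power_law(degree_distribution(Network(gnm)))
            assert pa_fit.r_squared > uniform_fit.r_squared


class TestDetectHubs:
    def test_worked_threshold_star_plus_chain(self):
        # hub 0 with 11 neighbors in a 12-node graph: verify strictness of
        # the mean + 2 sd rule against the exact arithmetic oracle.
        net = _net([(0, leaf) for leaf in range(1, 12)])
        call = detect_hubs(net)
        assert call.hubs == hub_call_exact(net.node_degrees)
        assert call.threshold == pytest.approx(call.mean_degree + 2 * call.sd_degree)

    def test_all_equal_degrees_yield_no_hubs(self):
        net = _net([(1, 2), (3, 4)])
        call = detect_hubs(net)
        assert call.hubs == frozenset()
        assert call.threshold == pytest.approx(1.0)

    def test_degree_sequence_worked_threshold(self):
        # degree sequence [1]*9 + [11]: mean 2, sample sd sqrt(10), so the
        # cutoff is 2 + 2*sqrt(10) ~ 8.32 and only the degree-11 node passes.
        degrees = {node: 1 for node in range(9)} | {9: 11}
        mean = np.mean(list(degrees.values()))
        sd = np.std(list(degrees.values()), ddof=1)
        assert mean + 2 * sd == pytest.approx(2 + 2 * math.sqrt(10), abs=1e-9)
        assert hub_call_exact(degrees) == {9}

    def test_degenerate_single_node_rejected(self):
        g = nx.Graph()
        g.add_node(1)
        with pytest.raises(ValueError):
            detect_hubs(Network(g))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_rational_oracle_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(40, 0.12, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() < 2:
            pytest.skip("degenerate draw")
        net = Network(g)
        assert detect_hubs(net).hubs == hub_call_exact(net.node_degrees)
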