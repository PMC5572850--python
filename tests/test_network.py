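"""Network assembly, centralities, power-law fit and class comparison."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from cernet import (
    CentralityRecord,
    build_network,
    centralities,
    compare_classes,
    fit_degree_loglog,
    fit_power_law,
)
from cernet.containers import LNCRNA, MRNA
from cernet.errors import ConsistencyError, InsufficientDataError, UsageError
from conftest import make_edge, network_from_edgelist


def brute_force_centralities(g: nx.Graph):
    """All-pairs shortest-path betweenness (pair-count form) and
    component-restricted closeness, by explicit enumeration."""
    betweenness = {n: 0.0 for n in g}
    closeness = {}
    for n in g:
        lengths = nx.single_source_shortest_path_length(g, n)
        reachable = len(lengths) - 1
        total = sum(lengths.values())
        closeness[n] = reachable / total if total > 0 else 0.0
    for s, t in itertools.combinations(sorted(g), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for n in g:
            if n in (s, t):
                continue
            frac = sum(1 for p in paths if n in p) / len(paths)
            betweenness[n] += frac
    return betweenness, closeness


class TestBuildNetwork:
    def test_star_of_four_nodes(self):
        net = network_from_edgelist([("L1", "G1"), ("L1", "G2"), ("L1", "G3")])
        assert net.n_nodes == 4 and net.n_edges == 3
        assert net.node_class("L1") == LNCRNA
        assert net.mRNAs == ["G1", "G2", "G3"]

    def test_handshake_lemma(self):
        net = network_from_edgelist(
            [("L1", "G1"), ("L1", "G2"), ("L2", "G1"), ("L2", "G3"), ("L3", "G3")])
        assert sum(d for _, d in net.graph.degree) == 2 * net.n_edges

    def test_empty_edge_list_rejected(self):
        with pytest.raises(UsageError):
            build_network([])

    def test_conflicting_duplicate_weight_rejected(self):
        e1 = make_edge("L1", "G1", weight=0.9)
        e2 = make_edge("L1", "G1", weight=1.1)
        with pytest.raises(ConsistencyError, match="conflicting"):
            build_network([e1, e2])
        # identical duplicates collapse silently
        net = build_network([e1, make_edge("L1", "G1", weight=0.9)])
        assert net.n_edges == 1


class TestCentralities:
    def test_path_graph_betweenness(self):
        net = network_from_edgelist([("L1", "G1"), ("L2", "G1")])  # path L1-G1-L2
        recs = {r.node: r for r in centralities(net)}
        assert recs["G1"].betweenness == 1.0
        assert recs["L1"].betweenness == 0.0

    def test_star_closeness_closed_form(self):
        net = network_from_edgelist([("L1", "G1"), ("L1", "G2"), ("L1", "G3")])
        recs = {r.node: r for r in centralities(net)}
        assert recs["L1"].closeness == pytest.approx(1.0)
        assert recs["G1"].closeness == pytest.approx(3 / 5)

    def test_hub_threshold_is_strict(self):
        edges = [("L1", f"G{i}") for i in range(62)] + [("L2", f"G{i}") for i in range(60)]
        net = network_from_edgelist(edges)
        recs = {r.node: r for r in centralities(net, hub_threshold=60)}
        assert recs["L1"].degree == 62 and recs["L1"].is_hub
        assert recs["L2"].degree == 60 and not recs["L2"].is_hub

    def test_hub_calling_monotone_in_threshold(self):
        net = network_from_edgelist([("L1", f"G{i}") for i in range(10)]
                                    + [("L2", "G0"), ("L2", "G1")])
        hubs_at = lambda t: {r.node for r in centralities(net, hub_threshold=t) if r.is_hub}
        assert hubs_at(5) >= hubs_at(9)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(0, 2**31)))
            mapping = {i: (f"L{i}" if i < n // 2 else f"G{i}") for i in g.nodes}
            g = nx.relabel_nodes(g, mapping)
            edges = []
            for u, v in g.edges:
                lnc, partner = (u, v) if u.startswith("L") else (v, u)
                if not lnc.startswith("L"):
                    continue
                cls = LNCRNA if partner.startswith("L") else MRNA
                edges.append(make_edge(lnc, partner, partner_class=cls))
            if not edges:
                continue
            net = build_network(edges)
            bf_btw, bf_clo = brute_force_centralities(net.graph)
            for r in centralities(net):
                assert r.betweenness == pytest.approx(bf_btw[r.node], abs=1e-9)
                assert r.closeness == pytest.approx(bf_clo[r.node], abs=1e-9)

    def test_star_dominated_network_has_zero_mrna_betweenness(self):
        # every mRNA touches exactly one lncRNA
        edges = [("L1", f"G{i}") for i in range(5)] + [("L2", f"H{i}") for i in range(4)]
        net = network_from_edgelist(edges)
        for r in centralities(net):
            if r.node_class == MRNA:
                assert r.betweenness == 0.0


class TestPowerLawFit:
    def test_exact_collinear_input(self):
        # frequencies f(k) = 64 * k^-2 over k in {1, 2, 4, 8}
        degrees = []
        for k in (1, 2, 4, 8):
            degrees.extend([k] * int(64 / k**2))
        fit = fit_degree_loglog(degrees)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.n_points == 4

    def test_insufficient_distinct_degrees(self):
        net = network_from_edgelist([("L1", "G1"), ("L1", "G2")])
        with pytest.raises(InsufficientDataError):
            fit_power_law(net)

    def test_preferential_attachment_fits_well(self):
        ba = nx.barabasi_albert_graph(2000, 1, seed=0)
        fit = fit_degree_loglog(d for _, d in ba.degree)
        assert fit.r_squared >= 0.8
        assert fit.slope < -1.0


class TestCompareClasses:
    def _records(self, lnc_vals, mrna_vals):
        recs = [CentralityRecord(f"L{i}", LNCRNA, int(v), float(v), 0.0, False)
                for i, v in enumerate(lnc_vals)]
        recs += [CentralityRecord(f"G{i}", MRNA, int(v), float(v), 0.0, False)
                 for i, v in enumerate(mrna_vals)]
        return recs

    def test_identical_lists_give_t_zero_p_one(self):
        recs = self._records([1, 2, 3], [1, 2, 3])
        cmp = compare_classes(recs, "degree")
        assert cmp.t_stat == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_complete_separation_is_significant(self):
        recs = self._records(range(100, 120), range(1, 21))
        cmp = compare_classes(recs, "degree")
        assert cmp.p_value < 1e-3
        assert cmp.mean_lnc > cmp.mean_mrna

    def test_matches_hand_welch_statistic(self):
        lnc = np.array([5.0, 7.0, 9.0, 4.0])
        mrna = np.array([1.0, 2.0, 2.5])
        cmp = compare_classes(self._records(lnc, mrna), "betweenness")
        se = math.sqrt(lnc.var(ddof=1) / lnc.size + mrna.var(ddof=1) / mrna.size)
        assert cmp.t_stat == pytest.approx((lnc.mean() - mrna.mean()) / se, rel=1e-12)

    def test_absent_class_errors_by_name(self):
        recs = self._records([1, 2, 3], [])
        with pytest.raises(UsageError, match=MRNA):
            compare_classes(recs, "degree")
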