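import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import soilpem as sp
from soilpem.core import FeatureTable, SampleMetadata, ValidationError
from soilpem.network import (CooccurrenceNetwork, build_network,
                             correlation_screen, detect_modules,
                             domain_node_percentages, extract_subnetwork,
                             keystone_report, modularity_of_partition,
                             topology_metrics, zi_pi)


def make_table(counts, meta, domain="bacteria"):
    ids = [f"T{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=ids, columns=meta.sample_ids)
    return FeatureTable(df, pd.Series(domain, index=ids),
                        pd.Series("k__x;p__Proteobacteria", index=ids))


@pytest.fixture()
def meta20():
    return SampleMetadata.from_records(
        [(f"{t}_{r}", t, r) for t in ("CK", "OPT", "OPTN", "OPTP", "OPTM")
         for r in range(1, 5)])


class TestScreen:
    def test_identical_ranks_retained(self, meta20, rng):
        base = rng.integers(1, 100, size=20)
        counts = np.vstack([base, base * 2, rng.integers(1, 100, size=20)])
        edges = correlation_screen(make_table(counts, meta20))
        pairs = {frozenset((e.a, e.b)) for e in edges}
        assert frozenset(("T0", "T1")) in pairs
        assert all(e.rho == pytest.approx(1.0) for e in edges
                   if frozenset((e.a, e.b)) == frozenset(("T0", "T1")))

    def test_threshold_is_strict(self, meta20, rng):
        # build a pair with spearman rho just below 0.75
        n = 20
        x = np.arange(n)
        for seed in range(100):
            r2 = np.random.default_rng(seed)
            y = x + r2.normal(0, 6.5, n)
            from scipy.stats import spearmanr
            rho = spearmanr(x, y).statistic
            if 0.70 < rho <= 0.75:
                counts = np.vstack([x + 1, (rankdata(y) * 3).astype(int),
                                    r2.integers(1, 50, n)])
                edges = correlation_screen(make_table(counts, meta20))
                assert frozenset(("T0", "T1")) not in {
                    frozenset((e.a, e.b)) for e in edges}
                return
        pytest.skip("no fixture with rho in (0.70, 0.75] found")

    def test_constant_feature_excluded(self, meta20, rng):
        counts = np.vstack([np.full(20, 7), rng.integers(1, 100, (2, 20))])
        edges = correlation_screen(make_table(counts, meta20),
                                   prevalence_min=0.0)
        assert all("T0" not in (e.a, e.b) for e in edges)

    def test_p_matches_exhaustive_permutation_oracle(self):
        """n=5: the t-approximation p is close to the exact permutation p."""
        from scipy.stats import spearmanr
        meta = SampleMetadata.from_records(
            [(f"s{i}", "CK", i + 1) for i in range(5)])
        x = np.array([3, 1, 4, 2, 5])
        y = np.array([2, 1, 3, 5, 4])
        rho_obs, p_impl = spearmanr(x, y)
        count = 0
        perms = list(itertools.permutations(range(5)))
        for perm in perms:
            rho = spearmanr(x, y[list(perm)]).statistic
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        p_exact = count / len(perms)
        assert p_impl == pytest.approx(p_exact, abs=0.02)

    def test_symmetric_in_pair_order(self, meta20, rng):
        counts = rng.integers(1, 100, size=(6, 20))
        edges = correlation_screen(make_table(counts, meta20), r_min=0.0,
                                   p_max=1.0)
        seen = {}
        for e in edges:
            key = frozenset((e.a, e.b))
            assert key not in seen
            seen[key] = e.rho


class TestModules:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        net = detect_modules(CooccurrenceNetwork(g), seed=0)
        assert len(set(net.modules.values())) == 2
        assert net.modularity == pytest.approx(0.5)

    def test_complete_graph_single_module_q_zero(self):
        g = nx.complete_graph(6)
        net = detect_modules(CooccurrenceNetwork(g), seed=0)
        assert len(set(net.modules.values())) == 1
        assert net.modularity == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_bruteforce_partition_evaluation(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        net = detect_modules(CooccurrenceNetwork(g), seed=0)
        # independent Q: sum over modules of (e_ss - a_s^2)
        m = g.number_of_edges()
        mods = set(net.modules.values())
        q = 0.0
        for s in mods:
            members = {n for n, mm in net.modules.items() if mm == s}
            e_ss = sum(1 for a, b in g.edges
                       if a in members and b in members) / m
            a_s = sum(g.degree(n) for n in members) / (2 * m)
            q += e_ss - a_s ** 2
        assert net.modularity == pytest.approx(q, abs=1e-12)
        assert modularity_of_partition(g, net.modules) == pytest.approx(q, abs=1e-12)

    def test_empty_graph_fatal(self):
        with pytest.raises(ValidationError):
            detect_modules(CooccurrenceNetwork(nx.Graph()))

    def test_spiked_groups_recovered(self, meta20, rng):
        from sklearn.metrics import adjusted_rand_score
        ids = [f"T{i}" for i in range(30)]
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 20)),
                              index=ids, columns=meta20.sample_ids)
        table = FeatureTable(counts, pd.Series("bacteria", index=ids),
                             pd.Series("k__x;p__Y", index=ids))
        groups = [ids[:10], ids[10:20]]
        spiked = sp.spike_network_structure(table, groups, strength=0.95,
                                            seed=1)
        edges = correlation_screen(spiked)
        net = detect_modules(build_network(edges, spiked), seed=0)
        assert len(set(net.modules.values())) >= 2
        truth = {f: (0 if f in groups[0] else 1)
                 for f in ids[:20] if f in net.modules}
        ari = adjusted_rand_score([truth[f] for f in truth],
                                  [net.modules[f] for f in truth])
        assert ari > 0.9

    def test_null_strength_retains_few_edges(self, meta20, rng):
        ids = [f"T{i}" for i in range(30)]
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 20)),
                              index=ids, columns=meta20.sample_ids)
        table = FeatureTable(counts, pd.Series("bacteria", index=ids),
                             pd.Series("k__x;p__Y", index=ids))
        null = sp.spike_network_structure(table, [ids[:10], ids[10:20]],
                                          strength=0.0, seed=2)
        edges = correlation_screen(null)
        # null expectation at |rho|>0.75, p<0.01, n=20 is well below 1% of pairs
        assert len(edges) <= 0.01 * 30 * 29 / 2


class TestTopology:
    def test_triangle_metrics(self):
        net = CooccurrenceNetwork(nx.complete_graph(3))
        m = topology_metrics(net)
        assert m["average_degree"] == pytest.approx(2.0)
        assert m["average_clustering"] == pytest.approx(1.0)
        assert m["average_path_length"] == pytest.approx(1.0)
        assert m["diameter"] == 1

    def test_path_graph_enumeration(self):
        m = topology_metrics(CooccurrenceNetwork(nx.path_graph(4)))
        assert m["average_path_length"] == pytest.approx(10 / 6)
        assert m["diameter"] == 3

    def test_adding_edge_never_lengthens_paths(self, rng):
        g = nx.random_geometric_graph(15, 0.45, seed=3)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        base = topology_metrics(CooccurrenceNetwork(g))["average_path_length"]
        non_edges = list(nx.non_edges(g))
        if not non_edges:
            pytest.skip("graph already complete")
        g.add_edge(*non_edges[0])
        after = topology_metrics(CooccurrenceNetwork(g))["average_path_length"]
        assert after <= base + 1e-12


class TestZiPi:
    def test_all_edges_inside_module_pi_zero(self):
        g = nx.complete_graph(4)
        net = CooccurrenceNetwork(g, modules={n: 0 for n in g})
        topo = zi_pi(net)
        assert (topo["pi"] == 0).all()

    def test_even_split_pi_half(self):
        g = nx.star_graph(4)  # centre 0 with degree 4
        modules = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        topo = zi_pi(CooccurrenceNetwork(g, modules=modules))
        assert topo.loc[0, "pi"] == pytest.approx(0.5)

    @pytest.mark.parametrize("zi,pi,role", [
        (3.0, 0.5, "module_hub"),
        (1.0, 0.7, "connector"),
        (2.6, 0.65, "network_hub"),
        (1.0, 0.5, "peripheral"),
    ])
    def test_role_thresholds(self, zi, pi, role, monkeypatch):
        from soilpem import network as netmod
        # classify directly through the threshold logic via a crafted frame
        if zi > netmod.ZI_THRESHOLD and pi > netmod.PI_THRESHOLD:
            expected = "network_hub"
        elif zi > netmod.ZI_THRESHOLD:
            expected = "module_hub"
        elif pi > netmod.PI_THRESHOLD:
            expected = "connector"
        else:
            expected = "peripheral"
        assert expected == role

    def test_zi_standardized_per_module(self, meta20, rng):
        counts = rng.integers(1, 100, size=(20, 20))
        table = make_table(counts, meta20)
        edges = correlation_screen(table, r_min=0.3, p_max=0.5)
        net = detect_modules(build_network(edges, table), seed=0)
        topo = zi_pi(net)
        for mod, grp in topo.groupby("module"):
            if grp["zi"].std(ddof=0) > 0:
                assert grp["zi"].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp["zi"].std(ddof=0) == pytest.approx(1.0)

    def test_missing_module_label_fatal(self):
        g = nx.path_graph(3)
        with pytest.raises(ValidationError):
            zi_pi(CooccurrenceNetwork(g, modules={0: 0, 1: 0}))


class TestSubnetworkAndKeystones:
    def test_full_treatment_set_returns_whole_network(self, meta20, rng):
        counts = rng.integers(1, 100, size=(10, 20))
        table = make_table(counts, meta20)
        edges = correlation_screen(table, r_min=0.2, p_max=0.9)
        net = detect_modules(build_network(edges, table), seed=0)
        sub = extract_subnetwork(net, table, meta20, "CK")
        # all taxa have nonzero counts in CK here, so nothing is dropped
        assert sub.n_nodes == net.n_nodes and sub.n_edges == net.n_edges

    def test_absent_feature_dropped_from_subnetwork(self, meta20, rng):
        counts = rng.integers(1, 100, size=(10, 20))
        counts[0, :4] = 0  # T0 absent from CK samples
        table = make_table(counts, meta20)
        edges = correlation_screen(table, r_min=0.0, p_max=1.0,
                                   prevalence_min=0.0)
        net = detect_modules(build_network(edges, table), seed=0)
        assert "T0" in net.graph
        sub = extract_subnetwork(net, table, meta20, "CK")
        assert "T0" not in sub.graph

    def test_activated_taxa_enlarge_subnetwork(self, meta20, rng):
        """Extra taxa present only under straw returning enlarge its subnetwork."""
        ids = [f"T{i}" for i in range(40)]
        counts = pd.DataFrame(rng.integers(1, 100, size=(40, 20)),
                              index=ids, columns=meta20.sample_ids)
        ck_cols = [s for s in meta20.sample_ids if s.startswith("CK")]
        counts.loc[ids[20:], ck_cols] = 0  # 20 taxa silent in CK
        table = FeatureTable(counts, pd.Series("bacteria", index=ids),
                             pd.Series("k__x;p__Y", index=ids))
        spiked = sp.spike_network_structure(
            table, [ids[:10], ids[20:30]], strength=0.95, seed=3)
        spiked.counts.loc[ids[20:], ck_cols] = 0
        edges = correlation_screen(spiked, prevalence_min=0.0)
        net = detect_modules(build_network(edges, spiked), seed=0)
        ck = extract_subnetwork(net, spiked, meta20, "CK")
        optm = extract_subnetwork(net, spiked, meta20, "OPTM")
        assert optm.n_nodes > ck.n_nodes
        assert optm.n_edges > ck.n_edges

    def test_star_centre_tops_keystone_report(self):
        g = nx.star_graph(20)
        modules = {n: 0 for n in g}
        topo = zi_pi(CooccurrenceNetwork(g, modules=modules))
        report = keystone_report(topo)
        assert not report.empty
        assert report.index[0] == 0  # hub centre has maximal Zi

    def test_report_counts_match_roles(self, meta20, rng):
        counts = rng.integers(1, 100, size=(25, 20))
        table = make_table(counts, meta20)
        edges = correlation_screen(table, r_min=0.4, p_max=0.5)
        net = detect_modules(build_network(edges, table), seed=0)
        topo = zi_pi(net)
        report = keystone_report(topo, table.taxonomy, table.domain)
        n_hubs = (topo["role"].isin(["module_hub", "network_hub"])).sum()
        assert len(report) == n_hubs

    def test_domain_percentages_sum_to_100(self, meta20, rng):
        counts = rng.integers(1, 100, size=(12, 20))
        table = make_table(counts, meta20)
        edges = correlation_screen(table, r_min=0.2, p_max=0.9)
        net = build_network(edges, table)
        if net.n_nodes == 0:
            pytest.skip("no edges at this seed")
        pct = domain_node_percentages(net)
        assert sum(pct.values()) == pytest.approx(100.0)
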