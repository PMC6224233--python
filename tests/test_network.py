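"""Zero-order network construction, centralities, hubs, module permutation."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agemeta.network import (
    build_zero_order,
    centralities,
    components_and_modules,
    module_permutation_p,
    select_hubs,
)
from agemeta.synthetic import CompendiumSpec, generate_compendium, generate_ppi


def edges_df(pairs, score=950):
    return pd.DataFrame([
        {"protein1": a, "protein2": b, "combined_score": score} for a, b in pairs
    ])


def brute_betweenness(graph):
    """All-pairs shortest-path enumeration by BFS path counting (no Brandes)."""
    nodes = list(graph.nodes)
    adj = {v: set(graph.neighbors(v)) for v in nodes}

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        q = deque([src])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        return dist, sigma

    info = {v: bfs(v) for v in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sig_s = info[s]
        if t not in dist_s:
            continue
        d_st = dist_s[t]
        total = sig_s[t]
        dist_t, sig_t = info[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d_st:
                bc[v] += sig_s[v] * sig_t[v] / total
    return bc


class TestBuildZeroOrder:
    def test_threshold_and_seed_restriction(self):
        edges = edges_df([("A", "B")], 950)
        edges = pd.concat([edges, edges_df([("A", "D")], 990), edges_df([("B", "C")], 800)])
        g, log = build_zero_order(edges, {"A", "B", "C"}, score_threshold=900)
        assert set(g.edges) == {("A", "B")}
        assert log["n_isolated_seeds"] == 1  # C
        assert "D" not in g

    def test_zero_threshold_keeps_all_seed_edges(self):
        edges = edges_df([("A", "B"), ("B", "C"), ("A", "C")], 100)
        g, _ = build_zero_order(edges, {"A", "B", "C"}, score_threshold=0)
        assert g.number_of_edges() == 3

    def test_self_loops_and_duplicates_collapsed(self):
        edges = edges_df([("A", "A"), ("A", "B"), ("B", "A")], 950)
        g, _ = build_zero_order(edges, {"A", "B"})
        assert set(g.edges) == {("A", "B")}

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            build_zero_order(edges_df([("A", "B")]), set())

    def test_degrees_match_raw_edge_list_recount(self):
        _, truth = generate_compendium(CompendiumSpec(
            n_studies=2, genes_total=150, n_young=4, n_old=4,
            frac_up=0.3, frac_down=0.3, seed=8))
        edges = generate_ppi(truth, intra_p=0.4, inter_p=0.05, seed=8)
        seeds = sorted(truth.de_genes)
        g, _ = build_zero_order(edges, seeds, score_threshold=900)
        seed_set = set(seeds)
        for node in g.nodes:
            recount = sum(
                1 for a, b, s in edges.itertuples(index=False)
                if node in (a, b) and a != b and s >= 900
                and a in seed_set and b in seed_set
            )
            assert g.degree[node] == recount


class TestCentralities:
    def test_path_graph(self):
        g, _ = build_zero_order(edges_df([("A", "B"), ("B", "C")]), {"A", "B", "C"})
        table = centralities(g).set_index("gene")
        assert table.loc["B", "betweenness"] == 1.0
        assert table.loc["A", "betweenness"] == 0.0
        assert table.loc["B", "degree"] == 2

    def test_star_graph(self):
        pairs = [("X", f"L{i}") for i in range(4)]
        g, _ = build_zero_order(edges_df(pairs), {"X", "L0", "L1", "L2", "L3"})
        table = centralities(g).set_index("gene")
        assert table.loc["X", "betweenness"] == 6.0  # C(4,2) leaf pairs
        assert table.loc["X", "degree"] == 4

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            if g.number_of_edges() == 0:
                continue
            table = centralities(g).set_index("gene")
            ref = brute_betweenness(g)
            for node in g.nodes:
                assert table.loc[node, "betweenness"] == pytest.approx(ref[node], abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            centralities(nx.Graph())


class TestSelectHubs:
    def _table(self, rows):
        t = pd.DataFrame(rows, columns=["gene", "degree", "betweenness"])
        t = t.sort_values(["betweenness", "degree", "gene"],
                          ascending=[False, False, True]).reset_index(drop=True)
        t["rank"] = np.arange(1, len(t) + 1)
        return t

    def test_high_degree_top_bc_is_hub(self):
        rows = [("HUB", 30, 500.0)] + [(f"g{i}", 3, 10.0) for i in range(99)]
        out = select_hubs(self._table(rows), n_total_genes=100)
        assert out.set_index("gene").loc["HUB", "hub"]

    def test_degree_floor_blocks_top_bc_node(self):
        rows = [("LOWDEG", 9, 500.0)] + [(f"g{i}", 12, 10.0) for i in range(20)]
        out = select_hubs(self._table(rows), n_total_genes=21)
        assert not out.set_index("gene").loc["LOWDEG", "hub"]

    def test_rank_cut_uses_total_gene_denominator(self):
        rows = [(f"g{i}", 15, 100.0 - i) for i in range(20)]
        out = select_hubs(self._table(rows), top_fraction=0.10, n_total_genes=50)
        assert out.hub.sum() == 5  # ceil(0.10 * 50)

    def test_row_order_invariance(self, rng):
        rows = [(f"g{i}", int(rng.integers(1, 30)), float(rng.integers(0, 50)))
                for i in range(40)]
        a = select_hubs(self._table(rows), n_total_genes=40)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        b = select_hubs(self._table(shuffled), n_total_genes=40)
        assert list(a.gene) == list(b.gene)
        assert list(a.hub) == list(b.hub)

    def test_engineered_hubs_exactly_selected(self):
        """Three nodes wired for high degree and betweenness are the hub set."""
        rng = np.random.default_rng(42)
        g = nx.Graph()
        others = [f"g{i:03d}" for i in range(200)]
        hubs = ["HUB1", "HUB2", "HUB3"]
        # sparse background among the others
        for _ in range(150):
            a, b = rng.choice(others, 2, replace=False)
            if a != b:
                g.add_edge(a, b)
        # each hub connects to many background nodes -> high degree and BC
        for h in hubs:
            for n in rng.choice(others, 40, replace=False):
                g.add_edge(h, n)
        table = centralities(g)
        out = select_hubs(table, dc_min=10, top_fraction=0.10, n_total_genes=30)
        assert sorted(out.gene[out.hub]) == hubs


class TestModules:
    def test_two_triangles_fail_size_filter(self):
        pairs = [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        g, _ = build_zero_order(edges_df(pairs), {p for pr in pairs for p in pr})
        comps, modules = components_and_modules(g, min_size=5, n_perm=100, seed=0)
        assert len(comps) == 2
        assert modules == []

    def test_planted_clique_detected(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(100, 0.03, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(100)})
        clique = [f"n{i:03d}" for i in range(5)]
        for a, b in itertools.combinations(clique, 2):
            g.add_edge(a, b)
        # ensure the graph is connected enough for one big component
        comps = list(nx.connected_components(g))
        comps.sort(key=len, reverse=True)
        main = comps[0]
        for c in comps[1:]:
            g.add_edge(next(iter(c)), next(iter(main)))
        _, modules = components_and_modules(g, min_size=5, n_perm=999, seed=9)
        best = [m for m in modules if set(clique) <= set(m.members)]
        assert best, "planted clique not recovered inside any significant module"
        assert best[0].p_value <= 0.01

    def test_permutation_p_deterministic_under_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(40)})
        members = [f"n{i}" for i in range(6)]
        pool = list(g.nodes)
        r1 = module_permutation_p(g, members, pool, n_perm=199, seed=77)
        r2 = module_permutation_p(g, members, pool, n_perm=199, seed=77)
        assert r1 == r2

    def test_permutation_null_is_calibrated(self):
        """For pre-specified node sets on unstructured random graphs the
        permutation p is valid: at most ~5-10% reach p < 0.05."""
        sig = total = 0
        for seed in range(50):
            g = nx.gnp_random_graph(60, 0.08, seed=seed)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(60)})
            comps = sorted(nx.connected_components(g), key=len, reverse=True)
            continent = sorted(comps[0])
            if len(continent) < 20:
                continue
            rng = np.random.default_rng(seed)
            for _ in range(4):
                members = list(rng.choice(continent, 7, replace=False))
                total += 1
                _, p = module_permutation_p(g, members, continent,
                                            n_perm=199, seed=int(rng.integers(2**31)))
                if p < 0.05:
                    sig += 1
        assert total >= 100
        assert sig / total <= 0.10

    def test_planted_partition_recovery(self):
        """Communities of the generator are recovered from a clean graph."""
        _, truth = generate_compendium(CompendiumSpec(
            n_studies=2, genes_total=120, n_young=4, n_old=4,
            frac_up=0.5, frac_down=0.33, module_size=20, seed=13))
        edges = generate_ppi(truth, intra_p=1.0, inter_p=0.0, seed=13)
        g, _ = build_zero_order(edges, sorted(truth.de_genes))
        comps, modules = components_and_modules(g, min_size=5, n_perm=199, seed=4)
        planted = {}
        for gene, m in truth.planted_module_assignments.items():
            planted.setdefault(m, set()).add(gene)
        planted_sets = {frozenset(v) for v in planted.values() if len(v) >= 5}
        found_sets = {frozenset(c) for c in comps}
        assert planted_sets <= found_sets
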