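import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from microstrat.network import (
    SpearmanCooccurrence,
    bipartite_function_host,
    build_network,
    classify_roles,
    detect_modules,
    network_summary,
    prevalence_filter,
    spearman_matrix,
    zi_pi,
)


class TestPrevalenceFilter:
    def test_zero_threshold_is_identity(self, random_table):
        table = random_table(seed=0)
        pd.testing.assert_frame_equal(prevalence_filter(table, 0.0), table)

    def test_low_prevalence_taxon_removed(self):
        table = pd.DataFrame(np.ones((10, 2), int), columns=["keep", "drop"])
        table.index = table.index.astype(str)
        table.loc[:, "drop"] = 0
        table.iloc[:2, 1] = 1  # present in 2/10 samples
        kept = prevalence_filter(table, 0.3)
        assert list(kept.columns) == ["keep"]

    def test_brute_force_presence_recount(self, random_table):
        table = random_table(seed=6, depth=3)  # many zeros
        threshold = 0.4
        kept = set(prevalence_filter(table, threshold).columns)
        expected = {
            t for t in table.columns
            if (table[t] > 0).sum() / len(table) >= threshold
        }
        assert kept == expected

    def test_all_removed_is_error(self):
        table = pd.DataFrame(np.zeros((5, 3), int), columns=list("abc"))
        table.index = table.index.astype(str)
        with pytest.raises(ValueError, match="removed all"):
            prevalence_filter(table, 0.5)


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        table = pd.DataFrame(
            {"up": [1, 2, 3, 4, 5], "up2": [2, 4, 8, 16, 32], "down": [9, 7, 5, 3, 1]},
            index=[f"s{i}" for i in range(5)],
        )
        rho, _ = spearman_matrix(table)
        assert rho.loc["up", "up2"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)

    def test_rank_then_pearson_oracle(self, random_table):
        table = random_table(seed=8, n_samples=12, n_taxa=20)
        rho, p = spearman_matrix(table)
        for a, b in itertools.combinations(table.columns, 2):
            ra = stats.rankdata(table[a])
            rb = stats.rankdata(table[b])
            expected = stats.pearsonr(ra, rb).statistic
            assert rho.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_constant_taxon_is_nan_and_warns(self):
        table = pd.DataFrame(
            {"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]}, index=[f"s{i}" for i in range(4)]
        )
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(table)
        assert np.isnan(rho.loc["a", "b"])

    def test_too_few_samples(self, random_table):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(random_table(n_samples=3))


class TestBuildNetwork:
    def test_all_below_threshold_gives_empty_graph(self, random_table):
        rho, p = spearman_matrix(random_table(seed=1, n_samples=30, n_taxa=8))
        g = build_network(rho, p, r_threshold=0.999)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_toy_two_pairs(self):
        # two perfectly correlated pairs plus an unrelated taxon
        rng = np.random.default_rng(0)
        base1, base2 = rng.normal(size=10), rng.normal(size=10)
        table = pd.DataFrame(
            {
                "a1": base1, "a2": base1 + 100,
                "b1": base2, "b2": -base2,
                "c": rng.normal(size=10),
            },
            index=[f"s{i}" for i in range(10)],
        )
        table = (table - table.min().min() + 1).round(3)
        rho, p = spearman_matrix(table)
        g = build_network(rho, p, r_threshold=0.9, correction="bh")
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 2
        assert g.edges[("a1", "a2")]["sign"] == 1
        assert g.edges[("b1", "b2")]["sign"] == -1

    def test_exhaustive_threshold_scan_oracle(self, random_table):
        from statsmodels.stats.multitest import multipletests

        table = random_table(seed=3, n_samples=15, n_taxa=12)
        rho, p = spearman_matrix(table)
        r_thr = 0.45
        g = build_network(rho, p, r_threshold=r_thr, alpha=0.05, correction="bh")
        pairs = list(itertools.combinations(range(12), 2))
        raw = [p.iloc[i, j] for i, j in pairs]
        adj = multipletests(raw, method="fdr_bh")[1]
        expected = {
            frozenset((table.columns[i], table.columns[j]))
            for (i, j), pa in zip(pairs, adj)
            if abs(rho.iloc[i, j]) > r_thr and pa < 0.05
        }
        assert {frozenset(e) for e in g.edges} == expected

    def test_graph_is_simple_undirected(self, random_table):
        rho, p = spearman_matrix(random_table(seed=4))
        g = build_network(rho, p, r_threshold=0.3)
        assert not g.is_directed()
        assert all(u != v for u, v in g.edges)


class TestDetectModules:
    def test_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        modules = detect_modules(g)
        assert len(set(modules.values())) == 2
        for comp in nx.connected_components(g):
            assert len({modules[n] for n in comp}) == 1

    def test_triangle_is_one_module(self):
        modules = detect_modules(nx.complete_graph(3))
        assert len(set(modules.values())) == 1

    def test_deterministic(self):
        g = nx.planted_partition_graph(2, 15, 0.5, 0.02, seed=5)
        assert detect_modules(g) == detect_modules(g)

    def test_planted_partition_recovery(self):
        scores = []
        for seed in range(20):
            g = nx.planted_partition_graph(2, 15, 0.5, 0.02, seed=seed)
            truth = [0] * 15 + [1] * 15
            modules = detect_modules(g)
            scores.append(adjusted_rand_score(truth, [modules[n] for n in range(30)]))
        assert np.mean(scores) >= 0.9


class TestZiPi:
    def test_all_edges_in_own_module_gives_pi_zero(self):
        g = nx.complete_graph(4)
        topo = zi_pi(g, {n: 0 for n in g})
        assert (topo["Pi"] == 0.0).all()

    def test_even_split_gives_half(self):
        g = nx.star_graph(4)  # center 0 with 4 leaves
        modules = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        topo = zi_pi(g, modules)
        assert topo.loc[0, "Pi"] == pytest.approx(0.5)

    def test_brute_force_tally_oracle(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(25, 0.25, seed=12)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules = {n: n % 3 for n in g}
        topo = zi_pi(g, modules)
        for node in g:
            k = g.degree(node)
            per_module = {}
            for nbr in g.neighbors(node):
                per_module[modules[nbr]] = per_module.get(modules[nbr], 0) + 1
            pi = 1 - sum((v / k) ** 2 for v in per_module.values())
            own = modules[node]
            within = [
                sum(1 for nbr in g.neighbors(m) if modules[nbr] == own)
                for m in g if modules[m] == own
            ]
            mu, sd = np.mean(within), np.std(within)
            zi = 0.0 if sd == 0 else (per_module.get(own, 0) - mu) / sd
            assert topo.loc[node, "Pi"] == pytest.approx(pi, abs=1e-12)
            assert topo.loc[node, "Zi"] == pytest.approx(zi, abs=1e-12)

    def test_degree_partition_identity_and_zi_mean(self):
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules = detect_modules(g)
        topo = zi_pi(g, modules)
        # per-module Zi mean is 0 wherever sd > 0
        for s, group in topo.groupby("module"):
            if group["within_degree"].std(ddof=0) > 0:
                assert group["Zi"].mean() == pytest.approx(0.0, abs=1e-10)
        # sum over modules of k_{i,t} equals k_i, via Pi's construction
        for node in topo.index:
            assert topo.loc[node, "degree"] == g.degree(node)

    def test_pi_invariant_under_module_relabeling(self):
        g = nx.gnp_random_graph(15, 0.3, seed=8)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules = {n: n % 2 for n in g}
        relabeled = {n: 1 - m for n, m in modules.items()}
        pd.testing.assert_series_equal(
            zi_pi(g, modules)["Pi"], zi_pi(g, relabeled)["Pi"]
        )

    def test_isolated_node_excluded_with_warning(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        with pytest.warns(UserWarning, match="isolated"):
            topo = zi_pi(g, {0: 0, 1: 0, 2: 1})
        assert 2 not in topo.index

    def test_uncovered_node_is_error(self):
        with pytest.raises(ValueError, match="cover"):
            zi_pi(nx.Graph([(0, 1)]), {0: 0})


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (3.0, 0.1, "module hub"),
            (0.0, 0.7, "connector"),
            (3.0, 0.8, "network hub"),
            (1.0, 0.3, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundaries are strict
        ],
    )
    def test_role_regions(self, zi, pi, role):
        topo = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
        out = classify_roles(topo)
        assert out.loc["n", "role"] == role
        assert out.loc["n", "keystone"] == (role != "peripheral")

    def test_nonfinite_rejected(self):
        topo = pd.DataFrame({"Zi": [np.nan], "Pi": [0.2]}, index=["n"])
        with pytest.raises(ValueError, match="finite"):
            classify_roles(topo)


class TestNetworkSummary:
    def test_counts_and_fractions(self):
        g = nx.path_graph(10)
        nx.set_edge_attributes(g, 1, "sign")
        labels = pd.Series(
            ["abundant"] * 3 + ["rare"] * 4 + ["intermediate"] * 3,
            index=range(10),
        )
        s = network_summary(g, labels)
        assert s.n_nodes == 10 and s.n_edges == 9
        assert s.abundance_fractions["abundant"] == pytest.approx(0.30)
        assert s.positive_edge_fraction == 1.0

    def test_empty_graph_no_division_error(self):
        s = network_summary(nx.Graph(), pd.Series(dtype=object))
        assert s.n_nodes == 0 and s.positive_edge_fraction == 0.0

    def test_brute_force_recount(self, random_table):
        table = random_table(seed=10, n_samples=20, n_taxa=15)
        model = SpearmanCooccurrence(r_threshold=0.4, min_prevalence=0.0).fit(table)
        s = network_summary(model.graph_, None, model.modules_)
        assert s.n_nodes == len(model.graph_.nodes)
        assert s.n_edges == len(model.graph_.edges)
        pos = sum(1 for *_, d in model.graph_.edges(data=True) if d["rho"] > 0)
        if s.n_edges:
            assert s.positive_edge_fraction == pytest.approx(pos / s.n_edges)
        assert sum(s.module_sizes.values()) == s.n_nodes


class TestBipartite:
    def make_tables(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        taxa = pd.DataFrame(
            rng.integers(1, 100, (n, 4)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(4)],
        )
        funcs = pd.DataFrame(
            rng.integers(1, 100, (n, 3)),
            index=taxa.index,
            columns=[f"f{j}" for j in range(3)],
        )
        return taxa, funcs

    def test_identical_vector_gives_rho_one_edge(self):
        taxa, funcs = self.make_tables(seed=2)
        funcs["f0"] = taxa["t0"]
        g = bipartite_function_host(taxa, funcs, r_threshold=0.9)
        assert ("t0", "f0") in g.edges
        assert g.edges[("t0", "f0")]["rho"] == pytest.approx(1.0)
        assert g.nodes["t0"]["kind"] == "taxon"
        assert g.nodes["f0"]["kind"] == "function"

    def test_edges_only_cross_partition(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        taxa = pd.DataFrame(
            {"t0": base, "t1": base * 2 + 1}, index=[f"s{i}" for i in range(12)]
        ) + 10
        funcs = pd.DataFrame({"f0": base + 5}, index=taxa.index)
        g = bipartite_function_host(taxa, funcs, r_threshold=0.9)
        # t0-t1 correlate perfectly but are never candidates
        assert ("t0", "t1") not in g.edges
        assert {("t0", "f0"), ("t1", "f0")} <= {tuple(e) for e in g.edges} | {
            tuple(reversed(e)) for e in g.edges
        }

    def test_orthogonal_vectors_no_edge(self):
        taxa, funcs = self.make_tables(seed=5, n=20)
        g = bipartite_function_host(taxa, funcs, r_threshold=0.9)
        assert g.number_of_edges() == 0

    def test_sample_mismatch_error(self):
        taxa, funcs = self.make_tables()
        with pytest.raises(ValueError, match="samples"):
            bipartite_function_host(taxa, funcs.iloc[:-1])


class TestSpearmanCooccurrenceEstimator:
    def test_fit_sets_attributes_and_sklearn_params(self, random_table):
        table = random_table(seed=9, n_samples=25, n_taxa=12)
        model = SpearmanCooccurrence(r_threshold=0.4, min_prevalence=0.1)
        assert model.get_params()["r_threshold"] == 0.4
        model.set_params(r_threshold=0.45)
        model.fit(table)
        assert hasattr(model, "graph_") and hasattr(model, "topology_")
        assert set(model.modules_) == set(model.graph_.nodes)
        assert set(model.keystones_) <= set(model.graph_.nodes)

    def test_clone_compatible(self):
        from sklearn.base import clone

        model = SpearmanCooccurrence(r_threshold=0.5)
        assert clone(model).get_params() == model.get_params()
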