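import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adniche.abundance import AsvTable
from adniche.errors import (
    DegenerateTableError,
    InsufficientSamplesError,
    InvalidInputError,
)
from adniche.network import (
    build_network,
    components,
    composition_chisq,
    spearman_assoc,
    top_n_taxa,
)
from oracles import chi2_mc_p, exact_spearman_p_positive


def _abs_table(arr, taxa=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return AsvTable(pd.DataFrame(arr, index=taxa, columns=samples), mode="absolute")


class TestTopN:
    def test_identity_when_n_large(self, small_table):
        out = top_n_taxa(small_table, 100)
        assert out.taxa == small_table.taxa

    def test_single_most_abundant(self, small_table):
        out = top_n_taxa(small_table, 1)
        totals = small_table.data.sum(axis=1)
        assert out.taxa == [totals.idxmax()]

    def test_tie_broken_lexicographically(self):
        table = _abs_table([[5, 5], [4, 6], [6, 4]], taxa=["b", "c", "a"])
        out = top_n_taxa(table, 2)
        # all totals equal 10: lexicographic order decides
        assert out.taxa == ["a", "b"]


class TestSpearman:
    def test_perfect_monotone_exact_p(self):
        x = np.arange(5.0)
        rho, p = spearman_assoc(x, x * 2 + 1, method="exact")
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 120)

    def test_anti_monotone(self):
        x = np.arange(6.0)
        rho, p = spearman_assoc(x, -x, method="exact")
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1.0)

    def test_exact_matches_brute_force(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p = spearman_assoc(x, y, method="exact")
        assert p == pytest.approx(exact_spearman_p_positive(x, y))
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_t_approx_close_to_mc(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=12), rng.normal(size=12)
        _, p_t = spearman_assoc(x, y, method="t_approx")
        _, p_mc = spearman_assoc(x, y, method="exact", n_perm=10_000, seed=0)
        assert abs(p_t - p_mc) < 0.02

    def test_constant_series_error(self):
        with pytest.raises(InvalidInputError):
            spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])


class TestBuildNetwork:
    def _classes(self, taxa, cls="tolerant"):
        return pd.DataFrame({"nh3_class": [cls] * len(taxa)}, index=taxa)

    def test_identical_monotone_profiles_linked(self):
        base = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        arr = np.vstack([base, base * 3, base[::-1], [5, 1, 4, 2, 8, 3, 7, 6]])
        table = _abs_table(arr)
        g = build_network(table, self._classes(table.taxa), set(), seed=0, n_perm=499)
        assert g.has_edge("t0", "t1")
        assert g["t0"]["t1"]["rho"] == pytest.approx(1.0)
        assert not g.has_edge("t0", "t2")  # anti-correlated: positive-only rule

    def test_every_taxon_is_a_node(self):
        rng = np.random.default_rng(0)
        table = _abs_table(rng.random((6, 8)))
        g = build_network(table, self._classes(table.taxa), set(), seed=0, n_perm=199)
        assert set(g.nodes) == set(table.taxa)

    def test_node_typing(self):
        base = np.arange(8.0) + 1
        table = _abs_table([base, base, base], taxa=["s_tax", "t_tax", "m_tax"])
        classes = pd.DataFrame(
            {"nh3_class": ["sensitive", "tolerant", "enriched"]},
            index=["s_tax", "t_tax", "m_tax"],
        )
        g = build_network(table, classes, {"m_tax"}, seed=0, n_perm=199)
        assert g.nodes["s_tax"]["node_type"] == "sensitive"
        assert g.nodes["t_tax"]["node_type"] == "tolerant"
        # enriched taxa are NH3-tolerant in the two-way node typing
        assert g.nodes["m_tax"]["node_type"] == "tolerant_methanogen"

    def test_edge_set_shrinks_with_alpha(self):
        rng = np.random.default_rng(8)
        shared = rng.normal(size=10)
        arr = np.exp(shared + rng.normal(0, 0.4, size=(8, 10)))
        table = _abs_table(arr)
        edges = {}
        for alpha in (0.2, 0.05, 0.01):
            g = build_network(
                table, self._classes(table.taxa), set(), alpha=alpha, seed=1, n_perm=999
            )
            edges[alpha] = set(map(tuple, map(sorted, g.edges)))
        assert edges[0.01] <= edges[0.05] <= edges[0.2]

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        arr = rng.random((5, 9)) + 0.1
        t1 = _abs_table(arr)
        t2 = _abs_table(arr**3)
        g1 = build_network(t1, self._classes(t1.taxa), set(), seed=2, n_perm=499)
        g2 = build_network(t2, self._classes(t2.taxa), set(), seed=2, n_perm=499)
        assert set(g1.edges) == set(g2.edges)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        arr = rng.random((6, 8))
        table = _abs_table(arr)
        g1 = build_network(table, self._classes(table.taxa), set(), seed=7, n_perm=299)
        g2 = build_network(table, self._classes(table.taxa), set(), seed=7, n_perm=299)
        assert set(g1.edges) == set(g2.edges)
        for e in g1.edges:
            assert g1.edges[e]["p"] == g2.edges[e]["p"]

    def test_too_few_samples(self):
        table = _abs_table(np.ones((3, 3)))
        with pytest.raises(InsufficientSamplesError):
            build_network(table, self._classes(table.taxa), set())


class TestComponents:
    def _net(self, n, edges, meth=()):
        import networkx as nx

        g = nx.Graph()
        for i in range(n):
            name = f"t{i}"
            g.add_node(
                name,
                nh3_class="tolerant",
                is_methanogen=name in meth,
                node_type="tolerant_methanogen" if name in meth else "tolerant",
            )
        g.add_edges_from(edges)
        return g

    def test_no_edges_every_node_own_cluster(self):
        assignment, summary = components(self._net(4, []))
        assert len(set(assignment.values())) == 4
        assert (summary["size"] == 1).all()

    def test_complete_graph_single_cluster(self):
        import itertools

        nodes = [f"t{i}" for i in range(4)]
        assignment, summary = components(
            self._net(4, list(itertools.combinations(nodes, 2)))
        )
        assert set(assignment.values()) == {0}

    def test_two_triangles(self):
        edges = [("t0", "t1"), ("t1", "t2"), ("t0", "t2"),
                 ("t3", "t4"), ("t4", "t5"), ("t3", "t5")]
        assignment, summary = components(self._net(6, edges, meth=("t4",)))
        assert len(summary) == 2 and set(summary["size"]) == {3}
        cluster_of_t4 = assignment["t4"]
        row = summary[summary["cluster"] == cluster_of_t4].iloc[0]
        assert bool(row["has_methanogen"])


class TestCompositionChisq:
    def _net_with_counts(self, label, counts):
        import networkx as nx

        g = nx.Graph(condition=label)
        i = 0
        for node_type, k in counts.items():
            base = node_type.replace("_methanogen", "")
            for _ in range(k):
                g.add_node(
                    f"{label}_{i}",
                    nh3_class=base,
                    is_methanogen="methanogen" in node_type,
                    node_type=node_type,
                )
                i += 1
        return g

    def test_hand_example(self):
        n1 = self._net_with_counts("a", {"sensitive": 10, "tolerant": 20})
        n2 = self._net_with_counts("b", {"sensitive": 20, "tolerant": 10})
        res = composition_chisq([n1, n2])
        assert res.chi2 == pytest.approx(6.667, abs=5e-4)
        assert res.df == 1

    def test_identical_rows_zero(self):
        n1 = self._net_with_counts("a", {"sensitive": 5, "tolerant": 5})
        n2 = self._net_with_counts("b", {"sensitive": 5, "tolerant": 5})
        res = composition_chisq([n1, n2])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_close_to_mc_multinomial(self):
        table = [[10, 20], [20, 10]]
        n1 = self._net_with_counts("a", {"sensitive": 10, "tolerant": 20})
        n2 = self._net_with_counts("b", {"sensitive": 20, "tolerant": 10})
        res = composition_chisq([n1, n2])
        assert abs(res.p_value - chi2_mc_p(table, seed=0)) < 0.02

    def test_degenerate_table(self):
        n1 = self._net_with_counts("a", {"tolerant": 5})
        n2 = self._net_with_counts("b", {"tolerant": 7})
        with pytest.raises(DegenerateTableError):
            composition_chisq([n1, n2])
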