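import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from herbconnect import (EffectVector, build_network, effect_score, rwr,
                         synergy_frame, synergy_table, z_score)
from herbconnect.netprop import (NetworkError, RWRConvergenceError,
                                 read_edge_list, read_gene_set, score_targets)


def closed_form(P, chi0, r):
    """Dense oracle: chi = r (I - (1-r) P)^{-1} chi0."""
    P = np.asarray(P.todense() if sp.issparse(P) else P)
    return r * np.linalg.solve(np.eye(P.shape[0]) - (1 - r) * P, chi0)


def triangle_edges(w=0.95):
    return [("a", "b", w), ("b", "c", w), ("a", "c", w)]


class TestBuildNetwork:
    def test_triangle_columns_sum_to_one(self):
        net = build_network(triangle_edges())
        assert net.n_nodes == 3 and net.n_edges == 3
        assert np.allclose(np.asarray(net.P.sum(axis=0)).ravel(), 1.0)
        assert (net.P.toarray() >= 0).all()

    def test_low_confidence_edges_dropped(self):
        net = build_network(triangle_edges() + [("a", "d", 0.5)])
        assert "d" not in net.node_ids

    def test_rescue_target_kept_via_best_edge(self):
        edges = triangle_edges() + [("a", "d", 0.5), ("b", "d", 0.7)]
        net = build_network(edges, rescue_targets={"d"})
        assert "d" in net.node_ids
        # rescued through the single best edge only
        d = net.node_index["d"]
        assert (net.P[:, d] > 0).sum() == 1

    def test_string_score_scale_autodetected(self):
        net = build_network([("a", "b", 950.0), ("b", "c", 920.0), ("a", "c", 400.0)])
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.component_info["weight_scale"] == 1000.0

    def test_largest_component_retained(self):
        edges = triangle_edges() + [("x", "y", 0.99)]
        net = build_network(edges)
        assert set(net.node_ids) == {"a", "b", "c"}
        assert net.component_info["n_components"] == 2

    def test_matches_filter_then_flood_fill_oracle(self):
        """200-node random graph vs an independent filter + BFS component search."""
        rng = np.random.default_rng(21)
        names = [f"n{i}" for i in range(200)]
        edges = []
        for _ in range(600):
            a, b = rng.choice(200, 2, replace=False)
            edges.append((names[a], names[b], float(rng.uniform(0.8, 1.0))))
        threshold = 0.9
        net = build_network(edges, threshold)

        # oracle: keep edges > threshold, flood-fill the components
        adj: dict[str, set[str]] = {}
        kept_edges = set()
        for a, b, w in edges:
            if w > threshold and a != b:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
                kept_edges.add(frozenset((a, b)))
        seen, components = set(), []
        for start in adj:
            if start in seen:
                continue
            comp, stack = set(), [start]
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                stack.extend(adj[node] - comp)
            seen |= comp
            components.append(comp)
        giant = max(components, key=len)
        assert set(net.node_ids) == giant
        assert net.n_edges == sum(1 for e in kept_edges if e <= giant)

    def test_empty_surviving_network_raises(self):
        with pytest.raises(NetworkError):
            build_network([("a", "b", 0.1)], confidence_threshold=0.9)


class TestRWR:
    def test_two_node_worked_value(self):
        P = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        chi = rwr(P, np.array([1.0, 0.0]), r=0.3).values
        assert chi == pytest.approx([0.5882, 0.4118], abs=5e-5)

    def test_zero_seed_stays_zero(self):
        net = build_network(triangle_edges())
        assert np.all(rwr(net, np.zeros(3)).values == 0.0)

    def test_mass_conservation(self):
        net = build_network(triangle_edges())
        chi0 = np.array([1.0, 0.01, 0.0])
        ev = rwr(net, chi0)
        assert ev.values.sum() == pytest.approx(chi0.sum(), abs=1e-8)

    def test_fixed_point_property(self):
        net = build_network(triangle_edges())
        chi0 = np.array([1.0, 0.0, 0.0])
        ev = rwr(net, chi0, tol=1e-12)
        lhs = ev.values
        rhs = 0.7 * (net.P @ ev.values) + 0.3 * chi0
        assert np.abs(lhs - rhs).sum() < 1e-10

    @pytest.mark.parametrize("n_nodes,graph_seed", [(10, 0), (40, 1), (100, 2)])
    def test_matches_dense_closed_form(self, n_nodes, graph_seed):
        import networkx as nx
        g = nx.gnp_random_graph(n_nodes, 0.15, seed=graph_seed)
        edges = [(f"n{a}", f"n{b}", 0.95) for a, b in g.edges()]
        net = build_network(edges)
        rng = np.random.default_rng(graph_seed)
        chi0 = rng.uniform(0, 1, net.n_nodes)
        assert np.max(np.abs(rwr(net, chi0).values
                             - closed_form(net.P, chi0, 0.3))) < 1e-8

    def test_restart_one_limit_returns_seed(self):
        net = build_network(triangle_edges())
        chi0 = np.array([1.0, 0.0, 0.0])
        assert np.allclose(rwr(net, chi0, r=0.999).values, chi0, atol=1e-2)

    def test_restart_zero_limit_approaches_stationary_distribution(self):
        # connected non-bipartite graph: triangle; stationary = degree/2m, uniform here
        net = build_network(triangle_edges())
        chi = rwr(net, np.array([1.0, 0.0, 0.0]), r=1e-4, tol=1e-13,
                  max_iter=500_000).values
        assert np.allclose(chi, 1 / 3, atol=1e-2)

    def test_nonconvergence_carries_residual(self):
        net = build_network(triangle_edges())
        with pytest.raises(RWRConvergenceError) as err:
            rwr(net, np.array([1.0, 0.0, 0.0]), tol=1e-14, max_iter=2)
        assert err.value.residual > 0

    def test_invalid_restart_or_shape_rejected(self):
        net = build_network(triangle_edges())
        with pytest.raises(NetworkError):
            rwr(net, np.zeros(3), r=1.5)
        with pytest.raises(NetworkError, match="length"):
            rwr(net, np.zeros(5))


class TestEffectScore:
    def _vec(self, values, ids=("a", "b", "c")):
        return EffectVector(np.asarray(values, float), tuple(ids), 0.3, 1, 0.0)

    def test_disjoint_support_is_orthogonal(self):
        assert effect_score(self._vec([1, 0, 0]), self._vec([0, 0, 2])) == 0.0

    def test_self_overlap_is_squared_norm(self):
        v = self._vec([0.2, 0.3, 0.0])
        assert effect_score(v, v) == pytest.approx(0.04 + 0.09)

    def test_matches_loop_based_dot_product_oracle(self):
        rng = np.random.default_rng(9)
        ids = tuple(f"g{i}" for i in range(50))
        a, b = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        expected = 0.0
        for x, y in zip(a, b):  # independent summation
            expected += x * y
        assert effect_score(self._vec(a, ids), self._vec(b, ids)) == pytest.approx(expected)

    def test_index_mismatch_rejected(self):
        with pytest.raises(NetworkError, match="node sets"):
            effect_score(self._vec([1, 0, 0]), self._vec([1, 0, 0], ids=("x", "y", "z")))

    def test_cosine_variant_bounded_by_one(self):
        v = self._vec([0.5, 0.1, 0.0])
        assert effect_score(v, v, normalized=True) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def net():
    import networkx as nx
    g = nx.barabasi_albert_graph(120, 3, seed=4)
    return build_network([(f"n{a}", f"n{b}", 0.95) for a, b in g.edges()])


@pytest.fixture(scope="module")
def chi_disease(net):
    chi0 = net.seed_vector([f"n{i}" for i in range(15)], 1.0)
    return rwr(net, chi0, seed_kind="disease")


@pytest.fixture(scope="module")
def planted():
    from herbconnect import ComponentSpec, NetworkScenario, simulate_network
    scenario = NetworkScenario(
        n_nodes=300, module_size=20,
        components=(ComponentSpec("near", 16, 0.75),
                    ComponentSpec("far", 16, 0.0, min_distance=3)),
        rng_seed=8)
    sim = simulate_network(scenario)
    return sim, build_network(sim.edges, 0.9)


class TestZScore:
    def test_centering_when_s_equals_null_mean(self, net, chi_disease):
        probe = z_score(0.0, net, chi_disease, n_targets=5, n_random=200, rng_seed=1)
        centred = z_score(probe.null_mean, net, chi_disease, n_targets=5,
                          n_random=200, rng_seed=1)
        assert centred.z_score == pytest.approx(0.0, abs=1e-12)

    def test_z_is_the_stored_standardization(self, net, chi_disease):
        res = z_score(0.02, net, chi_disease, n_targets=5, n_random=300, rng_seed=2)
        assert res.z_score == pytest.approx((0.02 - res.null_mean) / res.null_sd)
        assert res.n_random == 300

    def test_bit_identical_under_same_seed(self, net, chi_disease):
        a = z_score(0.05, net, chi_disease, 8, n_random=150, rng_seed=77)
        b = z_score(0.05, net, chi_disease, 8, n_random=150, rng_seed=77)
        assert (a.null_mean, a.null_sd, a.z_score) == (b.null_mean, b.null_sd, b.z_score)
        c = z_score(0.05, net, chi_disease, 8, n_random=150, rng_seed=78)
        assert a.null_mean != c.null_mean

    def test_degenerate_null_flags_undefined_z(self, caplog):
        # complete graph, target count = all nodes: every subset is identical
        net = build_network([("a", "b", 0.95), ("b", "c", 0.95), ("a", "c", 0.95)])
        chi_d = rwr(net, net.seed_vector(["a"], 1.0))
        with caplog.at_level("WARNING"):
            res = z_score(0.01, net, chi_d, n_targets=3, n_random=10, rng_seed=0)
        assert np.isnan(res.z_score) and res.flagged == "degenerate-null"

    def test_low_precision_null_warns(self, net, chi_disease, caplog):
        with caplog.at_level("WARNING"):
            z_score(0.01, net, chi_disease, 4, n_random=2, rng_seed=0)
        assert any("low-precision" in r.message for r in caplog.records)

    def test_degree_matched_sampling_runs(self, net, chi_disease):
        targets = [net.node_index[n] for n in net.node_ids[:6]]
        res = z_score(0.01, net, chi_disease, 6, n_random=50, rng_seed=3,
                      degree_matched=True, degree_matched_to=targets)
        assert np.isfinite(res.null_mean)


class TestSynergyTable:
    def test_mixture_row_first_and_all_rows_present(self, planted):
        sim, net = planted
        rows = synergy_table(sim.component_targets, sim.disease_module, net,
                             n_random=200, seed=5)
        assert rows[0].label == "mixture"
        assert {r.label for r in rows} == {"mixture", "near", "far"}

    def test_distant_component_scores_lowest(self, planted):
        sim, net = planted
        rows = {r.label: r for r in synergy_table(sim.component_targets,
                                                  sim.disease_module, net,
                                                  n_random=300, seed=5)}
        assert rows["far"].z_score < rows["near"].z_score
        assert rows["far"].z_score == min(r.z_score for r in rows.values())

    def test_identical_component_sets_make_mixture_equal_row(self, planted):
        sim, net = planted
        targets = sim.component_targets["near"]
        rows = synergy_table({"c1": targets, "c2": targets}, sim.disease_module,
                             net, n_random=300, seed=6)
        by = {r.label: r for r in rows}
        # union of identical sets: same target count and same effect score
        assert by["mixture"].target_count == by["c1"].target_count
        assert by["mixture"].effect_score == pytest.approx(by["c1"].effect_score)
        # z differs only through null noise
        assert by["mixture"].z_score == pytest.approx(by["c1"].z_score, rel=0.3)

    def test_explicit_mixture_gene_set(self, planted):
        sim, net = planted
        explicit = set(list(sim.disease_module)[:10])
        rows = synergy_table(sim.component_targets, sim.disease_module, net,
                             mixture_rule=explicit, n_random=100, seed=2)
        assert rows[0].target_count == 10

    def test_empty_target_set_flags_row_and_computes_others(self, planted, caplog):
        sim, net = planted
        sets = dict(sim.component_targets)
        sets["ghost"] = {"not_a_node_1", "not_a_node_2"}
        with caplog.at_level("WARNING"):
            rows = {r.label: r for r in synergy_table(sets, sim.disease_module, net,
                                                      n_random=100, seed=1)}
        assert rows["ghost"].flagged == "empty-target-set"
        assert np.isnan(rows["ghost"].z_score)
        assert np.isfinite(rows["near"].z_score)

    def test_frame_layout(self, planted):
        sim, net = planted
        rows = synergy_table(sim.component_targets, sim.disease_module, net,
                             n_random=100, seed=0)
        df = synergy_frame(rows)
        assert list(df.columns) == ["label", "target_number", "effect_score",
                                    "null_mean", "null_sd", "z_score", "flagged"]
        assert df.iloc[0]["label"] == "mixture"


class TestFileReaders:
    def test_edge_list_with_and_without_header(self, tmp_path):
        body = "a\tb\t0.95\nb\tc\t0.99\n"
        plain = tmp_path / "e1.tsv"
        plain.write_text(body)
        headed = tmp_path / "e2.tsv"
        headed.write_text("node_a\tnode_b\tconfidence\n" + body)
        df1, df2 = read_edge_list(plain), read_edge_list(headed)
        pd.testing.assert_frame_equal(df1, df2)
        assert df1["confidence"].tolist() == [0.95, 0.99]

    def test_gene_set_formats(self, tmp_path):
        one_col = tmp_path / "s1.txt"
        one_col.write_text("g1\ng2\n\n")
        two_col = tmp_path / "s2.txt"
        two_col.write_text("setA\tg1\nsetB\tg9\nsetA\tg3\n")
        assert read_gene_set(one_col) == {"g1", "g2"}
        assert read_gene_set(two_col, label="setA") == {"g1", "g3"}

    def test_score_targets_reports_post_intersection_count(self):
        net = build_network(triangle_edges())
        chi_d = rwr(net, net.seed_vector(["a"], 1.0))
        s, count = score_targets(net, chi_d, ["b", "zzz"])
        assert count == 1 and s > 0
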