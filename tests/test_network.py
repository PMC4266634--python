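"""Propagation kernels against closed forms and dense linear-algebra
oracles; permutation p-values against exhaustive enumeration."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from varprior.network import (
    DEFAULT_PARAMS,
    EmptySeedError,
    GeneNetwork,
    METHODS,
    NetworkError,
    SeedVector,
    load_network,
    permutation_pvalues,
    prioritize,
    propagate,
    write_edge_list,
)


def path_graph(weights=(1.0, 1.0, 1.0, 1.0)):
    nodes = [f"n{i}" for i in range(len(weights) + 1)]
    edges = [(nodes[i], nodes[i + 1], w) for i, w in enumerate(weights)]
    return GeneNetwork(nodes, edges)


def random_network(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    rng = np.random.default_rng(seed)
    edges = [(f"g{u}", f"g{v}", float(rng.uniform(0.1, 1.0)))
             for u, v in g.edges()]
    return GeneNetwork(sorted({f"g{n}" for n in g.nodes}), edges)


class TestLoadNetwork:
    def test_string_score_scaling_and_threshold(self, tmp_path):
        path = tmp_path / "edges.txt"
        path.write_text("A B 900\nB C 350\nC D 700\nD E 100\n")
        net = load_network(path, score_threshold=400,
                           largest_component=False)
        weights = {frozenset((u, v)): w for u, v, w in net.edge_list()}
        assert weights == {
            frozenset(("A", "B")): 0.9,
            frozenset(("C", "D")): 0.7,
        }

    def test_largest_component_retained(self, tmp_path):
        path = tmp_path / "edges.txt"
        path.write_text("A B 500\nB C 500\nX Y 500\n")
        assert sorted(load_network(path).nodes) == ["A", "B", "C"]
        assert len(load_network(path, largest_component=False)) == 5

    def test_operator_rows_sum_to_one(self, tmp_path):
        path = tmp_path / "edges.txt"
        path.write_text("A B 900\nB C 350\nC D 700\nD E 100\nA E 250\n")
        net = load_network(path, largest_component=False)
        # PT columns are the row-stochastic rows of P
        col_sums = np.asarray(net.PT.sum(axis=0)).ravel()
        assert np.allclose(col_sums, 1.0, atol=1e-12)

    def test_non_numeric_score_raises(self, tmp_path):
        path = tmp_path / "edges.txt"
        path.write_text("A B high\n")
        with pytest.raises(NetworkError):
            load_network(path)

    def test_edge_list_roundtrip(self, tmp_path):
        net = random_network(20, 0.3, seed=5)
        path = tmp_path / "rt.txt"
        write_edge_list(net, path)
        again = load_network(path, largest_component=False)
        assert dict(
            (frozenset((u, v)), round(w, 3)) for u, v, w in again.edge_list()
        ) == dict(
            (frozenset((u, v)), round(w, 3)) for u, v, w in net.edge_list()
        )


class TestPropagate:
    def test_restart_one_returns_seed_vector(self):
        net = path_graph()
        res = propagate(net, ["n0", "n2"], params={"restart": 1.0})
        seeds = SeedVector(net, ["n0", "n2"])
        assert np.allclose(res.scores, seeds.vector)

    def test_kstep_one_step_on_edge(self):
        net = GeneNetwork(["a", "b"], [("a", "b", 0.8)])
        res = propagate(net, ["a"], "kstep_markov", {"k": 1})
        assert res.scores[net.index["b"]] == pytest.approx(1.0)
        assert res.scores[net.index["a"]] == pytest.approx(0.0)

    def test_kstep_one_equals_transition_applied_to_seed(self):
        net = random_network(15, 0.4, seed=8)
        seeds = SeedVector(net, [net.nodes[0], net.nodes[3]])
        res = propagate(net, seeds, "kstep_markov", {"k": 1})
        assert np.allclose(res.scores, net.PT @ seeds.vector, atol=1e-12)

    @pytest.mark.parametrize("restart", [0.3, 0.7])
    def test_restart_walk_matches_dense_solve(self, restart):
        """s = r (I - (1-r) P^T)^-1 p0, the stationary point of the walk."""
        net = random_network(5, 0.8, seed=1)
        seeds = SeedVector(net, [net.nodes[0]])
        res = propagate(net, seeds, "random_walk_restart",
                        {"restart": restart})
        n = len(net)
        direct = restart * np.linalg.solve(
            np.eye(n) - (1 - restart) * net.PT.toarray(), seeds.vector
        )
        assert res.converged
        assert np.abs(res.scores - direct).max() < 1e-8

    def test_heat_kernel_matches_matrix_exponential(self):
        net = random_network(12, 0.5, seed=3)
        seeds = SeedVector(net, [net.nodes[1]])
        res = propagate(net, seeds, "heat_kernel", {"t": 1.0, "terms": 30})
        n = len(net)
        oracle = expm(-1.0 * (np.eye(n) - net.PT.toarray())) @ seeds.vector
        assert np.abs(res.scores - oracle).max() < 1e-9

    def test_pagerank_is_restart_walk_with_damping(self):
        net = random_network(10, 0.5, seed=6)
        a = propagate(net, [net.nodes[0]], "pagerank_priors",
                      {"damping": 0.85})
        b = propagate(net, [net.nodes[0]], "random_walk_restart",
                      {"restart": 0.15})
        assert np.allclose(a.scores, b.scores, atol=1e-8)

    @pytest.mark.parametrize("method", METHODS)
    def test_nonnegative_and_mass(self, method):
        net = random_network(25, 0.3, seed=11)
        res = propagate(net, [net.nodes[0], net.nodes[5]], method)
        assert (res.scores >= 0).all()
        if method != "hits_priors":
            assert res.scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_seed_support_raises(self):
        net = path_graph()
        with pytest.raises(EmptySeedError):
            propagate(net, ["absent"])

    def test_unknown_method_raises(self):
        with pytest.raises(NetworkError):
            propagate(path_graph(), ["n0"], "laplace")

    def test_isolated_node_scores_zero(self):
        net = GeneNetwork(["a", "b", "iso"], [("a", "b", 0.5)])
        res = propagate(net, ["a"])
        assert res.scores[net.index["iso"]] == 0.0


class TestPermutations:
    def test_complete_graph_symmetry_gives_p_one(self):
        nodes = [f"k{i}" for i in range(5)]
        edges = [(u, v, 0.7) for u, v in itertools.combinations(nodes, 2)]
        net = GeneNetwork(nodes, edges)
        df = permutation_pvalues(net, ["k0"], n_perm=50, rng_seed=1)
        assert (df["p_value"] == 1.0).all()

    def test_matches_exhaustive_enumeration_on_four_nodes(self):
        """Single seed on 4 nodes: only 4 distinct placements exist, so
        the exact p-value is the fraction of placements tying/beating
        the observed score."""
        net = path_graph(weights=(0.9, 0.2, 0.6))
        seeds = SeedVector(net, ["n0"])
        observed = propagate(net, seeds).scores
        exact = np.zeros(len(net))
        for node in net.nodes:
            placed = propagate(net, [node], "random_walk_restart").scores
            exact += placed >= observed
        exact /= len(net)
        df = permutation_pvalues(net, seeds, n_perm=2000, rng_seed=7)
        for row in df.itertuples(index=False):
            i = net.index[row.gene]
            # binomial error at n_perm=2000 stays well under 0.05
            assert abs(row.p_value - exact[i]) < 0.05

    def test_determinism_under_rng_seed(self):
        net = random_network(20, 0.3, seed=2)
        kw = dict(n_perm=100, rng_seed=42)
        a = permutation_pvalues(net, [net.nodes[0]], **kw)
        b = permutation_pvalues(net, [net.nodes[0]], **kw)
        assert a.equals(b)

    def test_add_one_correction_bounds_p_away_from_zero(self):
        net = random_network(20, 0.3, seed=2)
        df = permutation_pvalues(net, [net.nodes[0]], n_perm=50, rng_seed=0,
                                 add_one_correction=True)
        assert (df["p_value"] >= 1 / 51).all()


class TestPrioritize:
    def test_published_cut_keeps_three_of_four(self):
        import pandas as pd

        df = pd.DataFrame({
            "gene": list("abcd"),
            "score": [0.4, 0.3, 0.2, 0.1],
            "p_value": [0.0, 0.002, 0.0028, 0.01],
            "rank": [1, 2, 3, 4],
        })
        out = prioritize(df, alpha=0.005)
        assert list(out["gene"]) == ["a", "b", "c"]

    def test_alpha_one_keeps_all_and_sorts(self):
        import pandas as pd

        df = pd.DataFrame({
            "gene": ["x", "y", "z"],
            "score": [0.1, 0.9, 0.5],
            "p_value": [0.5, 0.5, 0.2],
            "rank": [2, 1, 3],
        })
        out = prioritize(df, alpha=1.0)
        assert list(out["gene"]) == ["z", "y", "x"]

    def test_empty_input_empty_output(self):
        import pandas as pd

        df = pd.DataFrame(columns=["gene", "score", "p_value", "rank"])
        assert len(prioritize(df, 0.005)) == 0

    def test_alpha_out_of_range(self):
        import pandas as pd

        with pytest.raises(ValueError):
            prioritize(pd.DataFrame(columns=["gene", "score", "p_value"]), 0.0)
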