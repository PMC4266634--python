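"""Seed-based gene prioritization on a weighted interaction network.

Scores every gene by propagating prior mass from a binary seed set over
a weighted undirected graph, using one of five kernels in the PINTA
lineage:

* ``random_walk_restart`` — s_{t+1} = (1-r) P^T s_t + r p0
* ``heat_kernel``         — s = exp(-t (I - P^T)) p0, truncated series
* ``pagerank_priors``     — the restart walk with damping d (r = 1-d)
* ``hits_priors``         — prior-blended hub/authority updates on the
  symmetrized graph; the authority vector is the score
* ``kstep_markov``        — s = sum_{k=1..K} (P^T)^k p0 / K

P is the row-stochastic transition matrix of the weighted graph, so
P^T applied to a distribution redistributes mass along edges; the
restart walk, PageRank-with-priors, the heat kernel and the averaged
K-step Markov all conserve total mass.  Statistical significance of a
gene's score is assessed by permuting the seed-mass assignment
uniformly over all nodes and recomputing scores (empirical p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

METHODS = (
    "random_walk_restart",
    "heat_kernel",
    "pagerank_priors",
    "hits_priors",
    "kstep_markov",
)

DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "random_walk_restart": {"restart": 0.3},
    "heat_kernel": {"t": 1.0, "terms": 30},
    "pagerank_priors": {"damping": 0.85},
    "hits_priors": {"blend": 0.3},
    "kstep_markov": {"k": 6},
}

_TOL = 1e-9
_MAX_ITER = 10_000


class NetworkError(ValueError):
    pass


class EmptySeedError(NetworkError):
    pass


class GeneNetwork:
    """Weighted undirected graph over gene symbols.

    Edge weights lie in [0, 1]; self-loops are dropped.  The transition
    operator is the row-stochastic normalization of the symmetric
    weight matrix; rows of isolated nodes are left zero and such nodes
    always score 0 with p-value 1.
    """

    def __init__(self, nodes: list[str], edges: list[tuple[str, str, float]]):
        self.nodes = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node names")
        self.index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        rows, cols, vals = [], [], []
        seen: dict[tuple[int, int], int] = {}
        for u, v, w in edges:
            if u == v:
                continue
            if not 0.0 <= w <= 1.0:
                raise NetworkError(f"edge weight {w} outside [0, 1]")
            i, j = self.index[u], self.index[v]
            key = (min(i, j), max(i, j))
            if key in seen:  # last write wins on duplicates
                vals[seen[key]] = w
                vals[seen[key] + 1] = w
                continue
            seen[key] = len(vals)
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        self.W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        degree = np.asarray(self.W.sum(axis=1)).ravel()
        self.isolated = degree == 0
        inv = np.zeros(n)
        inv[~self.isolated] = 1.0 / degree[~self.isolated]
        # row-stochastic P; transposed once since every kernel applies P^T
        self.PT = (sp.diags(inv) @ self.W).T.tocsr()

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_networkx(cls, graph) -> "GeneNetwork":
        edges = [
            (u, v, float(d.get("weight", 1.0))) for u, v, d in graph.edges(data=True)
        ]
        return cls(sorted(graph.nodes), edges)

    def edge_list(self) -> list[tuple[str, str, float]]:
        coo = sp.triu(self.W, k=1).tocoo()
        return [
            (self.nodes[i], self.nodes[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


def load_network(
    path,
    score_threshold: float = 0.0,
    largest_component: bool = True,
) -> GeneNetwork:
    """Load a STRING-dialect edge list (node, node, integer score 0-1000).

    Scores are divided by 1000 to weights; edges with score below
    ``score_threshold`` are dropped; by default only the largest
    connected component of the surviving graph is retained.
    """
    import networkx as nx

    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["u", "v", "score"], comment="#",
        dtype={"u": str, "v": str},
    )
    try:
        scores = pd.to_numeric(df["score"])
    except (ValueError, TypeError) as exc:
        raise NetworkError(f"non-numeric score in {path}: {exc}") from exc
    g = nx.Graph()
    for u, v, s in zip(df["u"], df["v"], scores):
        if s >= score_threshold:
            g.add_edge(u, v, weight=float(s) / 1000.0)
    if largest_component and g.number_of_nodes() > 0:
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
    return GeneNetwork.from_networkx(g)


def write_edge_list(network: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for u, v, w in network.edge_list():
            fh.write(f"{u}\t{v}\t{int(round(w * 1000))}\n")


@dataclass
class SeedVector:
    """Per-node prior mass: binary seed membership normalized to sum 1.

    Optional per-gene weights (e.g. curated evidence scores) are
    blended in before normalization; unweighted seeds share mass
    uniformly.
    """

    network: GeneNetwork
    seeds: list[str]
    weights: dict[str, float] | None = None
    vector: np.ndarray = field(init=False)

    def __post_init__(self):
        support = [g for g in self.seeds if g in self.network.index]
        if not support:
            raise EmptySeedError("no seed gene is present in the network")
        v = np.zeros(len(self.network))
        for g in support:
            w = 1.0 if self.weights is None else float(self.weights.get(g, 1.0))
            if w < 0:
                raise NetworkError(f"negative seed weight for {g}")
            v[self.network.index[g]] = w
        total = v.sum()
        if total <= 0:
            raise EmptySeedError("seed weights sum to zero")
        self.vector = v / total
        self.support = support


@dataclass(frozen=True)
class PropagationResult:
    scores: np.ndarray
    converged: bool
    n_iter: int
    method: str

    def as_series(self, network: GeneNetwork) -> pd.Series:
        return pd.Series(self.scores, index=network.nodes, name="score")


def _iterate(update, s0: np.ndarray) -> tuple[np.ndarray, bool, int]:
    s = s0
    for it in range(1, _MAX_ITER + 1):
        s_next = update(s)
        if np.abs(s_next - s).sum() < _TOL:
            return s_next, True, it
        s = s_next
    return s, False, _MAX_ITER


def _propagate_vector(
    network: GeneNetwork, p0: np.ndarray, method: str, params: dict
) -> PropagationResult:
    PT = network.PT
    if method == "random_walk_restart" or method == "pagerank_priors":
        if method == "pagerank_priors":
            r = 1.0 - float(params["damping"])
        else:
            r = float(params["restart"])
        if not 0.0 < r <= 1.0:
            raise NetworkError("restart probability must lie in (0, 1]")
        if r == 1.0:
            return PropagationResult(p0.copy(), True, 0, method)
        s, conv, it = _iterate(lambda s: (1.0 - r) * (PT @ s) + r * p0, p0)
        return PropagationResult(s, conv, it, method)
    if method == "heat_kernel":
        t = float(params["t"])
        terms = int(params["terms"])
        if t < 0 or terms < 1:
            raise NetworkError("heat kernel needs t >= 0 and terms >= 1")
        # exp(-t(I - P^T)) p0 = e^{-t} sum_k t^k/k! (P^T)^k p0
        s = np.zeros_like(p0)
        term = p0.copy()
        coeff = math.exp(-t)
        s += coeff * term
        for k in range(1, terms):
            term = PT @ term
            coeff *= t / k
            s += coeff * term
        return PropagationResult(s, True, terms, method)
    if method == "kstep_markov":
        k = int(params["k"])
        if k < 1:
            raise NetworkError("kstep_markov needs k >= 1")
        s = np.zeros_like(p0)
        term = p0.copy()
        for _ in range(k):
            term = PT @ term
            s += term
        return PropagationResult(s / k, True, k, method)
    if method == "hits_priors":
        beta = float(params["blend"])
        if not 0.0 <= beta <= 1.0:
            raise NetworkError("hits blend must lie in [0, 1]")
        W = network.W

        def norm(x: np.ndarray) -> np.ndarray:
            t = x.sum()
            return x / t if t > 0 else x

        a = p0.copy()
        h = p0.copy()
        for it in range(1, _MAX_ITER + 1):
            a_next = (1.0 - beta) * norm(W.T @ h) + beta * p0
            h_next = (1.0 - beta) * norm(W @ a_next) + beta * p0
            delta = np.abs(a_next - a).sum() + np.abs(h_next - h).sum()
            a, h = a_next, h_next
            if delta < _TOL:
                return PropagationResult(a, True, it, method)
        return PropagationResult(a, False, _MAX_ITER, method)
    raise NetworkError(f"unknown method {method!r}; choose from {METHODS}")


def propagate(
    network: GeneNetwork,
    seeds: SeedVector | list[str],
    method: str = "random_walk_restart",
    params: dict | None = None,
) -> PropagationResult:
    """Propagate seed mass over the network with the chosen kernel.

    Returns nonnegative per-node scores aligned with ``network.nodes``;
    mass-conserving kernels sum to 1 within 1e-9.  Non-convergence
    within 10,000 iterations is flagged on the result, never silent.
    """
    if not isinstance(seeds, SeedVector):
        seeds = SeedVector(network, list(seeds))
    if method not in METHODS:
        raise NetworkError(f"unknown method {method!r}; choose from {METHODS}")
    full = dict(DEFAULT_PARAMS[method])
    full.update(params or {})
    res = _propagate_vector(network, seeds.vector, method, full)
    scores = res.scores.copy()
    scores[network.isolated & (seeds.vector == 0)] = 0.0
    return PropagationResult(scores, res.converged, res.n_iter, method)


def permutation_pvalues(
    network: GeneNetwork,
    seeds: SeedVector | list[str],
    method: str = "random_walk_restart",
    params: dict | None = None,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    add_one_correction: bool = False,
) -> pd.DataFrame:
    """Empirical permutation p-values for all non-seed genes.

    Each permutation reassigns the seed-mass entries uniformly at
    random over all nodes and reruns the propagation; for gene g,
    p = #(permuted score_g >= observed score_g) / n_perm, so ties count
    against significance and p may be exactly 0.  With
    ``add_one_correction`` the (k+1)/(n+1) estimator is used instead.
    Deterministic under ``rng_seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(seeds, SeedVector):
        seeds = SeedVector(network, list(seeds))
    full = dict(DEFAULT_PARAMS[method])
    full.update(params or {})
    observed = propagate(network, seeds, method, full).scores
    rng = np.random.default_rng(rng_seed)
    n = len(network)
    exceed = np.zeros(n, dtype=np.int64)
    for _ in range(n_perm):
        p0 = seeds.vector[rng.permutation(n)]
        perm_scores = _propagate_vector(network, p0, method, full).scores
        # ties at numerical precision count against significance
        exceed += perm_scores >= observed - 1e-12
    if add_one_correction:
        pvals = (exceed + 1) / (n_perm + 1)
    else:
        pvals = exceed / n_perm
    pvals = np.where(network.isolated, 1.0, pvals)
    seed_idx = {network.index[g] for g in seeds.support}
    rows = [
        (g, float(observed[i]), float(pvals[i]))
        for i, g in enumerate(network.nodes)
        if i not in seed_idx
    ]
    df = pd.DataFrame(rows, columns=["gene", "score", "p_value"])
    df = df.sort_values(
        ["p_value", "score", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def prioritize(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Genes with p < alpha, sorted by (p, -score)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    out = results[results["p_value"] < alpha]
    return out.sort_values(
        ["p_value", "score"], ascending=[True, False]
    ).reset_index(drop=True)
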