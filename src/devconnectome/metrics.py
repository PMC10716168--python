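"""Weighted graph metrics for structural connectomes.

Edge length is the reciprocal of edge weight, so strong connections are
short.  Global and nodal efficiency are harmonic means of inverse shortest
path lengths; clustering follows the Onnela geometric-mean form with weights
scaled by the network-wide maximum; betweenness uses shortest-path
multiplicities with 1/((n-1)(n-2)) normalization.  Small-world ratios are
computed against degree-sequence-preserving rewired null networks carrying a
random permutation of the observed weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import Connectome

logger = logging.getLogger(__name__)


@dataclass
class GlobalMetrics:
    e_glob: float
    e_loc: float
    l_p: float
    s_p: float
    c_p: float
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None

    def to_dict(self) -> dict:
        return {
            "e_glob": self.e_glob,
            "e_loc": self.e_loc,
            "l_p": self.l_p,
            "s_p": self.s_p,
            "c_p": self.c_p,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
        }


@dataclass
class NodalMetrics:
    n_eglob: np.ndarray
    n_eloc: np.ndarray
    degree_strength: np.ndarray
    betweenness: np.ndarray

    def by_name(self, name: str) -> np.ndarray:
        return {
            "nodal_efficiency": self.n_eglob,
            "nodal_local_efficiency": self.n_eloc,
            "degree_strength": self.degree_strength,
            "betweenness": self.betweenness,
        }[name]


def _weights(conn) -> np.ndarray:
    return conn.weights if isinstance(conn, Connectome) else np.asarray(conn, float)


def shortest_paths(conn) -> np.ndarray:
    """All-pairs shortest path lengths over edge lengths 1/w (inf if disconnected)."""
    w = _weights(conn)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(conn) -> float:
    w = _weights(conn)
    if w.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 regions")
    return _efficiency_from_distances(shortest_paths(w))


def nodal_efficiency(conn) -> np.ndarray:
    """Per-node mean inverse shortest-path distance to every other node."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 regions")
    d = shortest_paths(w)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_local_efficiency(conn) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph (node removed)."""
    w = _weights(conn)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_distances(shortest_paths(sub))
    return out


def local_efficiency(conn) -> float:
    return float(nodal_local_efficiency(conn).mean())


def characteristic_path_length(conn) -> float:
    """Mean shortest path length over connected ordered pairs.

    If any pair is disconnected the mean is restricted to finite pairs and a
    warning is logged.
    """
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 regions")
    d = shortest_paths(w)
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no connected node pair")
    if not finite.all():
        logger.warning(
            "network disconnected: path length restricted to %d of %d pairs",
            int(finite.sum()),
            vals.size,
        )
    return float(vals[finite].mean())


def degree_strength(conn) -> np.ndarray:
    return _weights(conn).sum(axis=1)


def network_strength(conn) -> float:
    return float(degree_strength(conn).mean())


def clustering_coefficient(conn) -> tuple[float, np.ndarray]:
    """Onnela weighted clustering, weights scaled by the network maximum.

    Nodes with binary degree <= 1 (isolated or single connection) get 0.
    Returns (network mean, per-node vector).
    """
    w = _weights(conn)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    cbrt = np.cbrt(w / wmax)
    tri = np.einsum("ij,jl,li->i", cbrt, cbrt, cbrt)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    ci = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(ci.mean()), ci


def betweenness_centrality(conn) -> np.ndarray:
    """Weighted shortest-path betweenness, normalized by (n-1)(n-2).

    Credit is split across tied shortest paths via path multiplicities.
    """
    w = _weights(conn)
    n = w.shape[0]
    if n < 3:
        raise ValueError("betweenness needs at least 3 regions")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, 1)
    mask = w[iu, ju] > 0
    G.add_weighted_edges_from(
        zip(iu[mask].tolist(), ju[mask].tolist(), (1.0 / w[iu, ju][mask]).tolist()),
        weight="length",
    )
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


def random_ensemble(conn, n: int = 5000, seed: int | None = None) -> list:
    """Matched random networks: degree-preserving topology rewiring plus
    weight permutation.

    Each surrogate rewires the binary topology with 10x|E| attempted
    double-edge swaps (preserving the exact degree sequence) and then places
    a random permutation of the observed weight multiset on the rewired
    edges.  Weight-degree coupling is deliberately not preserved.
    """
    conn = conn if isinstance(conn, Connectome) else Connectome(np.asarray(conn, float))
    w = conn.weights
    iu, ju = conn.edge_index()
    n_edges = len(iu)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    weights_pool = w[iu, ju]
    rng = np.random.default_rng(seed)
    G0 = nx.Graph()
    G0.add_nodes_from(range(conn.n_regions))
    G0.add_edges_from(zip(iu.tolist(), ju.tolist()))
    out = []
    for _ in range(n):
        G = G0.copy()
        nswap = 10 * n_edges
        try:
            nx.double_edge_swap(
                G, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # swap budget exhausted; keep partially rewired topology
        perm = rng.permutation(weights_pool)
        wr = np.zeros_like(w)
        for (a, b), wt in zip(G.edges(), perm):
            wr[a, b] = wt
            wr[b, a] = wt
        out.append(Connectome(weights=wr))
    return out


def small_worldness(conn, ensemble) -> tuple[float, float, float]:
    """gamma, lambda, sigma against a null ensemble (means of C_p and L_p)."""
    c_real, _ = clustering_coefficient(conn)
    l_real = characteristic_path_length(conn)
    c_rand = float(np.mean([clustering_coefficient(g)[0] for g in ensemble]))
    l_rand = float(np.mean([characteristic_path_length(g) for g in ensemble]))
    if c_rand == 0 or l_rand == 0:
        raise ValueError("degenerate null ensemble (zero mean metric)")
    gamma = c_real / c_rand
    lam = l_real / l_rand
    return gamma, lam, gamma / lam


def global_metrics(conn, ensemble=None) -> GlobalMetrics:
    c_p, _ = clustering_coefficient(conn)
    gm = GlobalMetrics(
        e_glob=global_efficiency(conn),
        e_loc=local_efficiency(conn),
        l_p=characteristic_path_length(conn),
        s_p=network_strength(conn),
        c_p=c_p,
    )
    if ensemble is not None:
        gm.gamma, gm.lambda_, gm.sigma = small_worldness(conn, ensemble)
    return gm


def nodal_metrics(conn) -> NodalMetrics:
    return NodalMetrics(
        n_eglob=nodal_efficiency(conn),
        n_eloc=nodal_local_efficiency(conn),
        degree_strength=degree_strength(conn),
        betweenness=betweenness_centrality(conn),
    )
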