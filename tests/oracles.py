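"""Independent brute-force graph-metric implementations used as oracles.

Everything here enumerates paths exhaustively (no Dijkstra, no networkx) so
it stays independent of the implementation under test.  Only viable for
tiny graphs (R <= ~8).
"""

import itertools

import numpy as np

TIE_TOL = 1e-12


def all_simple_paths_lengths(W, s, t):
    """Lengths (sum of 1/w) of every simple path s -> t."""
    n = W.shape[0]
    out = []

    def rec(node, visited, acc):
        if node == t:
            out.append(acc)
            return
        for nxt in range(n):
            if W[node, nxt] > 0 and nxt not in visited:
                rec(nxt, visited | {nxt}, acc + 1.0 / W[node, nxt])

    rec(s, {s}, 0.0)
    return out


def brute_distance_matrix(W):
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            lengths = all_simple_paths_lengths(W, s, t)
            if lengths:
                D[s, t] = min(lengths)
    return D


def brute_global_efficiency(W):
    D = brute_distance_matrix(W)
    n = W.shape[0]
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                tot += 1.0 / D[i, j]
    return tot / (n * (n - 1))


def brute_nodal_efficiency(W):
    D = brute_distance_matrix(W)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i and np.isfinite(D[i, j]) and D[i, j] > 0:
                out[i] += 1.0 / D[i, j]
    return out / (n - 1)


def brute_path_length(W):
    D = brute_distance_matrix(W)
    n = W.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals))


def brute_local_efficiency_vector(W):
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = brute_global_efficiency(sub)
    return out


def brute_clustering(W):
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    Wb = W / wmax
    out = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        tot = 0.0
        for j in range(n):
            for l in range(n):
                if j != i and l != i and j != l:
                    tot += (Wb[i, j] * Wb[j, l] * Wb[l, i]) ** (1.0 / 3.0)
        out[i] = tot / (k * (k - 1))
    return out


def brute_betweenness(W):
    """Eq-13-style betweenness by enumerating all shortest paths."""
    n = W.shape[0]
    counts = np.zeros(n)
    for j, k in itertools.permutations(range(n), 2):
        paths = _all_shortest_paths(W, j, k)
        if not paths:
            continue
        for i in range(n):
            if i == j or i == k:
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            counts[i] += through / len(paths)
    return counts / ((n - 1) * (n - 2))


def _all_shortest_paths(W, s, t):
    n = W.shape[0]
    best = [np.inf]
    paths = []

    def rec(node, visited, acc, path):
        if acc > best[0] + TIE_TOL:
            return
        if node == t:
            if acc < best[0] - TIE_TOL:
                best[0] = acc
                paths.clear()
            paths.append(list(path))
            return
        for nxt in range(n):
            if W[node, nxt] > 0 and nxt not in visited:
                rec(nxt, visited | {nxt}, acc + 1.0 / W[node, nxt], path + [nxt])

    rec(s, {s}, 0.0, [s])
    return [p for p in paths if abs(sum(1.0 / W[a, b] for a, b in zip(p, p[1:])) - best[0]) <= TIE_TOL]


def random_connected_weighted_graph(rng, n_max=7):
    """Random connected weighted graph for the oracle battery."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        p = rng.uniform(0.35, 0.9)
        A = rng.random((n, n)) < p
        A = np.triu(A, 1)
        W = np.where(A, rng.uniform(0.2, 3.0, (n, n)), 0.0)
        W = W + W.T
        # connectivity via reachability
        reach = (W > 0).astype(float) + np.eye(n)
        reach = np.linalg.matrix_power(reach, n) > 0
        if reach.all():
            return W
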