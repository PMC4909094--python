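"""Independent brute-force oracles used to validate the analytic routines.

These deliberately avoid the implementation's code paths: the walker oracle
builds the full Markov chain over directed-edge states and multiplies chain
entries along the node sequence; the matching oracle enumerates neighbours
with explicit loops; shortest paths are found by exhaustive simple-path
enumeration; the analytic-FC oracle goes through an eigendecomposition.
"""

import itertools

import numpy as np


def walker_chain_states(W, no_return=True):
    """Transition probabilities of the walker as an explicit state chain.

    States are ('start', i) and directed edges (i, j). Returns a dict
    {(state, next_state): probability}.
    """
    n = W.shape[0]
    T = {}
    starts = [("start", i) for i in range(n)]
    edges = [(i, j) for i in range(n) for j in range(n) if W[i, j] > 0]
    for a, b in starts + edges:
        allowed = [k for k in range(n) if W[b, k] > 0]
        if no_return and a != "start":
            allowed = [k for k in allowed if k != a]
        tot = sum(W[b, k] for k in allowed)
        for k in allowed:
            T[((a, b), (b, k))] = W[b, k] / tot
    return T


def walker_path_probability(W, path, no_return=True):
    """Probability that the walker emits exactly this node sequence."""
    T = walker_chain_states(W, no_return=no_return)
    state = ("start", path[0])
    p = 1.0
    for u, v in zip(path[:-1], path[1:]):
        nxt = (u, v)
        p *= T[(state, nxt)]
        state = nxt
    return p


def matching_index_oracle(W, u, v):
    """Shared-neighbour weight fraction, explicit loops, direct edge excluded."""
    n = W.shape[0]
    num = 0.0
    den = 0.0
    for k in range(n):
        if k == u or k == v:
            continue
        if W[u, k] > 0 and W[v, k] > 0:
            num += W[u, k] + W[v, k]
        if W[u, k] > 0:
            den += W[u, k]
        if W[v, k] > 0:
            den += W[v, k]
    return num / den if den > 0 else 0.0


def path_transitivity_oracle(W, path):
    """Mean matching index over node pairs of the path."""
    vals = [matching_index_oracle(W, a, b)
            for a, b in itertools.combinations(path, 2)]
    return float(np.mean(vals)) if vals else 0.0


def shortest_path_oracle(W, s, t):
    """Exhaustive simple-path search: (min length, lexicographically
    smallest minimal node sequence); lengths are summed inverse weights."""
    n = W.shape[0]
    best_len = np.inf
    best_path = None
    stack = [([s], 0.0)]
    while stack:
        path, length = stack.pop()
        u = path[-1]
        if u == t:
            if length < best_len - 1e-12 or (
                    abs(length - best_len) <= 1e-12 and tuple(path) < tuple(best_path)):
                best_len, best_path = length, list(path)
            continue
        if length >= best_len + 1e-12:
            continue
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                stack.append((path + [v], length + 1.0 / W[u, v]))
    return best_len, best_path


def fca_oracle(W_normalised, c):
    """Correlation of (I - cW)^-1 via eigendecomposition, not inversion."""
    lam, V = np.linalg.eigh(W_normalised)
    cov = (V * (1.0 / (1.0 - c * lam))) @ V.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def random_connected_graph(rng, n_min=3, n_max=8):
    """Random connected weighted graph with positive continuous weights."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = rng.uniform(0.3, 0.9)
        A = np.triu(rng.random((n, n)) < p, 1)
        W = np.where(A, rng.uniform(0.5, 5.0, (n, n)), 0.0)
        W = W + W.T
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if W[u, v] > 0 and v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if len(seen) == n:
            return W
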