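"""Independent brute-force oracles used to validate the fast implementations.

Each function here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mrd_double_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Modified Rogers distance via the explicit two-allele double sum."""
    total = 0.0
    L = len(x)
    for l in range(L):
        for pa, pb in [(x[l], y[l]), (1 - x[l], 1 - y[l])]:
            total += (pa - pb) ** 2
    return math.sqrt(total / (2 * L))


def expected_het_loop(p: np.ndarray) -> float:
    """Mean 2p(1-p) by explicit loop."""
    return sum(2 * v * (1 - v) for v in p) / len(p)


def simplex_grid_search(f: np.ndarray, G: np.ndarray, resolution: float = 1e-3,
                        ridge: float = 0.0) -> np.ndarray:
    """Exhaustive search of the probability simplex at a fixed resolution.

    Only practical for K <= 3.
    """
    K = G.shape[0]
    steps = int(round(1.0 / resolution))
    best, best_val = None, np.inf
    if K == 1:
        return np.array([1.0])
    if K == 2:
        for i in range(steps + 1):
            a = np.array([i / steps, 1 - i / steps])
            val = np.sum((f - a @ G) ** 2) + ridge * np.sum(a**2)
            if val < best_val:
                best, best_val = a, val
        return best
    if K == 3:
        for i in range(steps + 1):
            for j in range(steps + 1 - i):
                a = np.array([i / steps, j / steps, 1 - (i + j) / steps])
                val = np.sum((f - a @ G) ** 2) + ridge * np.sum(a**2)
                if val < best_val:
                    best, best_val = a, val
        return best
    raise NotImplementedError("grid search only for K <= 3")


def ward_brute_force(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Ward agglomeration by exhaustive pair evaluation (ward.D2 convention).

    Maintains squared inter-cluster distances through the Lance–Williams
    update and always merges the globally closest pair. Returns the merge
    sequence as (cluster_a, cluster_b, height) with heights on the
    distance (not squared) scale.
    """
    n = d.shape[0]
    clusters: dict[frozenset, None] = {frozenset([i]): None for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[frozenset([frozenset([i]), frozenset([j])])] = d[i, j] ** 2
    merges = []
    while len(clusters) > 1:
        pair = min(d2, key=lambda k: d2[k])
        height = math.sqrt(d2[pair])
        a, b = sorted(pair, key=lambda c: sorted(c))
        merged = a | b
        merges.append((a, b, height))
        na, nb = len(a), len(b)
        for c in list(clusters):
            if c in (a, b):
                continue
            nc = len(c)
            dac = d2[frozenset([a, c])]
            dbc = d2[frozenset([b, c])]
            dab = d2[pair]
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / (na + nb + nc)
            d2[frozenset([merged, c])] = new
        for key in [k for k in d2 if a in k or b in k]:
            del d2[key]
        del clusters[a]
        del clusters[b]
        clusters[merged] = None
    return merges


def random_additive_matrix(n_leaves: int, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Distance matrix of a random binary tree with positive branch lengths.

    Built by sequentially attaching leaves to random edges of a growing
    tree and summing path lengths over the explicit edge graph.
    """
    # edges: dict (u, v) -> length on a graph with integer node ids
    labels = [f"T{i}" for i in range(n_leaves)]
    edges: dict[tuple[int, int], float] = {}
    next_node = n_leaves

    def add_edge(u: int, v: int, w: float) -> None:
        edges[(min(u, v), max(u, v))] = w

    def blen() -> float:
        return float(rng.uniform(0.1, 0.3))

    add_edge(0, 1, blen())
    for leaf in range(2, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        w = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.3, 0.7)) * w
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(mid, leaf, blen())

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dists_from(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dists_from(i)
        for j in range(n_leaves):
            d[i, j] = di[j]
    np.fill_diagonal(d, 0.0)
    return d, labels


def best_quartet_tree(d: np.ndarray) -> tuple[tuple[tuple[int, int], tuple[int, int]], dict]:
    """Exhaustive least-squares fit over the 3 unrooted 4-leaf topologies.

    Returns the best split ((a,b),(c,d)) and its five fitted edge
    lengths keyed by leaf index plus 'internal'.
    """
    assert d.shape == (4, 4)
    best = None
    for (a, b), (c, e) in [(((0, 1)), ((2, 3))), (((0, 2)), ((1, 3))), (((0, 3)), ((1, 2)))]:
        # design matrix over 6 pairwise distances, unknowns: la, lb, lc, le, internal
        pairs = list(itertools.combinations(range(4), 2))
        leaf_cols = {a: 0, b: 1, c: 2, e: 3}
        A = np.zeros((6, 5))
        y = np.zeros(6)
        for r, (i, j) in enumerate(pairs):
            A[r, leaf_cols[i]] = 1
            A[r, leaf_cols[j]] = 1
            same_side = {i, j} in ({a, b}, {c, e})
            if not same_side:
                A[r, 4] = 1
            y[r] = d[i, j]
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        if best is None or rss < best[0]:
            lengths = {a: coef[0], b: coef[1], c: coef[2], e: coef[3], "internal": coef[4]}
            best = (rss, ((a, b), (c, e)), lengths)
    return best[1], best[2]
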