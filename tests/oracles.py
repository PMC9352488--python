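"""Independent brute-force oracles used to validate the implementations.

Each oracle is written from the definition of the quantity, not from the
code path it checks: hypergeometric enumeration for the Fisher test,
concordant-pair counting for AUC, full rank-assignment enumeration for the
rank-sum test, dense all-pairs shortest paths for BFS distances, and
minimum-degree peeling on a plain adjacency dict for the MCODE vertex
weight.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs * (1 + rel_tol):
            total += px
    return min(total, 1.0)


def auc_pair_counting(values, labels, positive) -> float:
    """Oriented AUC by counting concordant pairs (half credit for ties)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    raw = wins / (len(pos) * len(neg))
    return max(raw, 1.0 - raw)


def rank_sum_exact(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every rank assignment.

    Assumes no ties.  Uses the symmetry of the U distribution under H0:
    p = P(|U - nm/2| >= |U_obs - nm/2|).
    """
    x = list(x)
    y = list(y)
    nx_, ny_ = len(x), len(y)
    combined = sorted(x + y)
    ranks_of_x = [combined.index(v) + 1 for v in x]
    u_obs = sum(ranks_of_x) - nx_ * (nx_ + 1) / 2
    center = nx_ * ny_ / 2
    dev = abs(u_obs - center)
    all_ranks = range(1, nx_ + ny_ + 1)
    count = 0
    total = 0
    for subset in itertools.combinations(all_ranks, nx_):
        u = sum(subset) - nx_ * (nx_ + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def all_pairs_hops(G) -> dict:
    """Hop distances for every node pair by dense Floyd-Warshall."""
    nodes = sorted(G.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in G.edges:
        dist[idx[a], idx[b]] = 1.0
        dist[idx[b], idx[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return {u: {v: dist[idx[u], idx[v]] for v in nodes} for u in nodes}


def highest_core_weight(G, v) -> float:
    """MCODE vertex weight by minimum-degree peeling on an adjacency dict."""
    nbrs = set(G[v])
    if not nbrs:
        return 0.0
    nodes = nbrs | {v}
    adj = {u: set(G[u]) & nodes for u in nodes}

    best_k, best_nodes = 0, set()
    k = 1
    while True:
        cur = {u: set(a) for u, a in adj.items()}
        while True:
            low = [u for u, a in cur.items() if len(a) < k]
            if not low:
                break
            for u in low:
                for w in cur[u]:
                    cur[w].discard(u)
                del cur[u]
        if not cur:
            break
        best_k, best_nodes = k, set(cur)
        k += 1

    if best_k == 0 or len(best_nodes) < 2:
        return 0.0
    edges = sum(len(set(G[u]) & best_nodes) for u in best_nodes) / 2
    n = len(best_nodes)
    density = 2.0 * edges / (n * (n - 1))
    return best_k * density


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = math.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj
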