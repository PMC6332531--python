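"""Independent brute-force implementations used as ground truth in tests.

Everything here is written as plainly as possible — explicit loops over
node pairs, set intersections, exact fractions — and deliberately shares no
code with the package internals it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def tom_brute(nodes, edges):
    """Naive double-loop topological overlap: dict[(u,v)] -> float."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for i in nodes:
        for j in nodes:
            if i == j:
                out[(i, j)] = 1.0
                continue
            a_ij = 1 if j in adj[i] else 0
            shared = sum(1 for u in nodes if u not in (i, j) and u in adj[i] and u in adj[j])
            den = min(len(adj[i]), len(adj[j])) + 1 - a_ij
            out[(i, j)] = (shared + a_ij) / den
    return out


def ltom_brute(nodes, edges, loc):
    """Naive location-gated topological overlap; loc: dict[node] -> set."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for i in nodes:
        for j in nodes:
            if i == j:
                out[(i, j)] = 1.0
                continue
            a_ij = 1 if j in adj[i] else 0
            num = sum(
                1
                for u in nodes
                if u not in (i, j)
                and u in adj[i]
                and u in adj[j]
                and loc.get(i, set()) & loc.get(u, set()) & loc.get(j, set())
            )
            if a_ij and loc.get(i, set()) & loc.get(j, set()):
                num += 1
            den = min(len(adj[i]), len(adj[j])) + 1 - a_ij
            out[(i, j)] = num / den
    return out


def sn_ppv_acc_brute(predicted, reference):
    """Nested-loop clustering-wise sensitivity / PPV / accuracy."""
    predicted = [set(p) for p in predicted]
    reference = [set(c) for c in reference]
    t = [[len(p & c) for c in reference] for p in predicted]
    sn_num = sum(max(t[i][j] for i in range(len(predicted))) for j in range(len(reference)))
    sn_den = sum(len(c) for c in reference)
    ppv_num = sum(max(row) for row in t)
    ppv_den = sum(sum(row) for row in t)
    sn = sn_num / sn_den
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def hypergeom_upper_tail_exact(t, n, T, N):
    """P(X >= t) as an exact fraction via binomial-coefficient summation."""
    total = Fraction(0)
    for i in range(t, min(n, T) + 1):
        if n - i > N - T:
            continue
        total += Fraction(math.comb(T, i) * math.comb(N - T, n - i), math.comb(N, n))
    return total


def hypergeom_upper_tail_enumerated(t, n, T, N):
    """P(X >= t) by enumerating all C(N, n) draws — tiny N only."""
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < T) >= t:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted


def mcl_reference(adj, inflation=2.0, n_iter=200):
    """Plain MCL loop on a dense adjacency; returns frozenset clusters."""
    n = adj.shape[0]
    m = adj.astype(float) + np.eye(n)
    m = m / m.sum(axis=0)
    for _ in range(n_iter):
        m = np.linalg.matrix_power(m, 2)
        m = m ** inflation
        m = m / m.sum(axis=0)
    support = (m > 1e-6) | (m.T > 1e-6)
    clusters = []
    unseen = set(range(n))
    while unseen:
        stack = [unseen.pop()]
        comp = set(stack)
        while stack:
            x = stack.pop()
            for y in range(n):
                if y in unseen and support[x, y]:
                    unseen.remove(y)
                    comp.add(y)
                    stack.append(y)
        clusters.append(frozenset(comp))
    return {c for c in clusters if len(c) >= 2}


def avg_path_length_brute(nodes, edges):
    """Floyd-Warshall mean distance over connected ordered pairs."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    dists = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < inf]
    return sum(dists) / len(dists)


def avg_clustering_brute(nodes, edges):
    """Triple-counting local clustering coefficient averaged over all nodes."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    total = 0.0
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        total += 2.0 * links / (k * (k - 1))
    return total / len(nodes)
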