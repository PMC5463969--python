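"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity from first principles —
enumeration, textbook formulas, exact rational arithmetic — without
touching the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Hand-applied Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        value = p[idx] * n / rank_from_top
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def hypergeom_upper_tail(k: int, big_n: int, term: int, draws: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(big_n, term, draws), exact."""
    total = Fraction(0)
    denom = math.comb(big_n, draws)
    for kk in range(k, min(term, draws) + 1):
        total += Fraction(math.comb(term, kk) * math.comb(big_n - term, draws - kk), denom)
    return total


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), direct summation."""
    return float(sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)))


def paired_t(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Textbook paired t statistic and two-sided P (t distribution)."""
    from scipy import stats

    d = np.asarray(tumor, float) - np.asarray(normal, float)
    n = len(d)
    se = d.std(ddof=1) / math.sqrt(n)
    t = d.mean() / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return t, p


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r from raw covariance arithmetic; P from the t transform."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p


def graph_centralities(nodes: list, edges: list) -> dict:
    """Degree, betweenness, closeness by explicit all-pairs BFS counting.

    Betweenness sums, per node v, sigma_st(v)/sigma_st over unordered
    pairs {s, t} with s != t != v, in exact rational arithmetic.
    Closeness is (n_c - 1)/sum-of-distances within v's component,
    0 for isolated nodes.
    """
    adj = {u: set() for u in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in d:
                        d[w] = d[u] + 1
                        sig[w] = 0
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sig[w] += sig[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = sig

    def sigma_through(s, t, v):
        if v not in dist[s] or t not in dist[s]:
            return 0
        if dist[s][v] + dist[v][t] != dist[s][t]:
            return 0
        return sigma[s][v] * sigma[v][t]

    betweenness = {}
    closeness = {}
    degree = {u: len(adj[u]) for u in nodes}
    node_list = sorted(nodes)
    for v in node_list:
        total = Fraction(0)
        for i, s in enumerate(node_list):
            if s == v:
                continue
            for t in node_list[i + 1:]:
                if t == v or s == v:
                    continue
                if t not in dist[s]:
                    continue
                st = sigma_through(s, t, v)
                if st:
                    total += Fraction(st, sigma[s][t])
        betweenness[v] = total
        reachable = dist[v]
        n_c = len(reachable)
        if n_c <= 1:
            closeness[v] = Fraction(0)
        else:
            closeness[v] = Fraction(n_c - 1, sum(reachable.values()))
    return {"degree": degree, "betweenness": betweenness, "closeness": closeness}
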