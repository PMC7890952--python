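"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (enumeration, direct
formulas, BFS path counting) and deliberately shares no code with the
package implementations it checks.
"""

from __future__ import annotations

import math
from collections import deque
from fractions import Fraction

import numpy as np
from scipy.stats import norm


def bf_ms(t: int, T1: int, T2: int, Q: int) -> float:
    """1 - partial sum of exact hypergeometric pmf terms (rational arithmetic)."""
    denom = math.comb(Q, T2)
    acc = Fraction(0)
    for i in range(t):
        acc += Fraction(math.comb(T1, i) * math.comb(Q - T1, T2 - i), denom)
    return float(1 - acc)


def bf_pcc(x, y) -> float:
    """Textbook two-pass Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n)) / n
    vx = sum((x[i] - mx) ** 2 for i in range(n)) / n
    vy = sum((y[i] - my) ** 2 for i in range(n)) / n
    return cov / math.sqrt(vx * vy)


def bf_mi(labels_x, labels_y) -> float:
    """Plug-in MI by explicit loops over observed label values (nats)."""
    n = len(labels_x)
    xs, ys = sorted(set(labels_x)), sorted(set(labels_y))
    total = 0.0
    for a in xs:
        px = sum(1 for v in labels_x if v == a) / n
        for b in ys:
            pxy = sum(
                1 for i in range(n) if labels_x[i] == a and labels_y[i] == b
            ) / n
            if pxy > 0:
                py = sum(1 for v in labels_y if v == b) / n
                total += pxy * math.log(pxy / (px * py))
    return total


def bf_cmi(labels_x, labels_y, labels_z) -> float:
    """Plug-in conditional MI by an explicit triple sum (nats)."""
    n = len(labels_x)
    triples = list(zip(labels_x, labels_y, labels_z))
    total = 0.0
    for a in sorted(set(labels_x)):
        for b in sorted(set(labels_y)):
            for c in sorted(set(labels_z)):
                pabc = triples.count((a, b, c)) / n
                if pabc == 0:
                    continue
                pc = sum(1 for v in labels_z if v == c) / n
                pac = sum(
                    1 for i in range(n)
                    if labels_x[i] == a and labels_z[i] == c
                ) / n
                pbc = sum(
                    1 for i in range(n)
                    if labels_y[i] == b and labels_z[i] == c
                ) / n
                total += pabc * math.log(pc * pabc / (pac * pbc))
    return total


def bf_vdw(v) -> list[float]:
    """Van der Waerden scores via explicit average ranks."""
    n = len(v)
    scores = []
    for i in range(n):
        less = sum(1 for w in v if w < v[i])
        equal = sum(1 for w in v if w == v[i])
        avg_rank = less + (equal + 1) / 2
        scores.append(float(norm.ppf(avg_rank / (n + 1))))
    return scores


def bf_la(x, y, m) -> float:
    """Direct evaluation of the liquid-association average."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - my) ** 2 for v in y) / (n - 1))
    scores = bf_vdw(m)
    return sum(
        ((x[i] - mx) / sx) * ((y[i] - my) / sy) * scores[i] for i in range(n)
    ) / n


# ---------------------------------------------------------------------------
# graph oracles: explicit all-pairs BFS shortest-path enumeration


def _all_shortest_paths(adj, s, t):
    """Every shortest s-t path, via BFS distances + DFS backtracking."""
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t not in dist:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(list(path))
            return
        for v in adj[node]:
            if dist.get(v) == dist[node] + 1 and dist[v] <= dist[t]:
                path.append(v)
                walk(v, path)
                path.pop()

    walk(s, [s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def bf_topology(nodes, edges):
    """degree / betweenness / closeness / clustering / edge betweenness.

    Conventions match the package: betweenness counts unordered pairs with
    endpoints excluded; closeness is within-component (n_reachable-1)/dist;
    clustering of degree-<2 nodes is 0; edge betweenness counts unordered
    pairs whose shortest paths use the edge (endpoints included).
    """
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    degree = {n: len(adj[n]) for n in nodes}
    betweenness = {n: 0.0 for n in nodes}
    edge_bet = {tuple(sorted(e)): 0.0 for e in edges}
    closeness = {}
    clustering = {}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    betweenness[v] += 1.0 / sigma
                for a, b in zip(p, p[1:]):
                    edge_bet[tuple(sorted((a, b)))] += 1.0 / sigma
    for s in nodes:
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        reach = len(dist) - 1
        closeness[s] = reach / sum(dist.values()) if reach > 0 else 0.0
    for n in nodes:
        k = degree[n]
        if k < 2:
            clustering[n] = 0.0
            continue
        nbrs = list(adj[n])
        links = sum(
            1
            for a in range(len(nbrs))
            for b in range(a + 1, len(nbrs))
            if nbrs[b] in adj[nbrs[a]]
        )
        clustering[n] = 2.0 * links / (k * (k - 1))
    return degree, betweenness, closeness, clustering, edge_bet


def bf_modularity(nodes, edges, module_of) -> float:
    """Newman-Girvan modularity via the pairwise A_ij - k_i k_j / 2m sum."""
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    m = len(edges)
    if m == 0:
        return 0.0
    k = {n: len(adj[n]) for n in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if module_of.get(i) is not None and module_of.get(i) == module_of.get(j):
                a_ij = 1.0 if j in adj[i] else 0.0
                q += a_ij - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def bf_km(times, events):
    """Product-limit estimator evaluated by direct counting."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    out = []
    s = 1.0
    for t in event_times:
        n_at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1 - d / n_at_risk
        out.append((t, s))
    return out


def bf_logrank_2group(labels, times, events, group_a):
    """Two-sample log-rank via per-event-time hypergeometric increments."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({times[i] for i in range(len(times)) if events[i] == 1}):
        at_risk = [i for i in range(len(times)) if times[i] >= t]
        n = len(at_risk)
        d = sum(1 for i in at_risk if times[i] == t and events[i] == 1)
        n_a = sum(1 for i in at_risk if labels[i] == group_a)
        d_a = sum(
            1 for i in at_risk
            if labels[i] == group_a and times[i] == t and events[i] == 1
        )
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var
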