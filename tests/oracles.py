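"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (pure python / direct
linear algebra), deliberately not via the code paths or library calls the
package itself uses, so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- graph topology ---------------------------------------------------------


def all_shortest_paths(adj: dict[str, set[str]], s: str, t: str) -> list[list[str]]:
    """Enumerate every shortest s-t path by depth-first search."""
    if s == t:
        return [[s]]
    best: list[list[str]] = []
    best_len = [math.inf]

    def dfs(node: str, path: list[str]) -> None:
        if len(path) - 1 > best_len[0]:
            return
        if node == t:
            if len(path) - 1 < best_len[0]:
                best_len[0] = len(path) - 1
                best.clear()
            if len(path) - 1 == best_len[0]:
                best.append(path.copy())
            return
        for nb in sorted(adj[node]):
            if nb not in path:
                path.append(nb)
                dfs(nb, path)
                path.pop()

    dfs(s, [s])
    return best


def brute_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Normalized endpoint-excluding betweenness by explicit path counting."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            bc[v] += on / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: (bc[v] / norm if norm > 0 else 0.0) for v in nodes}


def brute_degree_centrality(adj: dict[str, set[str]]) -> dict[str, float]:
    n = len(adj)
    return {v: len(nb) / (n - 1) for v, nb in adj.items()}


def brute_clustering(adj: dict[str, set[str]]) -> dict[str, float]:
    out = {}
    for v, nb in adj.items():
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(sorted(nb), 2) if b in adj[a]
        )
        out[v] = links / (k * (k - 1) / 2)
    return out


def graph_as_adj(edges: list[tuple[str, str]], nodes: list[str]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


# -- diffusion --------------------------------------------------------------


def rwr_linear_solve(
    edges: list[tuple[str, str]], nodes: list[str], seeds: set[str], alpha: float
) -> dict[str, float]:
    """Closed-form fixed point of s = a W s + (1-a) e by dense linear solve."""
    order = sorted(nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v in edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    deg = a.sum(axis=0)
    w = np.divide(a, deg, out=np.zeros_like(a), where=deg > 0)
    e = np.zeros(n)
    for s in seeds:
        e[idx[s]] = 1.0 / len(seeds)
    sol = np.linalg.solve(np.eye(n) - alpha * w, (1 - alpha) * e)
    return {v: float(sol[idx[v]]) for v in order}


# -- hypergeometric / enrichment -------------------------------------------


def hypergeom_tail(ks: int, n_total: int, s0: int, k: int) -> float:
    """P(X >= ks) for X ~ Hypergeom(N=n_total, K=s0, n=k), by direct sum."""
    total = 0.0
    for x in range(ks, min(s0, k) + 1):
        total += (
            math.comb(s0, x) * math.comb(n_total - s0, k - x) / math.comb(n_total, k)
        )
    return total


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


# -- classification metrics -------------------------------------------------


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    def safe(num, den):
        return num / den if den else 0.0

    total = tp + tn + fp + fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "acc": safe(tp + tn, total),
        "prec": safe(tp, tp + fp),
        "rec": safe(tp, tp + fn),
        "npv": safe(tn, tn + fn),
        "ppv": safe(tp, tp + fp),
        "mcc": safe(tp * tn - fp * fn, mcc_den),
    }


def mann_whitney_auc(scores_pos: list[float], scores_neg: list[float]) -> float:
    """ROC AUC as the normalized Mann–Whitney U statistic."""
    wins = 0.0
    for p in scores_pos:
        for n in scores_neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


# -- voting -----------------------------------------------------------------


def enumerate_votes(classes: tuple[int, int, int], posteriors: tuple[float, ...]):
    """Reference jury / consensus / red-flag outcomes by direct definition."""
    votes = sum(classes)
    jury = 1 if votes > 0 else -1
    c = sum(p * cls for p, cls in zip(posteriors, classes))
    cons = 1 if c > 0 else -1
    if abs(votes) == 3:
        red = classes[0]
    else:
        counts = {1: classes.count(1), -1: classes.count(-1)}
        red = 1 if counts[1] < counts[-1] else -1
    return jury, c, cons, red


# -- random graphs ----------------------------------------------------------


def random_graph(rng: np.random.Generator, n: int, p: float):
    """Erdős–Rényi edge list over string node labels n0..n{n-1}."""
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges


def random_connected_graph(rng: np.random.Generator, n: int, p: float):
    """ER graph with a random spanning tree added, hence connected."""
    nodes, edges = random_graph(rng, n, p)
    edge_set = {frozenset(e) for e in edges}
    perm = list(rng.permutation(n))
    for i in range(1, n):
        u, v = f"n{perm[i]}", f"n{perm[int(rng.integers(i))]}"
        if frozenset((u, v)) not in edge_set:
            edge_set.add(frozenset((u, v)))
            edges.append((u, v))
    return nodes, edges
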