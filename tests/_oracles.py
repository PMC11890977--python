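"""Independent brute-force oracles for graph metrics and rank statistics.

These deliberately share no code with the package: distances via a
Floyd-Warshall triple loop, betweenness via exhaustive enumeration of all
shortest paths, clustering via explicit neighbor-pair counting, Spearman
via hand-rolled average ranks plus the Pearson formula.
"""

from __future__ import annotations

import math

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1)) if n > 1 else 0.0


def brute_nodal_efficiency(a: np.ndarray) -> np.ndarray:
    d = floyd_warshall(a)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                out[i] += 1.0 / d[i, j]
        out[i] /= max(n - 1, 1)
    return out


def brute_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for x in range(k) for y in range(x + 1, k) if a[nbrs[x], nbrs[y]])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = brute_global_efficiency(sub)
    return out


def brute_char_path_length(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    return float(np.mean(finite)) if finite else math.nan


def brute_nodal_path_length(a: np.ndarray) -> np.ndarray:
    d = floyd_warshall(a)
    n = a.shape[0]
    out = np.full(n, math.nan)
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])]
        if finite:
            out[i] = float(np.mean(finite))
    return out


def _all_shortest_paths(a: np.ndarray, s: int, t: int, d: np.ndarray) -> list[list[int]]:
    """Every shortest s-t path, by DFS down the distance gradient."""
    if not math.isfinite(d[s, t]):
        return []
    paths = []

    def extend(path: list[int]) -> None:
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in range(a.shape[0]):
            if a[v, w] and d[w, t] == d[v, t] - 1:
                extend(path + [w])

    extend([s])
    return paths


def brute_betweenness(a: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness by exhaustive enumeration of all shortest paths."""
    n = a.shape[0]
    d = floyd_warshall(a)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(a, s, t, d)
            if not paths:
                continue
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(values)
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho = Pearson correlation of average ranks."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    return float((x @ y) / math.sqrt((x @ x) * (y @ y)))


def random_er_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    return a + a.T
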