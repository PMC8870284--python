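"""Independent brute-force oracles for the graph measures and the rank-sum
test.

Everything here is deliberately naive: Floyd-Warshall distances, exhaustive
simple-path enumeration for shortest-path counts, direct triangle counting,
and full enumeration of rank assignments.  None of it shares code with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs

def enumerate_connected_graphs(n: int):
    """All labelled connected simple graphs on n nodes as adjacency arrays."""
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        a = np.zeros((n, n))
        for bit, (i, j) in enumerate(pairs):
            if mask >> bit & 1:
                a[i, j] = a[j, i] = 1.0
        if _connected(a):
            yield a


def _connected(a: np.ndarray) -> bool:
    n = a.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(a[u]):
            if v not in seen:
                seen.add(int(v))
                stack.append(int(v))
    return len(seen) == n


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    d = lengths.copy().astype(float)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def edge_lengths(w: np.ndarray, binary: bool) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, (1.0 if binary else 1.0 / np.where(w > 0, w, 1)), np.inf)
    if binary:
        lengths = np.where(w > 0, 1.0, np.inf)
    return lengths


def count_shortest_paths(w: np.ndarray, binary: bool, tol: float = 1e-9):
    """Distances and shortest-path counts by exhaustive simple-path
    enumeration."""
    n = w.shape[0]
    lengths = edge_lengths(w, binary)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best, cnt = np.inf, 0
            for path in _simple_paths(lengths, s, t):
                plen = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                if plen < best - tol:
                    best, cnt = plen, 1
                elif abs(plen - best) <= tol:
                    cnt += 1
            dist[s, t] = best
            counts[s, t] = cnt
    return dist, counts


def _simple_paths(lengths: np.ndarray, s: int, t: int, path=None):
    path = [s] if path is None else path
    u = path[-1]
    if u == t:
        yield list(path)
        return
    for v in np.flatnonzero(np.isfinite(lengths[u])):
        v = int(v)
        if v not in path:
            yield from _simple_paths(lengths, s, t, path + [v])


# --------------------------------------------------------------- metrics

def oracle_global_efficiency(w: np.ndarray, binary: bool):
    d = floyd_warshall(edge_lengths(w, binary))
    n = w.shape[0]
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
    per = inv.sum(axis=1) / (n - 1)
    return per, inv.sum() / (n * (n - 1))


def oracle_char_path(w: np.ndarray, binary: bool):
    d = floyd_warshall(edge_lengths(w, binary))
    n = w.shape[0]
    per = np.zeros(n)
    vals = []
    unreach = 0
    for i in range(n):
        row = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        unreach += sum(1 for j in range(n) if j != i and not np.isfinite(d[i, j]))
        per[i] = np.mean(row) if row else 0.0
        vals.extend(row)
    return per, (np.mean(vals) if vals else 0.0), unreach


def oracle_local_efficiency(w: np.ndarray, binary: bool):
    n = w.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(edge_lengths(sub, binary))
        tot = 0.0
        for a in range(nbrs.size):
            for b in range(nbrs.size):
                if a != b and np.isfinite(d[a, b]):
                    tot += 1.0 / d[a, b]
        per[i] = tot / (nbrs.size * (nbrs.size - 1))
    return per, per.mean()


def oracle_clustering(w: np.ndarray):
    """Direct triangle counting on the binary pattern."""
    a = (w > 0).astype(float)
    n = a.shape[0]
    per = np.zeros(n)
    for h in range(n):
        nbrs = np.flatnonzero(a[h])
        d = nbrs.size
        if d < 2:
            continue
        links = sum(
            a[i, j] for i in nbrs for j in nbrs if i != j
        )  # ordered neighbor pairs
        per[h] = links / (d * (d - 1))
    return per, per.mean()


def oracle_betweenness(w: np.ndarray, binary: bool):
    n = w.shape[0]
    lengths = edge_lengths(w, binary)
    nb = np.zeros(n)
    for v in range(n):
        for t in range(v + 1, n):
            shortest = []
            best = np.inf
            for path in _simple_paths(lengths, v, t):
                plen = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                if plen < best - 1e-9:
                    best, shortest = plen, [path]
                elif abs(plen - best) <= 1e-9:
                    shortest.append(path)
            if not shortest:
                continue
            for u in range(n):
                if u in (v, t):
                    continue
                through = sum(1 for p in shortest if u in p[1:-1])
                nb[u] += through / len(shortest)
    return nb


def oracle_strength(w: np.ndarray):
    return w.sum(axis=1)


def oracle_assortativity(w: np.ndarray, binary: bool):
    ii, jj = np.nonzero(np.triu(w, 1))
    if ii.size == 0:
        return np.nan
    x = (w > 0).sum(axis=1).astype(float) if binary else w.sum(axis=1)
    j = x[ii]
    k = x[jj]
    e = ii.size
    m1 = np.sum((j + k) / 2) / e
    num = np.sum(j * k) / e - m1**2
    den = np.sum((j**2 + k**2) / 2) / e - m1**2
    return np.nan if abs(den) < 1e-15 else num / den


# -------------------------------------------------------------- rank sum

def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of rank assignments
    (midranks for ties)."""
    from scipy.stats import rankdata

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    n = len(pooled)
    mu = na * (n + 1) / 2.0
    w_obs = ranks[:na].sum()
    hits = total = 0
    for idx in itertools.combinations(range(n), na):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total
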