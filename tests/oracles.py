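"""Brute-force reference implementations used as independent test oracles.

Everything here is deliberately naive (path enumeration, direct formula
evaluation) and shares no code with the package's implementations.
"""

from __future__ import annotations

import numpy as np


def enumerate_simple_paths(lengths: np.ndarray, s: int, t: int):
    """All simple paths s -> t as (node list, total length) pairs."""
    n = lengths.shape[0]
    out = []

    def _extend(path, total):
        cur = path[-1]
        if cur == t:
            out.append((list(path), total))
            return
        for nxt in range(n):
            if np.isfinite(lengths[cur, nxt]) and nxt not in path:
                path.append(nxt)
                _extend(path, total + lengths[cur, nxt])
                path.pop()

    _extend([s], 0.0)
    return out


def brute_shortest_paths(lengths: np.ndarray) -> np.ndarray:
    """Shortest-path matrix by exhaustive simple-path enumeration."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(lengths, s, t)
            if paths:
                best = min(total for _, total in paths)
                d[s, t] = d[t, s] = best
    return d


def brute_betweenness(lengths: np.ndarray, rel_tol: float = 1e-9) -> np.ndarray:
    """Unnormalised betweenness by enumerating all shortest paths per pair.

    For every unordered pair, all simple paths within relative tolerance of
    the minimum length count as shortest; each interior node receives the
    fraction of those paths passing through it.
    """
    n = lengths.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(lengths, s, t)
            if not paths:
                continue
            best = min(total for _, total in paths)
            shortest = [p for p, total in paths if total <= best * (1 + rel_tol)]
            for p in shortest:
                for node in p[1:-1]:
                    bc[node] += 1.0 / len(shortest)
    return bc


def brute_clustering(weights: np.ndarray) -> np.ndarray:
    """Geometric-mean triangle clustering by direct triple loops."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = int(np.sum(w[i] > 0))
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (wn[i, j] * wn[j, h] * wn[h, i]) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def brute_global_efficiency(lengths: np.ndarray) -> float:
    d = brute_shortest_paths(lengths)
    n = d.shape[0]
    acc = 0.0
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            cnt += 1
            if np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / cnt if cnt else 0.0


def brute_local_efficiency(weights: np.ndarray) -> np.ndarray:
    """Neighbour-subgraph efficiency on globally max-normalised weights."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    wmax = w.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    wn = w / wmax
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), np.inf)
        np.fill_diagonal(lengths, np.inf)
        out[i] = brute_global_efficiency(lengths)
    return out


def brute_bh_stepup(p_values, q: float):
    """Literal Benjamini-Hochberg step-up: rejections and adjusted values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    q_sorted = np.empty(m)
    running = 1.0
    for k in range(m, 0, -1):
        running = min(running, m * ps[k - 1] / k)
        q_sorted[k - 1] = running
    q_adj = np.empty(m)
    q_adj[order] = q_sorted
    return q_adj, reject


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.5):
    """Random symmetric weighted adjacency with roughly the given density."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    vals = rng.uniform(0.2, 5.0, size=iu.size) * present
    w[iu, ju] = vals
    w[ju, iu] = vals
    return w


def all_metric_closed_forms_complete(n: int) -> dict:
    """Closed-form metrics for the unit-weight complete graph K_n."""
    return {
        "strength": float(n - 1),
        "char_path_length": 1.0,
        "global_efficiency": 1.0,
        "betweenness": 0.0,
        "clustering": 1.0,
        "local_efficiency": 1.0,
    }
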