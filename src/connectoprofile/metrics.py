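"""The eight global graph metrics for weighted structural connectomes.

Conventions follow common practice for streamline-weighted connectomes:

* edge weight -> length remap is the reciprocal, L_ij = 1 / w_ij (strong
  connections are short paths); absent edges have infinite length;
* the characteristic path length averages shortest-path lengths over the
  connected (finite) unordered node pairs and reports how many pairs were
  unreachable;
* global efficiency averages 1 / d_ij over all unordered pairs, counting
  unreachable pairs as zero efficiency;
* the weighted clustering coefficient is the geometric-mean triangle
  (Onnela) formula on weights normalised by the network maximum;
* local efficiency of node i is the global efficiency of the subgraph
  induced by i's neighbours, on max-normalised weights;
* betweenness centrality is the unnormalised weighted Brandes count over
  unordered source-target pairs, with equal-length path multiplicities
  split fractionally;
* navigation efficiency scores decentralised greedy geometric routing:
  from s, repeatedly hop to the connected neighbour closest (Euclidean,
  region centroids) to t, failing when the walk revisits a node or hits a
  node without neighbours; successful walks contribute the reciprocal of
  their summed edge lengths, failures contribute zero;
* the normalised clustering coefficient divides mean clustering by the
  mean clustering of degree-preserving rewired surrogates that keep the
  multiset of edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import MetricUndefinedError
from .io import ConnectivityMatrix, NodeTable

METRIC_NAMES = [
    "strength",
    "global_efficiency",
    "char_path_length",
    "navigation_efficiency",
    "local_efficiency",
    "clustering",
    "normalized_clustering",
    "betweenness",
]


@dataclass
class NullModelConfig:
    """Parameters of the degree-preserving rewiring null model."""

    n_nulls: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1 or self.rewires_per_edge < 1:
            raise ValueError("n_nulls and rewires_per_edge must be positive")


@dataclass
class MetricProfile:
    """The eight global metrics for one subject, plus per-node vectors."""

    subject_id: str
    strength: float
    global_efficiency: float
    char_path_length: float
    navigation_efficiency: float
    local_efficiency: float
    clustering: float
    normalized_clustering: float
    betweenness: float
    strength_vec: np.ndarray = field(repr=False, default=None)
    clustering_vec: np.ndarray = field(repr=False, default=None)
    local_efficiency_vec: np.ndarray = field(repr=False, default=None)
    betweenness_vec: np.ndarray = field(repr=False, default=None)
    n_unreachable_pairs: int = 0
    navigation_success_rate: float = 1.0
    seed: int | None = None

    def values(self) -> dict[str, float]:
        """The eight global metrics in canonical order."""
        return {name: float(getattr(self, name)) for name in METRIC_NAMES}


def remap_weights_to_lengths(weights: np.ndarray) -> np.ndarray:
    """Reciprocal weight->length remap; zero weights become +inf (no edge)."""
    w = np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, np.inf)  # self-loops excluded; d_ii set to 0 downstream
    return lengths


def all_pairs_shortest_paths(lengths: np.ndarray) -> np.ndarray:
    """Dijkstra over the length matrix; d_ii = 0, unreachable pairs +inf."""
    n = lengths.shape[0]
    finite = np.isfinite(lengths)
    graph = csr_matrix((lengths[finite], np.nonzero(finite)), shape=(n, n))
    d = dijkstra(graph, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def characteristic_path_length(d: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path length over connected unordered pairs.

    Returns ``(L, n_excluded)`` where ``n_excluded`` counts unreachable
    unordered pairs left out of the mean. Raises
    :class:`MetricUndefinedError` when no pair is connected.
    """
    iu, ju = np.triu_indices(d.shape[0], k=1)
    vals = d[iu, ju]
    reachable = np.isfinite(vals)
    n_excluded = int(np.sum(~reachable))
    if not np.any(reachable):
        raise MetricUndefinedError("all node pairs unreachable; path length undefined")
    return float(vals[reachable].mean()), n_excluded


def global_efficiency(d: np.ndarray) -> float:
    """Mean of 1/d_ij over all unordered pairs, with 1/inf := 0."""
    iu, ju = np.triu_indices(d.shape[0], k=1)
    vals = d[iu, ju]
    with np.errstate(divide="ignore"):
        inv = np.where(vals > 0, 1.0 / np.where(vals > 0, vals, 1.0), 0.0)
    inv[~np.isfinite(vals)] = 0.0
    return float(inv.mean())


def node_strengths(weights: np.ndarray) -> np.ndarray:
    """s_i = sum_j w_ij."""
    return np.asarray(weights, dtype=float).sum(axis=1)


def clustering_coefficients(weights: np.ndarray) -> np.ndarray:
    """Weighted clustering via geometric-mean triangles on max-normalised weights.

    C_i = sum_{j,h} (w~_ij w~_jh w~_hi)^(1/3) / (k_i (k_i - 1)), with
    w~ = w / max(w) and k_i the binary degree; nodes of degree < 2 get 0.
    """
    w = np.asarray(weights, dtype=float)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    cbrt = np.cbrt(w / wmax)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)  # 2 * sum of cube-root triangle products
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(w.shape[0])
    mask = denom > 0
    out[mask] = triangles[mask] / denom[mask]
    return out


def local_efficiency(weights: np.ndarray) -> np.ndarray:
    """Per-node global efficiency of the neighbour-induced subgraph.

    Weights are max-normalised by the whole-network maximum before the
    reciprocal remap, so values lie in [0, 1]; nodes with fewer than two
    neighbours get 0.
    """
    w = np.asarray(weights, dtype=float)
    wmax = w.max()
    out = np.zeros(w.shape[0])
    if wmax == 0:
        return out
    wn = w / wmax
    for i in range(w.shape[0]):
        nbrs = np.nonzero(wn[i])[0]
        if nbrs.size < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        d = all_pairs_shortest_paths(remap_weights_to_lengths(sub))
        out[i] = global_efficiency(d)
    return out


def betweenness_centrality(lengths: np.ndarray) -> np.ndarray:
    """Unnormalised weighted betweenness (Brandes) on the length matrix.

    Counts unordered source-target pairs whose shortest paths pass through
    each node, splitting ties fractionally; endpoints are excluded. On an
    84-node connectome hub values reach the low thousands.
    """
    n = lengths.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(lengths[iu, ju])
    g.add_weighted_edges_from(
        zip(iu[finite].tolist(), ju[finite].tolist(), lengths[iu, ju][finite].tolist()),
        weight="length",
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(n)])


def navigation_efficiency(
    weights: np.ndarray,
    coords: np.ndarray,
    length: str = "reciprocal",
) -> tuple[float, np.ndarray]:
    """Greedy geometric navigation efficiency over all ordered pairs.

    From source s toward target t, each step moves to the connected
    neighbour with the smallest Euclidean distance to t (ties broken by
    lowest node index); the walk fails if that neighbour was already
    visited or the current node has no neighbours. ``length='reciprocal'``
    sums remapped edge lengths 1/w along successful walks;
    ``length='hops'`` counts hops. Returns the mean pairwise efficiency
    (failures contribute 0) and the ordered-pair success mask.
    """
    if length not in ("reciprocal", "hops"):
        raise ValueError(f"unknown navigation length variant '{length}'")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n, 3):
        raise ValueError("coordinates must be an (N, 3) array matching the matrix")
    diff = coords[:, None, :] - coords[None, :, :]
    geo = np.sqrt((diff**2).sum(axis=-1))  # Euclidean centroid distances
    neighbours = [np.nonzero(w[i])[0] for i in range(n)]
    success = np.zeros((n, n), dtype=bool)
    eff_sum = 0.0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            cur = s
            visited = {s}
            walk_len = 0.0
            while cur != t:
                nbrs = neighbours[cur]
                if nbrs.size == 0:
                    break
                # argmin is index-stable: ties resolve to the lowest node index
                nxt = nbrs[np.argmin(geo[nbrs, t])]
                if nxt in visited:
                    break
                walk_len += 1.0 if length == "hops" else 1.0 / w[cur, nxt]
                visited.add(nxt)
                cur = nxt
            if cur == t:
                success[s, t] = True
                eff_sum += 1.0 / walk_len
    return eff_sum / (n * (n - 1)), success


def rewired_surrogate(
    weights: np.ndarray, rng: np.random.Generator, rewires_per_edge: int = 10
) -> np.ndarray:
    """Degree-preserving double-edge-swap surrogate keeping the weight multiset.

    Attempts ``rewires_per_edge * E`` swaps; each picks two edges (a, b),
    (c, d) and rewires to (a, d), (c, b), rejecting self-loops and
    duplicate edges. Weights travel with the edge slots, so the multiset
    of weights and every node's binary degree are preserved (strengths are
    not — that is the point of the null).
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    heads = iu[mask].tolist()
    tails = ju[mask].tolist()
    wvals = w[iu, ju][mask].tolist()
    n_edges = len(heads)
    if n_edges < 2:
        return w.copy()
    present = set(zip(heads, tails))
    attempts = rewires_per_edge * n_edges
    e1s = rng.integers(0, n_edges, size=attempts)
    e2s = rng.integers(0, n_edges, size=attempts)
    flips = rng.random(attempts) < 0.5
    for e1, e2, flip in zip(e1s, e2s, flips):
        if e1 == e2:
            continue
        a, b = heads[e1], tails[e1]
        c, d = heads[e2], tails[e2]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (b, c) if b < c else (c, b)
        if new1 in present or new2 in present or new1 == new2:
            continue
        present.discard((heads[e1], tails[e1]))
        present.discard((heads[e2], tails[e2]))
        present.add(new1)
        present.add(new2)
        heads[e1], tails[e1] = new1
        heads[e2], tails[e2] = new2
    out = np.zeros_like(w)
    hs = np.array(heads, dtype=int)
    ts = np.array(tails, dtype=int)
    vs = np.array(wvals)
    out[hs, ts] = vs
    out[ts, hs] = vs
    return out


def normalized_clustering(weights: np.ndarray, cfg: NullModelConfig) -> float:
    """Mean clustering divided by its mean over rewired surrogates.

    Deterministic for a given ``cfg.seed``.
    """
    c_obs = clustering_coefficients(weights).mean()
    rng = np.random.default_rng(cfg.seed)
    null_means = np.empty(cfg.n_nulls)
    for k in range(cfg.n_nulls):
        surrogate = rewired_surrogate(weights, rng, cfg.rewires_per_edge)
        null_means[k] = clustering_coefficients(surrogate).mean()
    c_null = null_means.mean()
    if c_null == 0:
        raise MetricUndefinedError("null-model clustering is zero; C_norm undefined")
    return float(c_obs / c_null)


def compute_metric_profile(
    m: ConnectivityMatrix,
    nodes: NodeTable,
    cfg: NullModelConfig | None = None,
    navigation_length: str = "reciprocal",
) -> MetricProfile:
    """All eight global metrics plus per-node vectors for one subject."""
    cfg = cfg or NullModelConfig()
    w = m.weights
    lengths = remap_weights_to_lengths(w)
    d = all_pairs_shortest_paths(lengths)
    cpl, n_excluded = characteristic_path_length(d)
    strengths = node_strengths(w)
    clust = clustering_coefficients(w)
    loc_eff = local_efficiency(w)
    bc = betweenness_centrality(lengths)
    e_nav, nav_success = navigation_efficiency(w, nodes.coords, length=navigation_length)
    n = w.shape[0]
    return MetricProfile(
        subject_id=m.subject_id,
        strength=float(strengths.mean()),
        global_efficiency=global_efficiency(d),
        char_path_length=cpl,
        navigation_efficiency=float(e_nav),
        local_efficiency=float(loc_eff.mean()),
        clustering=float(clust.mean()),
        normalized_clustering=normalized_clustering(w, cfg),
        betweenness=float(bc.mean()),
        strength_vec=strengths,
        clustering_vec=clust,
        local_efficiency_vec=loc_eff,
        betweenness_vec=bc,
        n_unreachable_pairs=n_excluded,
        navigation_success_rate=float(nav_success.sum() / (n * (n - 1))),
        seed=cfg.seed,
    )
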