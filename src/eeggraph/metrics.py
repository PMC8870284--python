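"""Graph-theory measures of thresholded functional networks.

Seven measures are computed per network: local efficiency, clustering
coefficient, global efficiency, node strength, node betweenness
centrality, characteristic path length and degree assortativity.  All are
defined for undirected networks in either binary or weighted mode.

Conventions
-----------
* Weighted path length: an edge of weight ``w`` has length ``1/w``
  (stronger correlation = shorter path).  Binary edges have length 1.
* Unreachable pairs contribute 0 to efficiencies and are excluded from
  the characteristic path length, whose unreachable-pair count is
  recorded alongside.
* Nodes of degree < 2 contribute 0 to local efficiency and clustering,
  keeping the division by N in the network averages literal.
* Betweenness sums over unordered pairs with both endpoints distinct
  from the counted node and is not normalized.
* The clustering coefficient uses the binary connection pattern
  ``a_ij`` even in weighted mode; strength uses the weights.  In
  weighted mode assortativity correlates endpoint strengths instead of
  degrees.

Degenerate cases: assortativity of a degree-regular network is NaN
(zero variance on both edge ends); an edgeless network has no defined
assortativity and raises.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import Network

__all__ = [
    "MetricSet",
    "shortest_paths",
    "local_efficiency",
    "clustering_coefficient",
    "global_efficiency",
    "node_strength",
    "betweenness_centrality",
    "characteristic_path",
    "assortativity",
    "compute_metrics",
    "GraphMetricsExtractor",
    "METRIC_NAMES",
]

#: Canonical order of the seven measures in feature layouts and tables.
METRIC_NAMES = (
    "local_efficiency",
    "clustering",
    "strength",
    "betweenness",
    "global_efficiency",
    "char_path",
    "assortativity",
)

_REL_TOL = 1e-12  # relative tolerance for equal-length shortest paths


def _as_network(net) -> Network:
    if isinstance(net, Network):
        return net
    w = np.asarray(net, dtype=float)
    mode = "binary" if set(np.unique(w)) <= {0.0, 1.0} else "weighted"
    return Network(w=w, density=1.0, mode=mode)


def _length_matrix(net: Network) -> np.ndarray:
    """Edge lengths: 1 for binary edges, 1/w for weighted; inf where absent."""
    with np.errstate(divide="ignore"):
        lengths = np.where(net.w > 0, 1.0 / np.where(net.w > 0, net.w, 1.0), np.inf)
    if net.mode == "binary":
        lengths = np.where(net.w > 0, 1.0, np.inf)
    return lengths


def _dijkstra_counts(lengths: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-source shortest-path distances and path counts.

    Equal-length alternatives are merged with a relative tolerance, which
    matters only for weighted graphs with numerically tied path sums.
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in np.flatnonzero(np.isfinite(lengths[u])):
            if done[v]:
                continue
            nd = d + lengths[u, v]
            tol = _REL_TOL * max(1.0, nd)
            if nd < dist[v] - tol:
                dist[v] = nd
                sigma[v] = sigma[u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tol:
                sigma[v] += sigma[u]
    return dist, sigma


def shortest_paths(net) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and shortest-path counts.

    Returns ``(D, sigma)`` where ``D[i, j]`` is the distance (hop count in
    binary mode, sum of 1/w lengths in weighted mode; inf if unreachable)
    and ``sigma[i, j]`` the number of distinct shortest i-j paths
    (``sigma[i, i] = 1``).
    """
    net = _as_network(net)
    lengths = _length_matrix(net)
    n = net.n_nodes
    D = np.empty((n, n))
    S = np.empty((n, n))
    for s in range(n):
        D[s], S[s] = _dijkstra_counts(lengths, s)
    return D, S


def _pairwise_subgraph_distances(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    out = np.empty((n, n))
    for s in range(n):
        out[s], _ = _dijkstra_counts(lengths, s)
    return out


def local_efficiency(net) -> tuple[np.ndarray, float]:
    """Per-node and network local efficiency.

    For node i with d_i >= 2 neighbors: the mean inverse shortest-path
    length between its neighbors, measured in the induced subgraph of the
    neighbors with node i removed, normalized by d_i(d_i - 1) ordered
    pairs.  Degree-deficient nodes score 0.  The network value is the
    plain mean over all N nodes.
    """
    net = _as_network(net)
    n = net.n_nodes
    lengths = _length_matrix(net)
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(net.w[i] > 0)
        d_i = nbrs.size
        if d_i < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        dists = _pairwise_subgraph_distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dists
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        per_node[i] = inv.sum() / (d_i * (d_i - 1))
    return per_node, float(per_node.mean())


def clustering_coefficient(net) -> tuple[np.ndarray, float]:
    """Per-node and network clustering coefficient (triangle intensity).

    Per node h with degree >= 2: the number of ordered connected neighbor
    pairs divided by d_h(d_h - 1); computed on the binary pattern of the
    thresholded network in both modes.
    """
    net = _as_network(net)
    a = net.binary_pattern()
    deg = a.sum(axis=1)
    # (A^3)_hh counts ordered neighbor pairs (i, j) of h with a_ij = 1
    ordered_pairs = np.diag(a @ a @ a)
    per_node = np.zeros(net.n_nodes)
    ok = deg >= 2
    per_node[ok] = ordered_pairs[ok] / (deg[ok] * (deg[ok] - 1))
    return per_node, float(per_node.mean())


def global_efficiency(net) -> tuple[np.ndarray, float]:
    """Per-node efficiency e_i and network global efficiency.

    e_i = mean of 1/L_ij over the other N-1 nodes; the network value is
    the mean over all ordered pairs, with 1/inf = 0 for unreachable pairs.
    """
    net = _as_network(net)
    D, _ = shortest_paths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    n = net.n_nodes
    per_node = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    glob = inv.sum() / (n * (n - 1)) if n > 1 else 0.0
    return per_node, float(glob)


def node_strength(net) -> np.ndarray:
    """S(i): row sum of the (weighted or binary) adjacency."""
    net = _as_network(net)
    return net.w.sum(axis=1)


def betweenness_centrality(net) -> np.ndarray:
    """Unnormalized node betweenness.

    NB(u) sums, over unordered pairs {v, w} with u, v, w all distinct, the
    fraction of shortest v-w paths passing through u; disconnected pairs
    contribute 0.
    """
    net = _as_network(net)
    n = net.n_nodes
    D, S = shortest_paths(net)
    nb = np.zeros(n)
    for v in range(n):
        for w in range(v + 1, n):
            if not np.isfinite(D[v, w]) or S[v, w] == 0:
                continue
            for u in range(n):
                if u == v or u == w:
                    continue
                through = D[v, u] + D[u, w]
                if np.isfinite(through) and abs(through - D[v, w]) <= _REL_TOL * max(
                    1.0, D[v, w]
                ):
                    nb[u] += S[v, u] * S[u, w] / S[v, w]
    return nb


def characteristic_path(net) -> tuple[np.ndarray, float, int]:
    """Per-node mean distance L_i, network characteristic path length CP,
    and the count of unreachable ordered pairs.

    Both averages run over reachable pairs only (the mean of an infinite
    distance is undefined); a node with no reachable peers gets L_i = 0.
    """
    net = _as_network(net)
    D, _ = shortest_paths(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    per_node = np.zeros(n)
    for i in range(n):
        m = finite[i]
        if m.any():
            per_node[i] = D[i, m].mean()
    n_unreachable = int(np.count_nonzero(off & ~finite))
    cp = float(D[finite].mean()) if finite.any() else 0.0
    return per_node, cp, n_unreachable


def assortativity(net) -> float:
    """Degree (binary) or strength (weighted) correlation across edges.

    Negative values mean hubs preferentially attach to low-degree nodes
    (disassortative); NaN for degree-regular networks (0/0).
    """
    net = _as_network(net)
    edges = net.edge_list()
    if not edges:
        raise ValueError("assortativity undefined for a network with no edges")
    x = net.degrees() if net.mode == "binary" else node_strength(net)
    j = np.array([x[i] for i, _, _ in edges])
    k = np.array([x[jj] for _, jj, _ in edges])
    m1 = np.mean((j + k) / 2.0)
    num = np.mean(j * k) - m1**2
    den = np.mean((j**2 + k**2) / 2.0) - m1**2
    if abs(den) < 1e-15:
        return float("nan")
    return float(num / den)


@dataclass
class MetricSet:
    """All seven measures for one network (one epoch)."""

    loc_eff_node: np.ndarray
    loc_eff: float
    clustering_node: np.ndarray
    clustering: float
    glob_eff_node: np.ndarray
    glob_eff: float
    strength_node: np.ndarray
    betweenness_node: np.ndarray
    char_path_node: np.ndarray
    char_path: float
    assortativity: float
    n_unreachable_pairs: int = 0
    subject_id: str = ""
    group: str = ""
    state: str = ""
    epoch_index: int = 0
    channel_labels: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return len(self.strength_node)

    def nodal_matrix(self) -> np.ndarray:
        """7 x N matrix of per-node values in :data:`METRIC_NAMES` order.

        Network-level assortativity is broadcast across nodes; NaN
        assortativity (degree-regular network) appears as NaN here and is
        imputed downstream.
        """
        n = self.n_nodes
        return np.vstack(
            [
                self.loc_eff_node,
                self.clustering_node,
                self.strength_node,
                self.betweenness_node,
                self.glob_eff_node,
                self.char_path_node,
                np.full(n, self.assortativity),
            ]
        )

    def network_scalars(self) -> dict[str, float]:
        """Network-level value of each measure (per-node measures averaged)."""
        return {
            "local_efficiency": self.loc_eff,
            "clustering": self.clustering,
            "strength": float(np.mean(self.strength_node)),
            "betweenness": float(np.mean(self.betweenness_node)),
            "global_efficiency": self.glob_eff,
            "char_path": self.char_path,
            "assortativity": self.assortativity,
        }


def compute_metrics(net) -> MetricSet:
    """Evaluate all seven measures on one thresholded network."""
    net = _as_network(net)
    loc_node, loc = local_efficiency(net)
    cc_node, cc = clustering_coefficient(net)
    ge_node, ge = global_efficiency(net)
    cp_node, cp, n_unreach = characteristic_path(net)
    try:
        assort = assortativity(net)
    except ValueError:
        assort = float("nan")
    return MetricSet(
        loc_eff_node=loc_node,
        loc_eff=loc,
        clustering_node=cc_node,
        clustering=cc,
        glob_eff_node=ge_node,
        glob_eff=ge,
        strength_node=node_strength(net),
        betweenness_node=betweenness_centrality(net),
        char_path_node=cp_node,
        char_path=cp,
        assortativity=assort,
        n_unreachable_pairs=n_unreach,
        subject_id=net.subject_id,
        group=net.group,
        state=net.state,
        epoch_index=net.epoch_index,
        channel_labels=net.channel_labels,
    )


class GraphMetricsExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of networks -> list of :class:`MetricSet`."""

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [compute_metrics(net) for net in X]


def metrics_to_frames(
    metric_sets: list[MetricSet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables: one row per (subject, state, epoch, node) with the seven
    nodal values, and a companion table of network-level scalars."""
    node_rows, net_rows = [], []
    for ms in metric_sets:
        labels = ms.channel_labels or tuple(f"CH{i + 1}" for i in range(ms.n_nodes))
        nodal = ms.nodal_matrix()
        for node_idx, label in enumerate(labels):
            row = {
                "subject_id": ms.subject_id,
                "group": ms.group,
                "state": ms.state,
                "epoch": ms.epoch_index,
                "node": label,
            }
            row.update(
                {name: nodal[m, node_idx] for m, name in enumerate(METRIC_NAMES)}
            )
            node_rows.append(row)
        net_row = {
            "subject_id": ms.subject_id,
            "group": ms.group,
            "state": ms.state,
            "epoch": ms.epoch_index,
            "n_unreachable_pairs": ms.n_unreachable_pairs,
        }
        net_row.update(ms.network_scalars())
        net_rows.append(net_row)
    return pd.DataFrame(node_rows), pd.DataFrame(net_rows)
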