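"""Graph-theoretic measures of binary brain networks.

Global measures
---------------
* clustering coefficient ``C``: mean over nodes of the fraction of
  realized edges among each node's neighbours (segregation),
* characteristic path length ``L``: mean shortest-path hop distance
  over node pairs (integration),
* small-world index ``sigma = (C/C_rand) / (L/L_rand)``, where
  ``C_rand`` and ``L_rand`` are ensemble means over degree-preserving
  random reference graphs obtained by connectivity-preserving edge-swap
  (Maslov-Sneppen) rewiring.

Nodal measure
-------------
* betweenness centrality: the fraction of all-pairs shortest paths
  passing through a node, normalized by ``(N-1)(N-2)/2`` so values lie
  in [0, 1].  A node is a *hub* when its betweenness is at least two
  standard deviations above the across-node mean.

Clustering and path length are computed with dense linear algebra and
``scipy.sparse.csgraph`` (fast inside permutation loops); betweenness
uses igraph's C implementation of Brandes' algorithm; rewiring uses
networkx.  On a disconnected graph the path length is computed on the
largest connected component (the caller can flag this via
:func:`scnet.networks.is_connected`).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .errors import DataError


@dataclass(frozen=True)
class GlobalMetrics:
    """Global measures of one binary graph at one density."""

    C: float
    L: float
    C_rand: float
    L_rand: float
    sigma: float
    n_random: int
    density: float


@dataclass(frozen=True)
class HubSet:
    """Regions whose betweenness is >= mean + 2 SD across regions."""

    hubs: tuple[tuple[str, float], ...]
    mean: float
    sd: float

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.hubs)


def clustering_coefficient(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient.

    Per-node value: edges among the node's neighbours divided by the
    number of possible such edges; nodes of degree < 2 contribute 0.
    """
    a = adj.astype(float)
    n = a.shape[0]
    if n == 0:
        return 0.0, np.zeros(0)
    deg = a.sum(axis=1)
    closed = np.einsum("ij,jk,ki->i", a, a, a)  # 2x triangles per node
    denom = deg * (deg - 1)
    per_node = np.where(denom > 0, closed / np.where(denom > 0, denom, 1.0), 0.0)
    return float(per_node.mean()), per_node


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    return csgraph.shortest_path(csr_matrix(adj), method="D", unweighted=True)


def characteristic_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path hop distance over unordered node pairs.

    On a disconnected graph the mean is taken over pairs within the
    largest connected component.
    """
    n = adj.shape[0]
    if n < 2:
        raise DataError("path length needs at least 2 nodes")
    dist = _hop_distances(adj)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if finite.all():
        return float(d.mean())
    n_comp, labels = csgraph.connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    comp = np.argmax(sizes)
    idx = np.flatnonzero(labels == comp)
    if len(idx) < 2:
        raise DataError("largest component has fewer than 2 nodes")
    sub = dist[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
    return float(sub.mean())


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness centrality per node, in [0, 1]."""
    n = adj.shape[0]
    rows, cols = np.nonzero(np.triu(adj, k=1))
    g = ig.Graph(n=n, edges=list(zip(rows.tolist(), cols.tolist())))
    raw = np.asarray(g.betweenness(), dtype=float)
    if n < 3:
        return np.zeros(n)
    return raw / ((n - 1) * (n - 2) / 2.0)


def random_reference(
    adj: np.ndarray,
    n_random: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Ensemble means (C_rand, L_rand) over degree-preserving rewirings.

    Each reference graph is produced by attempting
    ``n_swaps_per_edge * E`` double-edge swaps that preserve both the
    degree sequence and connectivity; swaps that would disconnect the
    graph are rejected.  Raises :class:`DataError` when the graph is so
    constrained that no swap ever succeeds.
    """
    g0 = nx.from_numpy_array(adj)
    n_edges = g0.number_of_edges()
    if n_edges < 2:
        raise DataError("graph too small to rewire")
    if not nx.is_connected(g0):
        raise DataError("random_reference requires a connected graph")
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    total_swapped = 0
    for _ in range(n_random):
        g = g0.copy()
        try:
            swapped = nx.connected_double_edge_swap(
                g, nswap=n_swaps_per_edge * n_edges, seed=rng
            )
        except nx.NetworkXError as exc:
            raise DataError(f"degree-preserving rewiring failed: {exc}") from exc
        total_swapped += swapped
        a = nx.to_numpy_array(g, dtype=bool)
        cs.append(clustering_coefficient(a)[0])
        ls.append(characteristic_path_length(a))
    if total_swapped == 0:
        raise DataError("graph too constrained to rewire (no swap accepted)")
    return float(np.mean(cs)), float(np.mean(ls))


def small_world_index(C: float, L: float, C_rand: float, L_rand: float) -> float:
    """sigma = (C/C_rand) / (L/L_rand).

    ``C`` may be zero (giving sigma 0); the remaining inputs must be
    strictly positive.
    """
    if C < 0:
        raise DataError(f"C must be nonnegative, got {C}")
    for name, v in (("L", L), ("C_rand", C_rand), ("L_rand", L_rand)):
        if v <= 0:
            raise DataError(f"{name} must be positive, got {v}")
    return (C / C_rand) / (L / L_rand)


def global_metrics(
    adj: np.ndarray,
    density: float,
    n_random: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """C, L, random-reference means, and sigma for one graph."""
    C, _ = clustering_coefficient(adj)
    L = characteristic_path_length(adj)
    C_rand, L_rand = random_reference(adj, n_random, n_swaps_per_edge, seed)
    sigma = small_world_index(C, L, C_rand, L_rand)
    return GlobalMetrics(C, L, C_rand, L_rand, sigma, n_random, density)


def identify_hubs(
    values: np.ndarray, region_names, ddof: int = 0
) -> HubSet:
    """Regions with betweenness >= mean + 2 SD.

    The SD is the population SD by default (``ddof=0``); pass
    ``ddof=1`` for the sample convention.  A zero SD (all regions
    equal) yields an empty hub set.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise DataError("hub detection needs at least 2 regions")
    if len(values) != len(region_names):
        raise DataError("values and region names differ in length")
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof))
    if sd == 0:
        return HubSet((), mean, sd)
    thr = mean + 2 * sd
    hubs = tuple(
        (str(region_names[i]), float(values[i]))
        for i in np.flatnonzero(values >= thr)
    )
    return HubSet(hubs, mean, sd)
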