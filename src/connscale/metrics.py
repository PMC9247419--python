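"""Binary graph metrics and degree-preserving null-model normalization.

Raw characteristic path length and clustering depend strongly on density
and degree sequence, so cross-species comparison uses values normalized by
the mean of the same metric over an ensemble of degree-preserved randomly
rewired reference networks (Maslov-Sneppen double-edge swaps; 1000
reference networks per connectome in the full analysis).  Normalization is
the ratio raw / null-mean.  Metrics are computed per hemisphere on the
intrahemispheric subnetwork.

Rewiring can disconnect a graph; path length therefore averages over
reachable pairs only and reports the unreachable fraction alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path


@dataclass
class NullModelConfig:
    n_reference: int = 1000
    swaps_per_edge: int = 10  # attempts per edge, not successful swaps
    seed: int = 0

    def __post_init__(self):
        if self.n_reference < 1 or self.swaps_per_edge < 1:
            raise ValueError("reference count and swap budget must be positive")


@dataclass
class MetricResult:
    metric: str
    raw: float
    null_mean: float
    null_sd: float
    normalized: float
    scope: str = ""
    n_nulls: int = 0

    def __post_init__(self):
        if self.null_sd < 0:
            raise ValueError("null SD must be non-negative")


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    a = (a > 0).astype(np.uint8)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0)
    return a


def characteristic_path_length(adjacency: np.ndarray) -> tuple[float, float]:
    """Mean shortest-path step count over reachable unordered node pairs.

    Returns ``(path_length, unreachable_fraction)``.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    if a.sum() == 0:
        raise ValueError("graph has no edges")
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    finite = np.isfinite(dv)
    unreachable = 1.0 - finite.mean()
    return float(dv[finite].mean()), float(unreachable)


def clustering_coefficient(adjacency: np.ndarray) -> float:
    """Mean over all nodes of (edges among neighbors) / (possible such edges).

    Nodes with degree < 2 contribute 0.
    """
    a = _check_adjacency(adjacency)
    if a.shape[0] < 3:
        raise ValueError("clustering needs at least 3 nodes")
    g = nx.from_numpy_array(a)
    return float(nx.average_clustering(g))


def rewire_degree_preserving(adjacency: np.ndarray, config: NullModelConfig) -> np.ndarray:
    """One Maslov-Sneppen rewired copy of a simple undirected graph.

    Performs ``swaps_per_edge × m`` double-edge swap attempts, rejecting
    any swap that would create a self-loop or multi-edge; the degree
    sequence is preserved exactly.  Deterministic for a given seed.
    """
    a = _check_adjacency(adjacency).astype(np.uint8).copy()
    edges = np.column_stack(np.nonzero(np.triu(a, 1)))
    m = len(edges)
    if m < 2:
        return a
    rng = np.random.default_rng(config.seed)
    attempts = config.swaps_per_edge * m
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y or u == y or v == x:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = sorted((u, x))
        edges[e2] = sorted((v, y))
    return a


def normalize_metric(raw: float, nulls: list[float], metric: str = "", scope: str = "") -> MetricResult:
    """Ratio normalization raw / mean(nulls), with the null moments recorded."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("at least one null value required")
    mean = float(nulls.mean())
    if mean == 0:
        raise ValueError("zero null mean: normalization undefined")
    return MetricResult(
        metric=metric,
        raw=float(raw),
        null_mean=mean,
        null_sd=float(nulls.std(ddof=0)),
        normalized=float(raw) / mean,
        scope=scope,
        n_nulls=int(nulls.size),
    )


def normalized_metrics(
    adjacency: np.ndarray, config: NullModelConfig, scope: str = ""
) -> dict[str, MetricResult]:
    """Path length and clustering normalized against a rewired ensemble."""
    raw_pl, _ = characteristic_path_length(adjacency)
    raw_cc = clustering_coefficient(adjacency)
    null_pl, null_cc = [], []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.n_reference):
        sub = NullModelConfig(
            n_reference=1,
            swaps_per_edge=config.swaps_per_edge,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        r = rewire_degree_preserving(adjacency, sub)
        pl, _ = characteristic_path_length(r)
        null_pl.append(pl)
        null_cc.append(clustering_coefficient(r))
    return {
        "path_length": normalize_metric(raw_pl, null_pl, "path_length", scope),
        "clustering": normalize_metric(raw_cc, null_cc, "clustering", scope),
    }


def hub_metrics(adjacency: np.ndarray) -> dict:
    """Degree, betweenness and the rich-club curve φ(k).

    Betweenness is the unnormalized pairwise count with equal-path
    splitting; φ(k) is the density of the subgraph on nodes of degree > k,
    reported for every realized degree k with at least 2 such nodes.
    """
    a = _check_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    degree = a.sum(axis=1).astype(int)
    betweenness = np.array(
        [nx.betweenness_centrality(g, normalized=False)[i] for i in range(a.shape[0])]
    )
    rich_club = {}
    for k in sorted(set(degree.tolist())):
        nodes = np.flatnonzero(degree > k)
        if len(nodes) < 2:
            continue
        sub = a[np.ix_(nodes, nodes)]
        possible = len(nodes) * (len(nodes) - 1) / 2
        rich_club[int(k)] = float(np.count_nonzero(np.triu(sub, 1)) / possible)
    pl, unreachable = characteristic_path_length(a) if a.sum() else (np.nan, 1.0)
    return {
        "degree": degree,
        "betweenness": betweenness,
        "rich_club": rich_club,
        "unreachable_fraction": unreachable,
    }
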