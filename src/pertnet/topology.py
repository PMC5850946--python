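"""Directed-network topology: global summaries and per-node centralities.

Conventions (the upstream tools this mirrors print these metrics without
formulas, so the exact definitions are fixed here):

* characteristic path length — mean shortest directed distance over ordered
  reachable pairs (s != t); unreachable pairs are excluded, not infinite.
* diameter / radius — max / min directed eccentricity over nodes that reach
  at least one other node; 0 for edgeless graphs.
* clustering coefficient, neighborhood connectivity, topological coefficient,
  shared-neighbor counts — computed on the undirected projection.
* closeness — harmonic: mean of 1/d(v, u) over the nodes u reachable from v,
  hence in [0, 1]; 0 for sinks.
* betweenness / stress — directed shortest-path counting, endpoints excluded,
  unnormalized.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .reconstruction import RegulatoryNetwork

__all__ = [
    "TopologySummary",
    "summarize",
    "node_metrics",
    "hub_extract",
    "HUB_OUT_DEGREE",
    "MAJOR_HUB_OUT_DEGREE",
]

#: Preset out-degree cutoffs for hub and major-hub extraction.
HUB_OUT_DEGREE = 10
MAJOR_HUB_OUT_DEGREE = 100


def _as_digraph(net) -> nx.DiGraph:
    return net.graph if isinstance(net, RegulatoryNetwork) else net


def _distances_and_counts(g: nx.DiGraph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances D and path counts S by BFS per source.

    D[i, j] = directed distance (np.inf if unreachable); S[i, j] = number of
    distinct shortest i->j paths (0 if unreachable).
    """
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [[index[w] for w in g.successors(v)] for v in nodes]
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for s in range(n):
        dist = D[s]
        sigma = S[s]
        dist[s] = 0.0
        sigma[s] = 1.0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if np.isinf(dist[w]):
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
    return D, S


@dataclass(frozen=True)
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_connected_components: int  # weakly connected
    diameter: float
    radius: float
    clustering_coefficient: float
    characteristic_path_length: float
    avg_neighbors: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(net) -> TopologySummary:
    """Global directed-topology summary of a regulatory network."""
    g = _as_digraph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    D, _ = _distances_and_counts(g, nodes)
    off = ~np.eye(len(nodes), dtype=bool)
    finite = np.isfinite(D) & off
    cpl = float(D[finite].mean()) if finite.any() else 0.0
    # eccentricity over nodes that reach at least one other node
    ecc = np.where(finite.any(axis=1), np.where(finite, D, -np.inf).max(axis=1), np.nan)
    ecc = ecc[~np.isnan(ecc)]
    und = g.to_undirected()
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_connected_components=nx.number_weakly_connected_components(g),
        diameter=float(ecc.max()) if ecc.size else 0.0,
        radius=float(ecc.min()) if ecc.size else 0.0,
        clustering_coefficient=float(nx.average_clustering(und)) if und.number_of_nodes() else 0.0,
        characteristic_path_length=cpl,
        avg_neighbors=float(np.mean([und.degree(v) for v in nodes])),
    )


def node_metrics(net) -> pd.DataFrame:
    """Per-node centralities and neighborhood statistics.

    Columns: in_degree, out_degree, betweenness, closeness, stress,
    neighborhood_connectivity, topological_coefficient, shared_neighbors_mean,
    shared_neighbors_max, isolated.
    """
    g = _as_digraph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    n = len(nodes)
    D, S = _distances_and_counts(g, nodes)
    finite = np.isfinite(D)

    # harmonic closeness over the out-reachable set
    inv = np.where(finite & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    reach = (finite & (D > 0)).sum(axis=1)
    closeness = np.divide(
        inv.sum(axis=1), reach, out=np.zeros(n), where=reach > 0
    )

    betweenness = np.zeros(n)
    stress = np.zeros(n)
    with np.errstate(invalid="ignore"):
        for v in range(n):
            through = D[:, v][:, None] + D[v, :][None, :]
            on = finite & (through == D)  # s->v->t lies on a shortest s->t path
            on[v, :] = False
            on[:, v] = False
            np.fill_diagonal(on, False)
            if not on.any():
                continue
            paths_via = S[:, v][:, None] * S[v, :][None, :]
            stress[v] = paths_via[on].sum()
            betweenness[v] = (paths_via[on] / S[on]).sum()

    und = g.to_undirected()
    A = nx.to_numpy_array(und, nodelist=nodes, dtype=float)
    deg = A.sum(axis=1)
    # neighborhood connectivity: mean undirected degree of neighbors
    nbr_conn = np.divide(A @ deg, deg, out=np.zeros(n), where=deg > 0)
    shared = A @ A  # shared-neighbor counts between node pairs
    np.fill_diagonal(shared, 0.0)
    # topological coefficient: mean over partners sharing >=1 neighbor of
    # (shared neighbors + 1 if adjacent) / degree
    J = shared + np.where(shared > 0, A, 0.0)
    partners = (shared > 0).sum(axis=1)
    tc = np.divide(
        np.where(shared > 0, J, 0.0).sum(axis=1),
        partners * np.where(deg > 0, deg, 1.0),
        out=np.zeros(n),
        where=(partners > 0) & (deg > 0),
    )
    return pd.DataFrame(
        {
            "in_degree": [g.in_degree(v) for v in nodes],
            "out_degree": [g.out_degree(v) for v in nodes],
            "betweenness": betweenness,
            "closeness": closeness,
            "stress": stress,
            "neighborhood_connectivity": nbr_conn,
            "topological_coefficient": tc,
            "shared_neighbors_mean": shared.sum(axis=1) / max(n - 1, 1),
            "shared_neighbors_max": shared.max(axis=1),  # diagonal already zeroed
            "isolated": deg == 0,
        },
        index=pd.Index(nodes, name="node"),
    )


def hub_extract(net, min_out_degree: int = HUB_OUT_DEGREE) -> list[str]:
    """Nodes with out-degree >= threshold, sorted by descending out-degree,
    ties by node id.  Presets: 10 (hubs) and 100 (major hubs)."""
    g = _as_digraph(net)
    hubs = [(v, g.out_degree(v)) for v in g.nodes if g.out_degree(v) >= min_out_degree]
    hubs.sort(key=lambda item: (-item[1], item[0]))
    return [v for v, _ in hubs]
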