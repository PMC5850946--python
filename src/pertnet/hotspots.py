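"""Expression-activated subnetwork ("hotspot") search.

Scores connected subnetworks of the regulatory network by the aggregate
response statistic z_A = sum(z_i) / sqrt(|A|) over member genes, where z_i is
a rank-inverse-normal transform of each gene's strongest consensus response
across perturbations, and greedily grows high-scoring modules from top-scoring
seed nodes.  Up to ``n_modules`` non-redundant modules (pairwise Jaccard
overlap <= ``overlap_threshold``) are returned, mirroring the active-modules
family of methods (module count 5 and overlap threshold 0.8 as presets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .consensus import ConsensusMatrix
from .reconstruction import RegulatoryNetwork

__all__ = [
    "HotspotParams",
    "HotspotModule",
    "node_activity_scores",
    "score_subnetwork",
    "search_modules",
    "calibrate_module_score",
]


@dataclass(frozen=True)
class HotspotParams:
    n_modules: int = 5
    overlap_threshold: float = 0.8
    search: str = "greedy"  # "greedy" or "local" (greedy + pruning pass)
    max_module_size: int = 50
    n_seed_candidates: int = 50
    n_random_restarts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if self.search not in ("greedy", "local"):
            raise ValueError("search must be 'greedy' or 'local'")
        if self.max_module_size < 1:
            raise ValueError("max_module_size must be >= 1")


@dataclass(frozen=True)
class HotspotModule:
    nodes: frozenset
    score: float
    seed_node: str

    def jaccard(self, other: "HotspotModule | frozenset") -> float:
        nodes = other.nodes if isinstance(other, HotspotModule) else frozenset(other)
        union = self.nodes | nodes
        return len(self.nodes & nodes) / len(union) if union else 0.0


def node_activity_scores(
    consensus: ConsensusMatrix, nodes=None
) -> tuple[pd.Series, list]:
    """Per-gene activity z-scores on a standard-normal scale.

    The raw statistic is each gene's maximum absolute consensus differential
    value across perturbations; it is mapped through a rank-inverse-normal
    transform (offset (r - 0.5)/N) across the study genes, so any monotone
    transform of the raw values leaves the scores unchanged.  Requested nodes
    absent from the study get score 0 and are reported as missing.
    """
    raw = np.abs(consensus.values).max(axis=1)
    ranks = rankdata(raw)  # average ranks for ties
    z = norm.ppf((ranks - 0.5) / len(ranks))
    scores = pd.Series(z, index=consensus.gene_ids, name="activity_z")
    if nodes is None:
        return scores, []
    nodes = list(nodes)
    missing = [v for v in nodes if v not in scores.index]
    out = scores.reindex(nodes, fill_value=0.0)
    out[missing] = 0.0
    return out, missing


def score_subnetwork(nodes, scores: pd.Series) -> float:
    """Aggregate module score z_A = sum(z_i) / sqrt(k)."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("cannot score an empty node set")
    return float(scores.loc[nodes].sum() / math.sqrt(len(nodes)))


def _grow_greedy(
    und: nx.Graph,
    scores: pd.Series,
    seed_node,
    params: HotspotParams,
    tie_attr: pd.Series | None,
) -> frozenset:
    module = {seed_node}
    total = float(scores.loc[seed_node])
    current = total
    frontier = set(und.neighbors(seed_node))
    while frontier and len(module) < params.max_module_size:
        best, best_score = None, current
        for cand in frontier:
            cand_score = (total + float(scores.loc[cand])) / math.sqrt(len(module) + 1)
            better = cand_score > best_score + 1e-12
            tied = best is not None and abs(cand_score - best_score) <= 1e-12
            if tied:  # deterministic tie-break: attribute weight, then node id
                if tie_attr is not None:
                    better = tie_attr.get(cand, 0.0) > tie_attr.get(best, 0.0) or (
                        tie_attr.get(cand, 0.0) == tie_attr.get(best, 0.0)
                        and str(cand) < str(best)
                    )
                else:
                    better = str(cand) < str(best)
            if better:
                best, best_score = cand, cand_score
        if best is None:
            break
        module.add(best)
        total += float(scores.loc[best])
        current = best_score
        frontier |= set(und.neighbors(best))
        frontier -= module
    return frozenset(module)


def _prune_local(und: nx.Graph, scores: pd.Series, module: frozenset, seed_node) -> frozenset:
    """Local refinement: drop nodes whose removal keeps the module connected
    and raises the aggregate score."""
    nodes = set(module)
    improved = True
    while improved and len(nodes) > 1:
        improved = False
        current = score_subnetwork(nodes, scores)
        for v in sorted(nodes, key=lambda x: (scores.loc[x], str(x))):
            if v == seed_node:
                continue
            trial = nodes - {v}
            if not nx.is_connected(und.subgraph(trial)):
                continue
            if score_subnetwork(trial, scores) > current + 1e-12:
                nodes = trial
                improved = True
                break
    return frozenset(nodes)


def search_modules(
    net: RegulatoryNetwork | nx.DiGraph,
    scores: pd.Series,
    params: HotspotParams = HotspotParams(),
    tie_attr: pd.Series | None = None,
) -> list[HotspotModule]:
    """Greedy high-scoring module search with overlap filtering.

    Seeds are the top-scoring nodes (optionally plus random restarts drawn
    with ``params.seed``); each seed grows greedily by the neighbor that most
    increases z_A until no improvement or ``max_module_size``.  Candidates are
    ranked by score; a candidate overlapping an accepted module with Jaccard
    index > ``overlap_threshold`` is discarded.  ``tie_attr`` (e.g. node
    betweenness or neighborhood connectivity) breaks ties between equal-gain
    neighbor additions.
    """
    g = net.graph if isinstance(net, RegulatoryNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    und = g.to_undirected()
    scores = scores.reindex(list(und.nodes), fill_value=0.0)
    ranked = sorted(und.nodes, key=lambda v: (-scores.loc[v], str(v)))
    seeds = ranked[: params.n_seed_candidates]
    if params.n_random_restarts > 0:
        rng = np.random.default_rng(params.seed)
        extras = rng.choice(len(ranked), size=min(params.n_random_restarts, len(ranked)), replace=False)
        seeds = list(dict.fromkeys(seeds + [ranked[i] for i in extras]))

    candidates: list[HotspotModule] = []
    seen: set[frozenset] = set()
    for s in seeds:
        module = _grow_greedy(und, scores, s, params, tie_attr)
        if params.search == "local":
            module = _prune_local(und, scores, module, s)
        if module in seen:
            continue
        seen.add(module)
        candidates.append(
            HotspotModule(nodes=module, score=score_subnetwork(module, scores), seed_node=s)
        )
    candidates.sort(key=lambda m: (-m.score, str(m.seed_node)))
    accepted: list[HotspotModule] = []
    for cand in candidates:
        if len(accepted) >= params.n_modules:
            break
        if any(cand.jaccard(acc) > params.overlap_threshold for acc in accepted):
            continue
        accepted.append(cand)
    return accepted


def calibrate_module_score(
    scores: pd.Series, k: int, n_samples: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo background for z_A: mean and sd of the aggregate score of
    random size-k node sets (connectivity ignored).  Optional; not applied to
    module scores by default."""
    if k < 1 or k > len(scores):
        raise ValueError("k must be in [1, n_nodes]")
    rng = np.random.default_rng(seed)
    vals = scores.to_numpy()
    draws = np.array(
        [vals[rng.choice(len(vals), size=k, replace=False)].sum() for _ in range(n_samples)]
    ) / math.sqrt(k)
    return float(draws.mean()), float(draws.std(ddof=1))
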