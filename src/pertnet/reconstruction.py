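"""Signed directed network reconstruction from thresholded differential calls.

A gene is called regulated by a perturbation when its standardized
differential value reaches the threshold theta (default 4, i.e. "4-fold" on
the standardized scale) in at least one qualifying biological replicate; the
edge runs from the perturbed gene to the responding gene with the sign of the
largest-magnitude supporting value.  An optional sign-aware transitive
simplification removes edges already explained by an indirect sign-consistent
path.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .profile_io import BiologicalReplicateMatrix

__all__ = [
    "ReconstructionParams",
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "call_regulations",
    "build_network",
    "simplify_network",
    "reconstruct",
]

RULES = ("any_biological_replicate", "selected_replicate_only")


@dataclass(frozen=True)
class ReconstructionParams:
    theta: float = 4.0
    rule: str = "any_biological_replicate"
    simplify: bool = False
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be > 0")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition
    magnitude: float  # max |differential value| supporting the call
    support: int  # number of qualifying biological replicates passing theta
    conflict: bool = False  # replicates passed theta with both signs


def call_regulations(
    b: BiologicalReplicateMatrix,
    params: ReconstructionParams,
    selected_index: int | None = None,
) -> list[RegulatoryEdge]:
    """Call regulated genes for one perturbation.

    Under ``any_biological_replicate`` every biological-replicate column may
    support a call; under ``selected_replicate_only`` only the consensus
    replicate (``selected_index``) is examined.  The edge sign follows the
    largest-|value| supporting replicate; opposite-sign passes are recorded as
    a conflict.
    """
    if params.rule == "selected_replicate_only":
        if selected_index is None:
            raise ValueError("selected_replicate_only rule needs selected_index")
        X = b.values[:, [selected_index]]
    else:
        X = b.values
    edges: list[RegulatoryEdge] = []
    passing = np.abs(X) >= params.theta
    for g in np.flatnonzero(passing.any(axis=1)):
        gene = b.gene_ids[g]
        if params.exclude_self and gene == b.perturbed_gene:
            continue
        vals = X[g, passing[g]]
        top = vals[np.argmax(np.abs(vals))]
        edges.append(
            RegulatoryEdge(
                source=b.perturbed_gene,
                target=gene,
                sign=1 if top > 0 else -1,
                magnitude=float(np.abs(vals).max()),
                support=int(passing[g].sum()),
                conflict=bool((vals > 0).any() and (vals < 0).any()),
            )
        )
    return edges


@dataclass
class RegulatoryNetwork:
    """Signed directed regulatory network over gene nodes.

    Backed by a :class:`networkx.DiGraph` whose edges carry ``sign``,
    ``magnitude``, ``support`` and ``conflict`` attributes.  ``perturbed_genes``
    are always nodes, even when they called no edges.
    """

    graph: nx.DiGraph
    perturbed_genes: frozenset = frozenset()
    params: ReconstructionParams | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def signed_edges(self) -> set[tuple[str, str, int]]:
        return {(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)}

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "sign": d["sign"],
                "magnitude": d.get("magnitude", np.nan),
                "support": d.get("support", 1),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "sign", "magnitude", "support"]
        ).sort_values(["source", "target"], ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)

    def write_sif(self, path: str | Path) -> None:
        """Simple-interaction-format export: source activates|inhibits target."""
        with open(path, "w") as fh:
            for u, v, d in sorted(self.graph.edges(data=True)):
                rel = "activates" if d["sign"] > 0 else "inhibits"
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in sorted(self.graph.nodes):
                if self.graph.degree(node) == 0:
                    fh.write(f"{node}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, perturbed_genes: Iterable[str] | None = None
    ) -> "RegulatoryNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.DiGraph()
        for r in df.itertuples():
            g.add_edge(
                r.source,
                r.target,
                sign=int(r.sign),
                magnitude=float(getattr(r, "magnitude", np.nan)),
                support=int(getattr(r, "support", 1)),
                conflict=False,
            )
        perturbed = (
            frozenset(perturbed_genes)
            if perturbed_genes is not None
            else frozenset(df["source"])
        )
        g.add_nodes_from(perturbed)
        return cls(graph=g, perturbed_genes=perturbed)


def build_network(
    calls: Sequence[Sequence[RegulatoryEdge]],
    perturbed_genes: Iterable[str] = (),
    params: ReconstructionParams | None = None,
) -> RegulatoryNetwork:
    """Union of per-perturbation calls into one network.

    Duplicate (source, target) pairs — e.g. the same perturbation assayed at
    two time points — merge keeping the larger magnitude; a sign disagreement
    between merged records resolves to the larger-magnitude sign and is
    recorded on the edge.
    """
    g = nx.DiGraph()
    perturbed = set(perturbed_genes)
    for edge_list in calls:
        for e in edge_list:
            perturbed.add(e.source)
            if g.has_edge(e.source, e.target):
                d = g[e.source][e.target]
                conflict = d["conflict"] or e.conflict or d["sign"] != e.sign
                if e.magnitude > d["magnitude"]:
                    d.update(sign=e.sign, magnitude=e.magnitude)
                d["support"] = max(d["support"], e.support)
                d["conflict"] = conflict
            else:
                g.add_edge(
                    e.source,
                    e.target,
                    sign=e.sign,
                    magnitude=e.magnitude,
                    support=e.support,
                    conflict=e.conflict,
                )
    g.add_nodes_from(perturbed)
    net = RegulatoryNetwork(
        graph=g, perturbed_genes=frozenset(perturbed), params=params
    )
    edge_repr = "".join(f"{u}>{v}:{d['sign']};" for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])))
    net.provenance = {
        "params": params,
        "study_hash": hashlib.sha256(edge_repr.encode()).hexdigest()[:16],
    }
    return net


def _signed_reachable(
    g: nx.DiGraph, source: str, target: str, sign: int, skip: tuple[str, str]
) -> bool:
    """True if a directed walk source~>target with sign product ``sign`` exists
    that avoids the single edge ``skip``.  BFS over (node, sign) states; since
    the graph is simple and ``skip`` is exactly (source, target), any such walk
    has length >= 2."""
    seen = {(source, 1)}
    queue = deque([(source, 1)])
    while queue:
        node, s = queue.popleft()
        for _, nxt, d in g.out_edges(node, data=True):
            if (node, nxt) == skip:
                continue
            state = (nxt, s * d["sign"])
            if state in seen:
                continue
            if nxt == target and state[1] == sign:
                return True
            seen.add(state)
            queue.append(state)
    return False


def simplify_network(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Sign-aware transitive simplification.

    Removes each edge (u, w, s) that is already explained by an indirect
    directed path u ~> w of length >= 2 whose edge-sign product equals s,
    using only edges still present at the time of the check.  Because an edge
    is only dropped when a sign-equal explanation survives without it, signed
    reachability is exactly preserved, the result is idempotent, and edges on
    cycles whose only explanation is themselves are retained.  On acyclic
    networks the result equals the classic (sign-refined) transitive
    reduction regardless of processing order.
    """
    g = net.graph.copy()
    for u, w in sorted(net.graph.edges):
        s = g[u][w]["sign"]
        if _signed_reachable(g, u, w, s, skip=(u, w)):
            g.remove_edge(u, w)
    out = RegulatoryNetwork(
        graph=g,
        perturbed_genes=net.perturbed_genes,
        params=replace(net.params, simplify=True) if net.params else None,
        provenance=dict(net.provenance, simplified=True),
    )
    return out


def reconstruct(
    matrices: Sequence[BiologicalReplicateMatrix],
    params: ReconstructionParams = ReconstructionParams(),
    selected_indices: Sequence[int] | None = None,
) -> RegulatoryNetwork:
    """Threshold, build and (optionally) simplify in one call."""
    calls = []
    for j, b in enumerate(matrices):
        k = selected_indices[j] if selected_indices is not None else None
        calls.append(call_regulations(b, params, selected_index=k))
    net = build_network(calls, perturbed_genes=[b.perturbed_gene for b in matrices], params=params)
    if params.simplify:
        net = simplify_network(net)
    return net
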