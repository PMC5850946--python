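"""Gene-set over-representation and pathway cross-talk analysis.

Enrichment of a gene query against a named collection of gene sets (GMT
format) uses the upper-tail hypergeometric test with Benjamini-Hochberg FDR
control (cutoff 0.05 by convention); cross-talk between two pathways is
quantified as the signed regulatory edges running from one set's genes to the
other's, with genes shared by both sets reported separately rather than
silently double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .reconstruction import RegulatoryNetwork

__all__ = [
    "GeneSetCollection",
    "hypergeometric_enrichment",
    "bh_adjust",
    "crosstalk_edges",
    "crosstalk_report",
    "module_enrichment_profile",
    "DEFAULT_FDR",
]

DEFAULT_FDR = 0.05

ENRICHMENT_COLUMNS = [
    "set_name",
    "overlap",
    "set_size",
    "query_size",
    "universe_size",
    "p_value",
    "fdr",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        if len(self.universe) == 0:
            raise ValueError("empty universe")
        restricted = {}
        for name, members in self.sets.items():
            restricted[name] = frozenset(members) & self.universe
        object.__setattr__(self, "sets", restricted)

    @classmethod
    def from_gmt(
        cls, path: str | Path, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        """Read a GMT file (one set per line: name, description, members)."""
        import gseapy  # heavy import; only needed for file-based collections

        sets = {name: frozenset(genes) for name, genes in gseapy.read_gmt(str(path)).items()}
        if universe is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets=sets, universe=frozenset(universe))

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\tna\t{members}\n")

    def __len__(self) -> int:
        return len(self.sets)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Query members outside the universe are dropped with a warning.  Returns a
    DataFrame with exact p-values and BH-adjusted FDR, sorted by FDR then
    p-value.
    """
    query = frozenset(query)
    outside = query - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query = query & collection.universe
    M = len(collection.universe)
    N = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        k = len(query & members)
        n = len(members)
        # P(overlap >= k) for overlap ~ Hypergeom(M, n, N)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append((name, k, n, N, M, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df["fdr"] = bh_adjust(df["p_value"]) if len(df) else []
    return df.sort_values(["fdr", "p_value", "set_name"], ignore_index=True)


@dataclass(frozen=True)
class CrosstalkEntry:
    source_set: str
    target_set: str
    n_edges: int
    n_activating: int
    n_inhibiting: int
    n_shared_genes: int  # |S ∩ T|
    n_edges_from_shared: int  # edges whose source gene belongs to both sets


def crosstalk_edges(
    net: RegulatoryNetwork,
    source_set: Iterable[str],
    target_set: Iterable[str],
    source_name: str = "S",
    target_name: str = "T",
) -> CrosstalkEntry:
    """Count signed regulatory edges running from one gene set into another.

    Every edge u -> v with u in S and v in T counts; edges whose source lies
    in S ∩ T are additionally tallied in ``n_edges_from_shared`` so that genes
    common to both pathways are visible rather than double-counted silently.
    """
    S = frozenset(source_set)
    T = frozenset(target_set)
    g = net.graph if isinstance(net, RegulatoryNetwork) else net
    n_edges = n_act = n_inh = n_shared_src = 0
    for u, v, d in g.edges(data=True):
        if u in S and v in T:
            n_edges += 1
            if d.get("sign", 1) > 0:
                n_act += 1
            else:
                n_inh += 1
            if u in T:
                n_shared_src += 1
    return CrosstalkEntry(
        source_set=source_name,
        target_set=target_name,
        n_edges=n_edges,
        n_activating=n_act,
        n_inhibiting=n_inh,
        n_shared_genes=len(S & T),
        n_edges_from_shared=n_shared_src,
    )


def crosstalk_report(
    net: RegulatoryNetwork,
    collection: GeneSetCollection,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Cross-talk counts for every ordered pair of sets (or the given pairs)."""
    names = sorted(collection.sets)
    if pairs is None:
        pairs = [(a, b) for a in names for b in names if a != b]
    rows = []
    for a, b in pairs:
        if a not in collection.sets or b not in collection.sets:
            raise KeyError(f"unknown gene set in pair ({a!r}, {b!r})")
        entry = crosstalk_edges(
            net, collection.sets[a], collection.sets[b], source_name=a, target_name=b
        )
        rows.append(entry.__dict__)
    return pd.DataFrame(rows)


def module_enrichment_profile(
    modules: Sequence[Iterable[str]],
    collection: GeneSetCollection,
    fdr_cutoff: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Enriched sets (FDR <= cutoff) per module, with overlap gene counts —
    the table behind a per-module enrichment bar plot."""
    if len(modules) == 0:
        raise ValueError("no modules given")
    frames = []
    for i, module in enumerate(modules):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = hypergeometric_enrichment(module, collection)
        df = df[df["fdr"] <= fdr_cutoff].copy()
        df.insert(0, "module", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
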