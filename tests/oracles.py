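"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, closed forms) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- averaging


def mean_by_loops(block: np.ndarray) -> np.ndarray:
    """Elementwise-summation mean over technical replicates."""
    n, q = block.shape
    out = np.zeros(n)
    for g in range(n):
        acc = 0.0
        for l in range(q):
            acc += block[g, l]
        out[g] = acc / q
    return out


def center_scale_by_loops(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-pass per-row center/scale with sample sd (m-1 denominator)."""
    n, m = X.shape
    Z = np.zeros_like(X, dtype=float)
    mu = np.zeros(n)
    sd = np.zeros(n)
    for g in range(n):
        mu[g] = sum(X[g]) / m
        ss = sum((x - mu[g]) ** 2 for x in X[g])
        sd[g] = math.sqrt(ss / (m - 1)) if m > 1 else 0.0
        for k in range(m):
            Z[g, k] = (X[g, k] - mu[g]) / sd[g] if sd[g] > 0 else 0.0
    return Z, mu, sd


# ---------------------------------------------------------------------- PCA


def pc1_power_iteration(Z: np.ndarray, n_iter: int = 2000) -> np.ndarray:
    """PC1 scores by power iteration on the replicate covariance matrix."""
    n, m = Z.shape
    mu = Z.mean(axis=0)
    C = np.zeros((m, m))
    Xc = Z - mu
    for a in range(m):
        for b in range(m):
            C[a, b] = float(np.dot(Xc[:, a], Xc[:, b])) / (n - 1)
    # random start: the all-ones direction is structurally a null eigenvector
    # of row-centered data, so a uniform start would be degenerate
    v = np.random.default_rng(12345).normal(size=m)
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        w = C @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        v = w / norm
    return Xc @ v


def pearson_by_hand(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xm @ xm)) * math.sqrt(float(ym @ ym))
    return float(xm @ ym) / denom if denom > 0 else float("nan")


# ------------------------------------------------------------ thresholding


def call_edges_by_scan(
    gene_ids, perturbed_gene, X: np.ndarray, theta: float, exclude_self=True
):
    """Exhaustive scan over genes/replicates returning (target, sign,
    magnitude, support) tuples."""
    out = []
    for g, gene in enumerate(gene_ids):
        if exclude_self and gene == perturbed_gene:
            continue
        passing = [v for v in X[g] if abs(v) >= theta]
        if not passing:
            continue
        top = max(passing, key=abs)
        out.append((gene, 1 if top > 0 else -1, max(abs(v) for v in passing), len(passing)))
    return out


# ----------------------------------------------------- signed graph algebra


def signed_paths(edges: dict, u, w, max_len=None):
    """All simple directed paths u -> w with their edge-sign products.

    ``edges`` maps (a, b) -> sign.  Yields (path tuple, sign product).
    """
    adj = {}
    for (a, b), s in edges.items():
        adj.setdefault(a, []).append((b, s))
    stack = [((u,), 1)]
    while stack:
        path, sign = stack.pop()
        node = path[-1]
        if node == w and len(path) > 1:
            yield path, sign
            continue
        if max_len is not None and len(path) > max_len:
            continue
        for nxt, s in adj.get(node, []):
            if nxt in path:
                continue
            stack.append((path + (nxt,), sign * s))


def transitive_reduction_by_paths(edges: dict) -> dict:
    """Oracle for acyclic signed networks: drop (u, w, s) iff some simple
    path u -> w of length >= 2 in the ORIGINAL graph has sign product s."""
    keep = {}
    for (u, w), s in edges.items():
        rest = {k: v for k, v in edges.items() if k != (u, w)}
        redundant = any(
            sign == s and len(path) >= 3 for path, sign in signed_paths(rest, u, w)
        )
        if not redundant:
            keep[(u, w)] = s
    return keep


def signed_closure(nodes, edges: dict) -> set:
    """Signed reachability closure by boolean fixpoint iteration.

    Returns the set of (u, w, sign) with a directed walk u -> w (length >= 1)
    of that sign product.
    """
    reach = {(u, w, s) for (u, w), s in edges.items()}
    changed = True
    while changed:
        changed = False
        for (a, b, s1) in list(reach):
            for (c, d, s2) in list(reach):
                if b == c and (a, d, s1 * s2) not in reach:
                    reach.add((a, d, s1 * s2))
                    changed = True
    return reach


# --------------------------------------------------------------- topology


def floyd_warshall(nodes, edges) -> dict:
    """Directed unit-weight all-pairs distances; inf when unreachable."""
    dist = {(a, b): math.inf for a in nodes for b in nodes}
    for a in nodes:
        dist[(a, a)] = 0
    for a, b in edges:
        dist[(a, b)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def all_shortest_paths(nodes, edges, dist):
    """Every shortest simple path per ordered pair, by DFS enumeration."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    paths = {}
    for s in nodes:
        for t in nodes:
            if s == t or math.isinf(dist[(s, t)]):
                continue
            found = []
            stack = [(s,)]
            while stack:
                path = stack.pop()
                node = path[-1]
                if node == t:
                    if len(path) - 1 == dist[(s, t)]:
                        found.append(path)
                    continue
                if len(path) - 1 >= dist[(s, t)]:
                    continue
                for nxt in adj.get(node, []):
                    if nxt not in path:
                        stack.append(path + (nxt,))
            paths[(s, t)] = found
    return paths


def topology_by_brute_force(nodes, edges):
    """Global summary + per-node metrics for a small digraph, from scratch."""
    nodes = sorted(nodes)
    dist = floyd_warshall(nodes, edges)
    paths = all_shortest_paths(nodes, edges, dist)

    finite = [
        dist[(a, b)] for a in nodes for b in nodes if a != b and math.isfinite(dist[(a, b)])
    ]
    cpl = sum(finite) / len(finite) if finite else 0.0
    eccs = []
    for a in nodes:
        ds = [dist[(a, b)] for b in nodes if b != a and math.isfinite(dist[(a, b)])]
        if ds:
            eccs.append(max(ds))
    diameter = max(eccs) if eccs else 0.0
    radius = min(eccs) if eccs else 0.0

    und = {frozenset((a, b)) for a, b in edges if a != b}
    nbrs = {v: {next(iter(e - {v})) for e in und if v in e} for v in nodes}
    avg_neighbors = sum(len(nbrs[v]) for v in nodes) / len(nodes)

    clustering = {}
    for v in nodes:
        k = len(nbrs[v])
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(
            1
            for a, b in itertools.combinations(sorted(nbrs[v]), 2)
            if frozenset((a, b)) in und
        )
        clustering[v] = 2.0 * links / (k * (k - 1))
    mean_clustering = sum(clustering.values()) / len(nodes)

    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for (s, t), plist in paths.items():
        if not plist:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in plist if v in p)
            if through:
                stress[v] += through
                betweenness[v] += through / len(plist)

    closeness = {}
    for v in nodes:
        reach = [dist[(v, u)] for u in nodes if u != v and math.isfinite(dist[(v, u)])]
        closeness[v] = sum(1.0 / d for d in reach) / len(reach) if reach else 0.0

    nbr_conn = {
        v: (sum(len(nbrs[u]) for u in nbrs[v]) / len(nbrs[v]) if nbrs[v] else 0.0)
        for v in nodes
    }

    tc = {}
    shared_mean = {}
    shared_max = {}
    for v in nodes:
        shared = {
            u: len(nbrs[v] & nbrs[u]) for u in nodes if u != v
        }
        vals = [
            (shared[u] + (1 if frozenset((u, v)) in und else 0)) / len(nbrs[v])
            for u in nodes
            if u != v and shared[u] > 0
        ]
        tc[v] = sum(vals) / len(vals) if vals and nbrs[v] else 0.0
        shared_mean[v] = sum(shared.values()) / max(len(nodes) - 1, 1)
        shared_max[v] = max(shared.values()) if shared else 0.0

    return {
        "cpl": cpl,
        "diameter": diameter,
        "radius": radius,
        "avg_neighbors": avg_neighbors,
        "clustering": mean_clustering,
        "betweenness": betweenness,
        "stress": stress,
        "closeness": closeness,
        "neighborhood_connectivity": nbr_conn,
        "topological_coefficient": tc,
        "shared_neighbors_mean": shared_mean,
        "shared_neighbors_max": shared_max,
    }


# -------------------------------------------------------------- enrichment


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """Exact P(overlap >= k) by combinatorial summation."""
    total = math.comb(M, N)
    acc = 0
    for i in range(k, min(n, N) + 1):
        acc += math.comb(n, i) * math.comb(M - n, N - i)
    return acc / total


def bh_step_up(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the textbook recipe."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
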