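"""Thresholded co-expression networks and module detection.

Genes are connected when the Pearson correlation of their expression
profiles across donors exceeds a hard threshold (default r > 0.6, strict);
unconnected genes are removed. Modules are found by an agglomerative
scheme driven by the edge clustering coefficient (ECC), a triangle-density
score: edges are processed from densest to sparsest, merging clusters
until both sides are self-contained modules (more internal than outgoing
edge ends). Small clusters are discarded.
"""

from __future__ import annotations

import warnings
import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["build_network", "edge_clustering_coefficient", "detect_modules"]


def build_network(
    expr: pd.DataFrame,
    r_threshold: float = 0.6,
    ev: pd.Series | None = None,
) -> nx.Graph:
    """Co-expression network over a gene set.

    Parameters
    ----------
    expr
        Gene x sample expression matrix (rows = the gene set).
    r_threshold
        Edge (g, h) exists iff Pearson r(g, h) > r_threshold (strict).
    ev
        Optional per-gene variability scores stored as the ``ev`` node
        attribute (used for node sizing in exports).

    Constant gene rows have undefined correlation and are excluded with a
    warning. Isolated nodes are removed.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes to build a network")
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples to estimate correlations")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) with undefined correlation"
        )
    genes = expr.index[~constant]
    vals = vals[~constant]
    corr = np.corrcoef(vals)
    g = nx.Graph()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = corr[iu, ju] > r_threshold
    for i, j, r in zip(iu[keep], ju[keep], corr[iu, ju][keep]):
        g.add_edge(genes[i], genes[j], r=float(r))
    if ev is not None:
        for node in g.nodes:
            g.nodes[node]["ev"] = float(ev.get(node, np.nan))
    return g


def edge_clustering_coefficient(g: nx.Graph) -> dict:
    """ECC(u, v) = (triangles on the edge + 1) / min(deg_u - 1, deg_v - 1).

    When either endpoint has degree <= 1 the denominator degenerates and
    the score is triangles + 1.
    """
    ecc = {}
    for u, v in g.edges:
        tri = len(set(g[u]) & set(g[v]))
        denom = min(g.degree[u] - 1, g.degree[v] - 1)
        ecc[(u, v)] = float(tri + 1) if denom <= 0 else (tri + 1) / denom
    return ecc


class _Clusters:
    """Union-find over nodes with internal-edge bookkeeping."""

    def __init__(self, g: nx.Graph):
        self.g = g
        self.members = {n: {n} for n in g.nodes}
        self.parent = {n: n for n in g.nodes}
        self.internal = {n: 0 for n in g.nodes}

    def find(self, n):
        while self.parent[n] != n:
            self.parent[n] = self.parent[self.parent[n]]
            n = self.parent[n]
        return n

    def is_module(self, root) -> bool:
        """A cluster is a module when its nodes have more internal than
        outgoing edge ends: 2 * m_in > m_out."""
        m_in = self.internal[root]
        deg_sum = sum(self.g.degree[n] for n in self.members[root])
        m_out = deg_sum - 2 * m_in
        return 2 * m_in > m_out

    def merge(self, ra, rb):
        if len(self.members[ra]) < len(self.members[rb]):
            ra, rb = rb, ra
        between = 0
        for n in self.members[rb]:
            between += sum(1 for nb in self.g[n] if self.find(nb) == ra)
        self.members[ra] |= self.members[rb]
        self.internal[ra] += self.internal[rb] + between
        self.parent[rb] = ra
        del self.members[rb], self.internal[rb]


def detect_modules(
    g: nx.Graph,
    min_size: int = 5,
    method: str = "ecc",
) -> list[set]:
    """Detect network modules.

    ``method='ecc'`` runs the ECC-ranked agglomeration: edges are visited
    in descending ECC order (ties broken by edge id for determinism) and
    the endpoint clusters merged unless both already qualify as modules —
    so dense cores lock before sparse bridges are reached.
    ``method='components'`` simply returns connected components. Clusters
    smaller than ``min_size`` are discarded. Module node sets are disjoint.
    """
    if g.number_of_nodes() == 0:
        return []
    if method == "components":
        comps = [set(c) for c in nx.connected_components(g)]
    elif method == "ecc":
        ecc = edge_clustering_coefficient(g)
        ordered = sorted(ecc, key=lambda e: (-ecc[e], str(e[0]), str(e[1])))
        clusters = _Clusters(g)
        for u, v in ordered:
            ru, rv = clusters.find(u), clusters.find(v)
            if ru == rv:
                continue  # edge already internal (counted at merge time)
            if clusters.is_module(ru) and clusters.is_module(rv):
                continue
            clusters.merge(ru, rv)
        comps = list(clusters.members.values())
    else:
        raise ValueError("method must be 'ecc' or 'components'")
    modules = [c for c in comps if len(c) >= min_size]
    modules.sort(key=lambda c: (-len(c), min(map(str, c))))
    return modules
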