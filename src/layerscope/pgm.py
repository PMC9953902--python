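"""Decomposable Gaussian graphical models over genes.

The network is built in two steps: (1) the spanning tree that maximizes the
Gaussian likelihood — equivalently the maximum-weight spanning tree under
pairwise mutual information ``MI = -0.5 * ln(1 - rho^2)`` (Chow–Liu); (2) a
greedy forward search that adds edges one at a time, keeping the graph
chordal (decomposable) and accepting only edges that lower the Bayesian
Information Criterion.  The resulting network is cut into connected
"functional node" branches whose per-sample mean expression serves as a
node activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "AssociationMatrix", "DecomposableGraph", "FunctionalNode",
    "pairwise_association", "likelihood_spanning_tree", "is_decomposable",
    "forward_edge_search", "split_into_branches", "node_activity",
    "node_activity_matrix",
]

MI_CAP = 0.5 * math.log(1e12)  # MI at |rho| = 1 - 5e-13; documented clamp


@dataclass
class AssociationMatrix:
    """Pairwise Pearson correlation and Gaussian mutual information (nats)."""

    gene_ids: list
    rho: np.ndarray
    mi: np.ndarray

    def mi_of(self, u, v) -> float:
        i, j = self.gene_ids.index(u), self.gene_ids.index(v)
        return float(self.mi[i, j])


@dataclass
class DecomposableGraph:
    """Chordal graph over genes with junction-tree bookkeeping and BIC."""

    graph: nx.Graph
    n: int                       # samples behind the fitted covariance
    bic: float = math.nan
    cliques: list = field(default_factory=list)
    separators: list = field(default_factory=list)   # with multiplicities
    bic_path: list = field(default_factory=list)     # BIC after each accepted edge

    @property
    def vertices(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def refresh_decomposition(self) -> None:
        self.cliques, self.separators = junction_tree_decomposition(self.graph)


@dataclass
class FunctionalNode:
    """A branch of the network: member genes plus an optional annotated core."""

    label: str
    genes: list
    main_function_genes: list | None = None


def pairwise_association(m: ExpressionMatrix) -> AssociationMatrix:
    """Pearson correlation and Gaussian MI for every gene pair."""
    x = m.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = x.std(axis=1)
    zero = [g for g, s in zip(m.gene_ids, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance genes: {zero[:5]}")
    rho = np.corrcoef(x)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log1p(-np.square(rho))
    mi = np.minimum(mi, MI_CAP)
    np.fill_diagonal(mi, 0.0)
    return AssociationMatrix(list(m.gene_ids), rho, mi)


def likelihood_spanning_tree(assoc: AssociationMatrix) -> DecomposableGraph:
    """Maximum-likelihood spanning tree = max-weight tree under MI weights.

    Kruskal with an explicit (-MI, u, v) sort so ties resolve to the
    lexicographically smallest edge, independent of input order.
    """
    genes = assoc.gene_ids
    p = len(genes)
    if p < 2:
        raise ValueError("need at least 2 genes for a spanning tree")
    order = sorted(
        ((i, j) for i in range(p) for j in range(i + 1, p)),
        key=lambda e: (-assoc.mi[e[0], e[1]],
                       min(genes[e[0]], genes[e[1]]),
                       max(genes[e[0]], genes[e[1]])))
    uf = nx.utils.UnionFind(genes)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j in order:
        u, v = genes[i], genes[j]
        if uf[u] != uf[v]:
            uf.union(u, v)
            g.add_edge(u, v, mi=float(assoc.mi[i, j]))
            if g.number_of_edges() == p - 1:
                break
    out = DecomposableGraph(g, n=0)
    out.refresh_decomposition()
    return out


def maximum_cardinality_search(g: nx.Graph):
    """MCS ordering and chordality verdict.

    Returns ``(order, chordal)`` where ``order`` lists vertices in visit
    order and ``chordal`` is True iff the reverse of ``order`` is a perfect
    elimination ordering.  Ties in cardinality break lexicographically.
    """
    nodes = sorted(g.nodes)
    weight = {v: 0 for v in nodes}
    visited: dict = {}
    order = []
    for step in range(len(nodes)):
        v = max((u for u in nodes if u not in visited),
                key=lambda u: (weight[u], _neg_key(u)))
        visited[v] = step
        order.append(v)
        # earlier-visited neighbors must form a clique for a PEO
        earlier = [u for u in g.neighbors(v) if u in visited and u != v]
        if earlier:
            last = max(earlier, key=visited.__getitem__)
            rest = set(earlier) - {last}
            if not rest <= set(g.neighbors(last)):
                return order, False
        for u in g.neighbors(v):
            if u not in visited:
                weight[u] += 1
    return order, True


class _neg_key:
    """Reverses sort order of a value, so max() picks the smallest label."""

    __slots__ = ("v",)

    def __init__(self, v):
        self.v = v

    def __lt__(self, other):
        return self.v > other.v

    def __eq__(self, other):
        return self.v == other.v


def is_decomposable(g: nx.Graph | DecomposableGraph) -> bool:
    """True iff the graph is chordal (maximum-cardinality-search test)."""
    graph = g.graph if isinstance(g, DecomposableGraph) else g
    if graph.number_of_nodes() == 0:
        return True
    _, chordal = maximum_cardinality_search(graph)
    return chordal


def junction_tree_decomposition(g: nx.Graph):
    """Maximal cliques and separators (with multiplicity) of a chordal graph."""
    if g.number_of_nodes() == 0:
        return [], []
    cliques = [tuple(sorted(c)) for c in nx.chordal_graph_cliques(g)] \
        if g.number_of_edges() else [(v,) for v in g.nodes]
    cliques = sorted(set(cliques))
    if len(cliques) == 1:
        return [list(cliques[0])], []
    # maximum-weight spanning tree over clique-intersection sizes
    jt = nx.Graph()
    jt.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            inter = set(cliques[i]) & set(cliques[j])
            if inter:
                jt.add_edge(i, j, weight=len(inter))
    seps = []
    for comp in nx.connected_components(jt):
        sub = jt.subgraph(comp)
        for i, j in nx.maximum_spanning_tree(sub, weight="weight").edges:
            seps.append(sorted(set(cliques[i]) & set(cliques[j])))
    return [list(c) for c in cliques], seps


def gaussian_model_bic(g: nx.Graph, corr: pd.DataFrame, n: int) -> float:
    """BIC of a decomposable Gaussian model from clique/separator determinants.

    Data are standardized per gene, so the correlation matrix is the
    covariance MLE; free parameters = #vertices + #edges.
    """
    cliques, seps = junction_tree_decomposition(g)
    p = g.number_of_nodes()
    logdet = 0.0
    for c in cliques:
        logdet += _logdet(corr.loc[c, c].to_numpy())
    for s in seps:
        logdet -= _logdet(corr.loc[s, s].to_numpy())
    loglik = -0.5 * n * (p * math.log(2 * math.pi) + logdet + p)
    k = p + g.number_of_edges()
    return -2.0 * loglik + k * math.log(n)


def _logdet(a: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(np.atleast_2d(a))
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD clique covariance")
    return float(val)


def _partial_corr(corr: pd.DataFrame, u, v, sep: list) -> float:
    idx = [u, v] + list(sep)
    omega = np.linalg.inv(corr.loc[idx, idx].to_numpy())
    return float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))


def forward_edge_search(g0: DecomposableGraph, m: ExpressionMatrix,
                        max_edges: int | None = None,
                        candidate_scope: str = "distance2") -> DecomposableGraph:
    """Greedy BIC-minimizing edge addition preserving decomposability.

    At each step every non-edge whose addition keeps the graph chordal is
    scored by ``dBIC = n * ln(1 - r^2_{uv.S}) + ln(n)`` with ``r`` the
    partial correlation of the endpoints given the separator ``S`` of the
    new clique; the most negative dBIC wins (ties lexicographic).  The loop
    stops when no candidate improves BIC or ``max_edges`` were added.

    ``candidate_scope='distance2'`` restricts candidates to vertex pairs at
    graph distance <= 2 (a speed heuristic); ``'all'`` scans every pair.
    """
    if not is_decomposable(g0):
        raise ValueError("forward search requires a decomposable start graph")
    if candidate_scope not in ("distance2", "all"):
        raise ValueError("candidate_scope must be 'distance2' or 'all'")
    x = m.data
    z = x.sub(x.mean(axis=1), axis=0).div(x.std(axis=1, ddof=0), axis=0)
    corr = pd.DataFrame(np.corrcoef(z.to_numpy()),
                        index=x.index, columns=x.index)
    n = m.n_samples
    g = g0.graph.copy()
    logn = math.log(n)
    bic = gaussian_model_bic(g, corr, n)
    bic_path = [bic]
    added = 0
    while max_edges is None or added < max_edges:
        best = None
        for u, v in _candidate_pairs(g, candidate_scope):
            g.add_edge(u, v)
            sep = _new_clique_separator(g, u, v)
            if sep is None:
                g.remove_edge(u, v)
                continue
            r = _partial_corr(corr, u, v, sep)
            r = max(min(r, 1 - 1e-12), -1 + 1e-12)
            dbic = n * math.log1p(-r * r) + logn
            g.remove_edge(u, v)
            if dbic < -1e-12 and (best is None or (dbic, u, v) < best):
                best = (dbic, u, v)
        if best is None:
            break
        dbic, u, v = best
        g.add_edge(u, v)
        bic += dbic
        bic_path.append(bic)
        added += 1
    out = DecomposableGraph(g, n=n, bic=bic, bic_path=bic_path)
    out.refresh_decomposition()
    return out


def _candidate_pairs(g: nx.Graph, scope: str):
    nodes = sorted(g.nodes)
    if scope == "all":
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if not g.has_edge(u, v):
                    yield u, v
    else:
        seen = set()
        for u in nodes:
            reach = set()
            for w in g.neighbors(u):
                reach.add(w)
                reach.update(g.neighbors(w))
            reach.discard(u)
            for v in reach:
                if not g.has_edge(u, v):
                    e = (u, v) if u < v else (v, u)
                    if e not in seen:
                        seen.add(e)
                        yield e


def _new_clique_separator(g: nx.Graph, u, v):
    """Separator of the clique created by edge (u, v), or None if non-chordal.

    In a decomposable graph a legal single-edge addition creates exactly one
    new maximal clique C = S ∪ {u, v}; S is returned sorted.
    """
    if not is_decomposable(g):
        return None
    cliques = [set(c) for c in nx.find_cliques(g, nodes=[u, v])]
    # a legal single-edge addition lives in exactly one new maximal clique
    c = max(cliques, key=lambda s: (len(s), sorted(s)))
    return sorted(c - {u, v})


def split_into_branches(g: DecomposableGraph, target_count: int = 13,
                        min_size: int = 2,
                        max_size: int | None = None) -> list[FunctionalNode]:
    """Partition the network into connected branches of bounded size.

    Components larger than ``max_size`` (default ``ceil(p / target_count)``)
    are cut at their highest edge-betweenness edge, recursively; undersized
    fragments are merged back into the neighbor component across the cut
    edge.  Deterministic for a fixed graph.
    """
    p = g.graph.number_of_nodes()
    if target_count > p:
        raise ValueError(f"target_count={target_count} exceeds {p} vertices")
    if max_size is None:
        max_size = max(min_size, math.ceil(p / target_count))
    work = g.graph.copy()
    cut_edges = []
    while True:
        big = [c for c in nx.connected_components(work) if len(c) > max_size]
        if not big:
            break
        comp = sorted(big, key=lambda c: (-len(c), sorted(c)[0]))[0]
        sub = work.subgraph(comp)
        btw = nx.edge_betweenness_centrality(sub)
        edge = max(btw, key=lambda e: (btw[e], tuple(sorted(e))))
        edge = tuple(sorted(edge))
        work.remove_edge(*edge)
        cut_edges.append(edge)
    comp_of = {}
    comps = [sorted(c) for c in nx.connected_components(work)]
    comps.sort(key=lambda c: c[0])
    for ci, c in enumerate(comps):
        for v in c:
            comp_of[v] = ci
    members = {ci: set(c) for ci, c in enumerate(comps)}
    # merge undersized fragments back across their cut edge
    for u, v in reversed(cut_edges):
        cu, cv = comp_of[u], comp_of[v]
        if cu == cv:
            continue
        small, large = (cu, cv) if len(members[cu]) <= len(members[cv]) else (cv, cu)
        if len(members[small]) < min_size:
            for w in members[small]:
                comp_of[w] = large
            members[large] |= members.pop(small)
    branches = sorted(members.values(), key=lambda s: sorted(s)[0])
    return [FunctionalNode(label=f"branch_{i + 1}", genes=sorted(s))
            for i, s in enumerate(branches)]


def node_activity(m: ExpressionMatrix, node: FunctionalNode,
                  use_main_function_subset: bool = False) -> pd.Series:
    """Per-sample activity = unweighted mean expression of the node's genes."""
    genes = node.genes
    if use_main_function_subset and node.main_function_genes:
        genes = node.main_function_genes
    if not genes:
        raise ValueError(f"functional node {node.label!r} has no genes")
    return m.data.loc[list(genes)].mean(axis=0).rename(node.label)


def node_activity_matrix(m: ExpressionMatrix, nodes: list[FunctionalNode],
                         use_main_function_subset: bool = False) -> pd.DataFrame:
    """Functional nodes x samples activity matrix."""
    return pd.DataFrame(
        [node_activity(m, nd, use_main_function_subset) for nd in nodes])
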