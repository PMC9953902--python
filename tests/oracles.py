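"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately written by direct enumeration or plain
arithmetic, independent of the library code paths it checks.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd

from layerscope.expression import ExpressionMatrix
from layerscope.pgm import junction_tree_decomposition


def matrix_from_cov(cov, n, seed, prefix="G"):
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    x = rng.multivariate_normal(np.zeros(p), cov, size=n).T
    return ExpressionMatrix(pd.DataFrame(
        x, index=[f"{prefix}{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)]))


def random_cov(p, rng):
    a = rng.normal(size=(p, p))
    cov = a @ a.T + p * np.eye(p)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def all_spanning_trees(genes):
    """All labeled spanning trees on the given vertices (16 for p=4)."""
    all_edges = list(itertools.combinations(genes, 2))
    p = len(genes)
    for edges in itertools.combinations(all_edges, p - 1):
        g = nx.Graph(edges)
        if g.number_of_nodes() == p and nx.is_tree(g):
            yield edges


def chordless_cycle_free(g: nx.Graph) -> bool:
    """Brute force chordality: no induced subgraph on >=4 vertices is a cycle."""
    nodes = list(g.nodes)
    for size in range(4, len(nodes) + 1):
        for sub in itertools.combinations(nodes, size):
            h = g.subgraph(sub)
            if h.number_of_edges() == size and \
                    all(d == 2 for _, d in h.degree) and nx.is_connected(h):
                return False
    return True


def global_bic_via_concentration(g: nx.Graph, corr: pd.DataFrame, n: int):
    """Independent BIC: assemble the MLE concentration matrix clique-by-
    clique and evaluate the Gaussian log-likelihood from it directly."""
    genes = list(corr.index)
    p = len(genes)
    pos = {v: i for i, v in enumerate(genes)}
    k = np.zeros((p, p))
    cliques, seps = junction_tree_decomposition(g)
    for c in cliques:
        idx = [pos[v] for v in c]
        k[np.ix_(idx, idx)] += np.linalg.inv(corr.loc[c, c].to_numpy())
    for s in seps:
        idx = [pos[v] for v in s]
        k[np.ix_(idx, idx)] -= np.linalg.inv(corr.loc[s, s].to_numpy())
    sign, logdet_k = np.linalg.slogdet(k)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD concentration matrix")
    r = corr.to_numpy()
    loglik = 0.5 * n * (logdet_k - p * math.log(2 * math.pi)
                        - np.trace(k @ r))
    n_params = p + g.number_of_edges()
    return -2.0 * loglik + n_params * math.log(n)


def sam_d_two_class(x, lab, s0):
    """Plain-arithmetic two-class SAM d."""
    i1, i2 = lab == "a", lab == "b"
    n1, n2 = i1.sum(), i2.sum()
    m1, m2 = x[:, i1].mean(axis=1), x[:, i2].mean(axis=1)
    ss = ((x[:, i1] - m1[:, None]) ** 2).sum(axis=1) + \
         ((x[:, i2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (m2 - m1) / (s + s0)


def logrank_two_groups(time, event, group):
    """From-scratch event-table log-rank (O, E, V, chi-square) for 2 groups."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    is_a = np.asarray(group) == np.asarray(group)[0]
    o1 = e1 = v1 = 0.0
    for t in np.unique(time[event == 1]):
        at = time >= t
        n, n1 = at.sum(), (at & is_a).sum()
        d = ((time == t) & (event == 1)).sum()
        o1 += ((time == t) & (event == 1) & is_a).sum()
        e1 += d * n1 / n
        if n > 1:
            v1 += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v1 if v1 > 0 else 0.0
    return o1, e1, v1, chi2
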