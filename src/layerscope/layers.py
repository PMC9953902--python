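"""Iterative sparse k-means + consensus-cluster layer discovery.

A *layer* is a subset of genes that sparse k-means assigns strictly positive
weights (one dominant source of between-sample variability), together with
the sample partition those genes induce under consensus clustering.  Layers
are peeled iteratively: once a layer's genes are identified they are removed
and the analysis repeats on the remainder, so statistically orthogonal
sources of structure (e.g. adhesion vs immune vs molecular programs) surface
as separate layers.  Redundant layers — those that partition the samples the
same way — are merged afterwards.

Sparse k-means follows the lasso-type feature-weighting formulation: weights
``w_j >= 0`` with ``||w||_2 <= 1`` and ``||w||_1 <= s`` maximize
``sum_j w_j * BCSS_j`` by alternating k-means on weight-scaled data with a
soft-threshold weight update.  Consensus clustering resamples subsets of
samples, re-clusters each, and summarizes pair co-clustering frequencies in
a consensus matrix; the proportion of ambiguous pairs (PAC) selects k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .expression import ExpressionMatrix

__all__ = [
    "SparseKmeansFit", "ConsensusResult", "Layer", "LayerSet",
    "sparse_kmeans", "tune_sparsity", "consensus_cluster", "choose_k",
    "peel_layers", "merge_layers",
]


@dataclass
class SparseKmeansFit:
    weights: pd.Series          # per gene, >= 0, ||w||_2 <= 1, ||w||_1 <= s
    labels: pd.Series           # per sample cluster id
    s: float
    objective: float            # sum_j w_j * BCSS_j at convergence
    objective_path: list        # per-iteration objective (non-decreasing)
    n_iter: int
    weight_path: list = field(default_factory=list)  # w after each iteration

    @property
    def selected_genes(self) -> list:
        return self.weights.index[self.weights > 0].tolist()


@dataclass
class ConsensusResult:
    consensus: dict             # k -> samples x samples DataFrame in [0,1]
    pac: dict                   # k -> proportion of ambiguous clustering
    cdf_area: dict              # k -> area under the consensus CDF
    delta_area: dict            # k -> Monti relative area increase
    chosen_k: int
    labels: pd.Series           # final labels at chosen_k


@dataclass
class Layer:
    index: int
    gene_weights: pd.Series
    labels: pd.Series
    k: int
    pac: float
    enrichment_label: str | None = None

    @property
    def genes(self) -> list:
        return self.gene_weights.index.tolist()


@dataclass
class LayerSet:
    layers: list = field(default_factory=list)
    merge_map: dict = field(default_factory=dict)   # raw index -> merged name
    merged: list = field(default_factory=list)      # merged Layer objects


def _bcss(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-cluster sum of squares per gene (rows of x)."""
    total = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    within = np.zeros(x.shape[0])
    for c in np.unique(labels):
        xc = x[:, labels == c]
        within += ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return total - within


def _soft_threshold_weights(b: np.ndarray, s: float) -> np.ndarray:
    """w ∝ (b - delta)_+ normalized to unit 2-norm with ||w||_1 = s.

    ``delta`` is found by bisection; delta = 0 if the unthresholded solution
    already satisfies the l1 bound.
    """
    b = np.maximum(b, 0.0)
    bmax = b.max()
    if bmax <= 0 or not np.isfinite(bmax):
        # degenerate flat BCSS: uniform weights shrunk into both constraint balls
        p = b.size
        return np.full(p, min(1.0 / math.sqrt(p), s / p))
    b = b / bmax          # scale-invariant; guards against under/overflow

    def l1_of(delta):
        w = np.maximum(b - delta, 0.0)
        nrm = np.linalg.norm(w)
        return (w / nrm).sum() if nrm > 0 else 0.0

    if l1_of(0.0) <= s:
        w = b / np.linalg.norm(b)
        return w
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if l1_of(mid) > s:
            lo = mid
        else:
            hi = mid
    w = np.maximum(b - hi, 0.0)
    nrm = np.linalg.norm(w)
    if nrm == 0.0:
        # tied maxima make ||w||_1/||w||_2 = sqrt(#ties) > s unreachable by
        # thresholding; fall back to the first maximal gene alone
        w = np.zeros_like(b)
        w[int(np.argmax(b))] = 1.0
        return w
    return w / nrm


def _weighted_objective(x, labels, w):
    return float(np.dot(w, _bcss(x, labels)))


def sparse_kmeans(m: ExpressionMatrix | pd.DataFrame, k: int, s: float,
                  max_iter: int = 15, seed: int = 0,
                  n_init: int = 5) -> SparseKmeansFit:
    """Sparse k-means with l1 sparsity bound ``s`` (1 <= s <= sqrt(#genes)).

    Alternates (a) k-means on the weight-scaled data and (b) the closed-form
    soft-threshold weight update; keeps whichever labeling (new k-means fit
    or previous labels) has the larger weighted objective, so the objective
    path is monotone non-decreasing.
    """
    data = m.data if isinstance(m, ExpressionMatrix) else m
    x = data.to_numpy()
    p, n = x.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if not (1.0 <= s <= math.sqrt(p) + 1e-9):
        raise ValueError(f"s={s} outside [1, sqrt(p)={math.sqrt(p):.3f}]")
    rng = np.random.default_rng(seed)
    w = np.full(p, 1.0 / math.sqrt(p))
    labels = None
    path = []
    w_path = []
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        xw = (x * np.sqrt(w)[:, None]).T           # samples x genes, scaled
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2**31 - 1))).fit(xw)
        new_labels = km.labels_
        if labels is not None and \
                _weighted_objective(x, labels, w) > _weighted_objective(x, new_labels, w):
            new_labels = labels
        labels = new_labels
        w_old = w
        w = _soft_threshold_weights(_bcss(x, labels), s)
        path.append(_weighted_objective(x, labels, w))
        w_path.append(w.copy())
        if np.abs(w - w_old).sum() / max(np.abs(w_old).sum(), 1e-12) < 1e-4:
            break
    return SparseKmeansFit(
        weights=pd.Series(w, index=data.index, name="weight"),
        labels=pd.Series(labels, index=data.columns, name="cluster"),
        s=s, objective=path[-1], objective_path=path, n_iter=n_iter,
        weight_path=w_path)


def _default_s_grid(p: int) -> np.ndarray:
    hi = math.sqrt(p)
    return np.unique(np.clip(np.geomspace(1.2, hi, 12), 1.0, hi))


def tune_sparsity(m: ExpressionMatrix | pd.DataFrame, k: int,
                  s_grid=None, n_perms: int = 5, seed: int = 0,
                  max_iter: int = 8, return_details: bool = False):
    """Choose the l1 bound by the gap statistic.

    ``gap(s) = log O(s) - mean_b log O*_b(s)`` where ``O`` is the sparse
    k-means objective and ``O*_b`` the objective on data with each gene's
    values permuted independently across samples (destroying sample
    structure while keeping gene-wise distributions).  Because the gap is a
    Monte-Carlo estimate that rises steeply and then plateaus once the
    dominant gene block is fully weighted, ties are read at Monte-Carlo
    precision: the smallest ``s`` whose gap is within one standard error of
    the maximum is returned (the one-SE gap convention); exact ties
    likewise resolve to the smallest ``s``.
    """
    if n_perms < 2:
        raise ValueError("n_perms must be >= 2")
    data = m.data if isinstance(m, ExpressionMatrix) else m
    p = data.shape[0]
    if s_grid is None:
        s_grid = _default_s_grid(p)
    s_grid = sorted(s_grid)
    rng = np.random.default_rng(seed)
    perms = []
    x = data.to_numpy()
    for _ in range(n_perms):
        xp = x.copy()
        for j in range(p):
            rng.shuffle(xp[j])
        perms.append(pd.DataFrame(xp, index=data.index, columns=data.columns))
    gaps, null_log_mat = [], []
    for s in s_grid:
        o = sparse_kmeans(data, k, s, max_iter=max_iter,
                          seed=int(rng.integers(2**31 - 1))).objective
        null_logs = [math.log(max(sparse_kmeans(xp, k, s, max_iter=max_iter,
                                                seed=int(rng.integers(2**31 - 1))
                                                ).objective, 1e-300))
                     for xp in perms]
        gaps.append(math.log(max(o, 1e-300)) - float(np.mean(null_logs)))
        null_log_mat.append(null_logs)
    null_log_mat = np.asarray(null_log_mat)          # |grid| x B
    i_best = int(np.argmax(gaps))
    se_best = float(np.std(null_log_mat[i_best], ddof=1)
                    / math.sqrt(n_perms))
    cutoff = gaps[i_best] - max(se_best, 1e-8)
    chosen = float(s_grid[i_best])
    for s, gap in zip(s_grid, gaps):
        if gap >= cutoff:
            chosen = float(s)
            break
    if return_details:
        return chosen, {"s_grid": [float(s) for s in s_grid],
                        "gaps": gaps, "max_gap": float(gaps[i_best])}
    return chosen


def consensus_cluster(m: ExpressionMatrix | pd.DataFrame, k_range=(2, 3, 4),
                      n_resamples: int = 1000, subsample_frac: float = 0.8,
                      seed: int = 0, pac_bounds=(0.1, 0.9)) -> ConsensusResult:
    """Consensus clustering over sample subsamples with k-means.

    For each k, samples are subsampled without replacement at
    ``subsample_frac``, clustered, and the consensus matrix entry (i, j) is
    the fraction of co-clusterings among co-samplings.  PAC is the fraction
    of off-diagonal entries strictly inside ``pac_bounds``; the consensus
    CDF area and Monti's relative delta-area are reported for diagnostics.
    """
    data = m.data if isinstance(m, ExpressionMatrix) else m
    x = data.to_numpy().T                           # samples x genes
    n = x.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2 or max(k_range) > n / 3:
        raise ValueError(f"k_range must lie within [2, n/3={n / 3:.1f}]")
    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_frac * n)), max(k_range) + 1)
    consensus, pac, area = {}, {}, {}
    iu = np.triu_indices(n, 1)
    for k in k_range:
        co = np.zeros((n, n))
        cnt = np.zeros((n, n))
        draws = 0
        while draws < n_resamples:
            idx = rng.choice(n, size=n_sub, replace=False)
            # one stochastic k-means++ run per resample: subsampling plus
            # seeding noise is the perturbation consensus clustering needs
            # to expose over- and under-fitted k
            km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(rng.integers(2**31 - 1))).fit(x[idx])
            lab = km.labels_
            same = (lab[:, None] == lab[None, :]).astype(float)
            co[np.ix_(idx, idx)] += same
            cnt[np.ix_(idx, idx)] += 1.0
            draws += 1
            if draws == n_resamples and (cnt[iu] == 0).any():
                if draws >= 10 * n_resamples:
                    raise RuntimeError("sample pairs never co-sampled after "
                                       "10x the requested resamples")
                n_resamples += max(1, n_resamples // 10)
        with np.errstate(invalid="ignore"):
            mk = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.0)
        np.fill_diagonal(mk, 1.0)
        mk = (mk + mk.T) / 2
        consensus[k] = pd.DataFrame(mk, index=data.columns, columns=data.columns)
        vals = mk[iu]
        lo, hi = pac_bounds
        pac[k] = float(np.mean((vals > lo) & (vals < hi)))
        # area under the empirical consensus CDF on [0, 1]
        sv = np.concatenate([[0.0], np.sort(vals), [1.0]])
        cdf = np.concatenate([[0.0], np.arange(1, vals.size + 1) / vals.size, [1.0]])
        area[k] = float(np.trapezoid(cdf, sv))
    delta = {}
    ks = sorted(area)
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    chosen = _min_pac_k(pac)
    final = KMeans(n_clusters=chosen, n_init=10,
                   random_state=int(rng.integers(2**31 - 1))).fit(x)
    labels = pd.Series(final.labels_, index=data.columns, name="cluster")
    return ConsensusResult(consensus=consensus, pac=pac, cdf_area=area,
                           delta_area=delta, chosen_k=chosen, labels=labels)


def _min_pac_k(pac: dict) -> int:
    return min(sorted(pac), key=lambda k: (pac[k], k))


def choose_k(c: ConsensusResult) -> int:
    """k with minimal PAC; ties resolve to the smaller k."""
    if len(c.pac) < 2:
        raise ValueError("need at least two candidate k")
    return _min_pac_k(c.pac)


@dataclass
class PeelConfig:
    """Knobs of the peeling loop (defaults are the workflow's conventions)."""

    k_select: int = 2            # structure-detector k during gene selection
    s_grid: tuple | None = None
    n_perms: int = 5
    k_range: tuple = (2, 3, 4)
    n_resamples: int = 100
    subsample_frac: float = 0.8
    min_genes: int = 20
    max_layers: int = 9
    pac_threshold: float = 0.3   # no-structure flag on the consensus matrix
    gap_threshold: float = 0.5   # min clustering evidence (max gap, nats)
    seed: int = 0


def peel_layers(m: ExpressionMatrix | pd.DataFrame,
                cfg: PeelConfig | None = None) -> LayerSet:
    """Iteratively peel information layers off the expression matrix.

    Each round tunes the sparsity bound, fits sparse k-means (k=2 as the
    cheapest structure detector), takes the positively weighted genes as the
    layer's gene set, consensus-clusters the samples on those genes to fix
    the layer's k and partition, then removes the genes and repeats.  The
    loop stops when fewer than ``min_genes`` genes are selected, when
    ``max_layers`` is reached, when the best consensus PAC exceeds
    ``pac_threshold``, or when the tuning gap never exceeds
    ``gap_threshold``.  The gap stop matters because the PAC flag alone is
    circular on structureless data: genes selected *because* they support
    one noise split reproduce that split under resampling, while the
    permutation gap is computed on all remaining genes before selection
    and stays near zero when no block structure is left.
    """
    cfg = cfg or PeelConfig()
    data = (m.data if isinstance(m, ExpressionMatrix) else m).copy()
    rng = np.random.default_rng(cfg.seed)
    ls = LayerSet()
    for idx in range(1, cfg.max_layers + 1):
        if data.shape[0] < cfg.min_genes:
            break
        seed_i = int(rng.integers(2**31 - 1))
        s, tune_info = tune_sparsity(data, cfg.k_select, s_grid=cfg.s_grid,
                                     n_perms=cfg.n_perms, seed=seed_i,
                                     return_details=True)
        if tune_info["max_gap"] < cfg.gap_threshold:
            break
        fit = sparse_kmeans(data, cfg.k_select, s, seed=seed_i)
        # a layer is a *proper* gene subset: if the tuned bound zeroes
        # nothing, step down the grid until soft-thresholding bites
        if len(fit.selected_genes) == data.shape[0]:
            grid = sorted(cfg.s_grid) if cfg.s_grid is not None \
                else list(_default_s_grid(data.shape[0]))
            for s_try in reversed([g for g in grid if g < s]):
                fit_try = sparse_kmeans(data, cfg.k_select, s_try, seed=seed_i)
                if 0 < len(fit_try.selected_genes) < data.shape[0]:
                    fit = fit_try
                    break
        genes = fit.selected_genes
        if len(genes) < cfg.min_genes:
            break
        cons = consensus_cluster(data.loc[genes], k_range=cfg.k_range,
                                 n_resamples=cfg.n_resamples,
                                 subsample_frac=cfg.subsample_frac,
                                 seed=seed_i)
        best_pac = cons.pac[cons.chosen_k]
        if best_pac > cfg.pac_threshold:
            break
        ls.layers.append(Layer(index=idx,
                               gene_weights=fit.weights.loc[genes],
                               labels=cons.labels, k=cons.chosen_k,
                               pac=best_pac))
        data = data.drop(index=genes)
    return ls


def merge_layers(ls: LayerSet, ari_threshold: float = 0.6,
                 k_range=(2, 3, 4), n_resamples: int = 100,
                 expression: ExpressionMatrix | pd.DataFrame | None = None,
                 seed: int = 0) -> LayerSet:
    """Merge layers whose sample partitions agree (ARI >= threshold).

    The merge relation is closed transitively; each merged layer's gene set
    is the union of its members' genes and, when the full expression matrix
    is supplied, its final partition and k are re-derived by consensus
    clustering on that union.
    """
    if not ls.layers:
        raise ValueError("no layers to merge")
    idxs = [ly.index for ly in ls.layers]
    parent = {i: i for i in idxs}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(idxs)):
        for b in range(a + 1, len(idxs)):
            la, lb = ls.layers[a], ls.layers[b]
            ari = adjusted_rand_score(la.labels.to_numpy(),
                                      lb.labels.reindex(la.labels.index).to_numpy())
            if ari >= ari_threshold:
                parent[find(lb.index)] = find(la.index)
    groups: dict[int, list] = {}
    for ly in ls.layers:
        groups.setdefault(find(ly.index), []).append(ly)
    out = LayerSet(layers=ls.layers)
    rng = np.random.default_rng(seed)
    for mi, (root, members) in enumerate(sorted(groups.items()), start=1):
        name = f"merged_{mi}"
        for ly in members:
            out.merge_map[ly.index] = name
        weights = pd.concat([ly.gene_weights for ly in members])
        weights = weights.groupby(level=0).max().sort_index()
        lead = members[0]
        labels, k, pac = lead.labels, lead.k, lead.pac
        if expression is not None and len(members) >= 1:
            data = (expression.data if isinstance(expression, ExpressionMatrix)
                    else expression)
            cons = consensus_cluster(data.loc[weights.index], k_range=k_range,
                                     n_resamples=n_resamples,
                                     seed=int(rng.integers(2**31 - 1)))
            labels, k, pac = cons.labels, cons.chosen_k, cons.pac[cons.chosen_k]
        out.merged.append(Layer(index=mi, gene_weights=weights, labels=labels,
                                k=k, pac=pac, enrichment_label=name))
    return out
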