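"""Synthetic multi-batch expression cohorts with planted information layers.

The generator emulates the structure the layer-discovery workflow assumes in
a merged colorectal-tumor expression cohort: blocks of genes driven by latent
sample-level factors — a binary *adhesion* factor, a binary *immune* factor
and a 4-level *molecular* factor — on top of additive per-batch offsets and
Gaussian residual noise, with exponential disease-free survival whose hazard
depends on the adhesion group.  The returned ground truth scores every
downstream stage (clustering, peeling, survival).

Model per gene g and sample i::

    x_gi = mu_g + beta_g * s_{L(g)}(group_{L(g)}(i)) + b_{batch(i),g} + eps_gi

with ``eps ~ N(0, sigma^2)``, loadings ``beta_g`` drawn around the layer
effect size ``delta_L`` (noise genes have ``beta_g = 0``), group codes ``s``
equal to +/-1 for the binary layers and orthogonal Hadamard contrast codes
for the 4-level molecular factor.  Survival times are exponential with rate
``lambda0 * exp(beta_surv * 1[adhesion-high])``, censored at the follow-up
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .expression import ClinicalTable, ExpressionMatrix

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "score_partition",
           "planted_cluster_matrix"]

# Centered one-vs-rest contrast codes for the 4-level molecular factor:
# genes of sub-block c mark level c (up in-group, down elsewhere, zero-sum),
# the marker-block structure molecular subtypes show in real cohorts.
# Codes are scaled to unit variance across levels so that delta means the
# same thing for every layer (the binary +/-1 codes are already unit SD).
_MOLECULAR_CONTRASTS = (4.0 * np.eye(4) - 1.0) / 3.0
_MOLECULAR_CONTRASTS /= np.sqrt((_MOLECULAR_CONTRASTS**2).mean(axis=1,
                                                               keepdims=True))

# Group prevalences mirror the cohort proportions the workflow was built
# around (adhesion 454:351, immune 364:441, molecular 221:137:300:147 of 805).
_ADHESION_PREV = (454 / 805, 351 / 805)
_IMMUNE_PREV = (364 / 805, 441 / 805)
_MOLECULAR_PREV = (221 / 805, 137 / 805, 300 / 805, 147 / 805)
_BATCH_PREV = (177 / 805, 62 / 805, 566 / 805)


@dataclass
class CohortConfig:
    """Parameters of the planted-layer cohort generator.

    Effect sizes ``delta_*`` are in units of the residual SD ``sigma``;
    hazards are per month.
    """

    n_samples: int = 400
    n_batches: int = 3
    genes_per_block: dict = field(default_factory=lambda: {
        "adhesion": 120, "immune": 100,
        "molecular_1": 30, "molecular_2": 30,
        "molecular_3": 30, "molecular_4": 30,
        "noise": 260,
    })
    delta_adhesion: float = 1.5
    delta_immune: float = 1.2
    delta_molecular: float = 1.0
    loading_spread: float = 0.2   # SD of beta_g around delta_L
    sigma: float = 1.0
    batch_offset_sd: float = 0.5
    baseline_hazard: float = 0.004        # events / month, adhesion-low
    log_hazard_adhesion: float = float(np.log(2.4))
    censor_horizon: float = 60.0          # months
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.genes_per_block.values()):
            raise ValueError("gene block counts must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")

    @property
    def n_genes(self) -> int:
        return sum(self.genes_per_block.values())


@dataclass
class GroundTruth:
    """Planted memberships and parameters, for scoring recovered structure."""

    adhesion: pd.Series        # per sample, {"low", "high"}
    immune: pd.Series          # per sample, {"low", "high"}
    molecular: pd.Series       # per sample, {1, 2, 3, 4}
    gene_block: pd.Series      # per gene, block name
    batch_offsets: pd.DataFrame  # batches x genes
    beta_surv: float

    def layer_labels(self, layer: str) -> pd.Series:
        try:
            return {"adhesion": self.adhesion, "immune": self.immune,
                    "molecular": self.molecular}[layer]
        except KeyError:
            raise KeyError(f"unknown layer {layer!r}; expected adhesion/"
                           "immune/molecular") from None


def _draw_levels(rng, n, prevalences, labels):
    """Deterministic composition: counts proportional to prevalence, shuffled."""
    counts = np.floor(np.asarray(prevalences) * n).astype(int)
    while counts.sum() < n:
        counts[np.argmax(np.asarray(prevalences) * n - counts)] += 1
    out = np.repeat(labels, counts)
    rng.shuffle(out)
    return out


def generate_cohort(cfg: CohortConfig) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Simulate one cohort; fully reproducible from ``cfg.seed``."""
    # a requested layer must carry at least one informative gene
    layer_of = lambda b: "molecular" if b.startswith("molecular") else b
    genes_per_layer: dict[str, int] = {}
    for b, c in cfg.genes_per_block.items():
        if b != "noise":
            genes_per_layer[layer_of(b)] = genes_per_layer.get(layer_of(b), 0) + c
    for layer, count in genes_per_layer.items():
        if count == 0:
            raise ValueError(f"layer {layer!r} requested with zero informative genes")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    adhesion = _draw_levels(rng, n, _ADHESION_PREV, np.array(["low", "high"]))
    immune = _draw_levels(rng, n, _IMMUNE_PREV, np.array(["low", "high"]))
    molecular = _draw_levels(rng, n, _MOLECULAR_PREV, np.array([1, 2, 3, 4]))
    batch_prev = (_BATCH_PREV if cfg.n_batches == 3
                  else tuple(1 / cfg.n_batches for _ in range(cfg.n_batches)))
    batch = _draw_levels(rng, n, batch_prev,
                         np.array([f"cohort{j + 1}" for j in range(cfg.n_batches)]))

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids, blocks, codes, deltas = [], [], [], []
    for b, count in cfg.genes_per_block.items():
        for j in range(count):
            gene_ids.append(f"{b.upper()}_{j:04d}")
            blocks.append(b)
    gene_block = pd.Series(blocks, index=gene_ids, name="block")
    p = len(gene_ids)

    # per-sample code value for each gene's driving factor
    adh_code = np.where(adhesion == "high", 1.0, -1.0)
    imm_code = np.where(immune == "high", 1.0, -1.0)
    mol_codes = _MOLECULAR_CONTRASTS[:, molecular.astype(int) - 1]  # 3 x n

    signal = np.zeros((p, n))
    beta = np.zeros(p)
    for g, b in enumerate(blocks):
        if b == "noise":
            continue
        if b == "adhesion":
            code, delta = adh_code, cfg.delta_adhesion
        elif b == "immune":
            code, delta = imm_code, cfg.delta_immune
        else:
            sub = int(b.rsplit("_", 1)[1])          # molecular_1..4
            code = mol_codes[sub - 1]
            delta = cfg.delta_molecular
        beta[g] = delta + cfg.loading_spread * rng.standard_normal()
        signal[g] = beta[g] * code

    mu = rng.normal(7.0, 1.0, size=p)               # log2-scale gene baselines
    offsets = rng.normal(0.0, cfg.batch_offset_sd,
                         size=(cfg.n_batches, p))
    batch_idx = np.array([int(bl[len("cohort"):]) - 1 for bl in batch])
    eps = rng.normal(0.0, cfg.sigma, size=(p, n))
    x = mu[:, None] + signal + offsets[batch_idx, :].T + eps

    expr = ExpressionMatrix(
        pd.DataFrame(x, index=gene_ids, columns=sample_ids),
        pd.Series(batch, index=sample_ids),
    )

    rate = cfg.baseline_hazard * np.exp(
        cfg.log_hazard_adhesion * (adhesion == "high"))
    t_event = rng.exponential(1.0 / rate)
    event = (t_event < cfg.censor_horizon).astype(int)
    dfs = np.minimum(t_event, cfg.censor_horizon)

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "batch": batch,
        "dfs_months": dfs,
        "relapse_event": event,
        "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.35, 0.38, 0.12]),
        "location": rng.choice(["proximal", "distal"], size=n),
    }))

    truth = GroundTruth(
        adhesion=pd.Series(adhesion, index=sample_ids),
        immune=pd.Series(immune, index=sample_ids),
        molecular=pd.Series(molecular.astype(int), index=sample_ids),
        gene_block=gene_block,
        batch_offsets=pd.DataFrame(
            offsets, index=[f"cohort{j + 1}" for j in range(cfg.n_batches)],
            columns=gene_ids),
        beta_surv=cfg.log_hazard_adhesion,
    )
    return expr, clinical, truth


def score_partition(partition, truth: GroundTruth, layer: str) -> float:
    """Adjusted Rand index between a sample partition and a planted layer.

    ``partition`` maps sample id -> group label (dict or Series) and must
    cover every sample in the truth.
    """
    labels_true = truth.layer_labels(layer)
    part = pd.Series(partition)
    missing = labels_true.index.difference(part.index)
    if len(missing):
        raise ValueError(f"partition does not cover samples: {list(missing)[:5]}")
    return float(adjusted_rand_score(labels_true.to_numpy().astype(str),
                                     part.reindex(labels_true.index).to_numpy().astype(str)))


def planted_cluster_matrix(n_samples: int, k: int, n_informative: int,
                           n_noise: int, delta: float, seed: int,
                           prevalences=None):
    """Single-factor planted clustering instance (genes x samples).

    A reduced version of :func:`generate_cohort` used to exercise one
    clustering stage in isolation: ``k`` groups, informative genes shifted by
    ``delta`` (unit residual SD) along centered one-vs-rest marker codes
    (+1 in-group, -1/(k-1) out; +/-1 for k=2), plus pure-noise genes.
    Returns ``(X, labels)`` with ``X`` a DataFrame and ``labels`` the true
    group per sample.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    if prevalences is None:
        prevalences = tuple(1 / k for _ in range(k))
    labels = _draw_levels(rng, n_samples, prevalences, np.arange(k))
    codes = (k * np.eye(k) - 1.0) / (k - 1.0)                    # k x k
    codes /= np.sqrt((codes**2).mean(axis=1, keepdims=True))     # unit SD
    n_codes = codes.shape[0]
    p = n_informative + n_noise
    x = rng.standard_normal((p, n_samples))
    for g in range(n_informative):
        code_row = codes[g % n_codes]
        x[g] += delta * code_row[labels]
    genes = [f"INF_{g:04d}" for g in range(n_informative)] + \
            [f"NOISE_{g:04d}" for g in range(n_noise)]
    df = pd.DataFrame(x, index=genes,
                      columns=[f"S{i:04d}" for i in range(n_samples)])
    return df, pd.Series(labels, index=df.columns)
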