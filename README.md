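# layerscope

Layered molecular characterization of tumor expression cohorts.

Bulk expression cohorts mix several independent axes of biology: how
adhesive/stromal a tumor is, how immune-infiltrated it is, and which
molecular program (stem-cell, Wnt, metabolic, extracellular) drives it.
A single clustering collapses these axes into one partition. `layerscope`
instead peels them apart as *layers of information*, following a workflow
developed for colorectal tumors: each layer is the gene set that sparse
k-means currently finds most informative, together with the patient
partition those genes induce under consensus clustering; the genes are then
removed and the analysis repeats on the remainder, so orthogonal biological
signals surface as separate, independently interpretable classifications.
The package is aimed at computational biologists who want that workflow —
and every statistic around it — as tested, scriptable Python.

## What it computes

- **Preprocessing** — merge cohorts on shared probes, collapse probes to
  genes by maximal variance, remove additive batch effects, filter genes by
  SD; unify clinical tables (DFS time, relapse event, stage, location, CMS).
- **Graphical model** — pairwise Gaussian mutual information
  MI = −½ ln(1 − ρ²); the maximum-likelihood (Chow–Liu) spanning tree;
  greedy edge addition minimizing BIC while keeping the graph decomposable
  (chordal), using ΔBIC = n·ln(1 − r²_{uv·S}) + ln n per edge; splitting
  into functional-node branches and per-sample node activities (mean
  expression of a branch).
- **Layer discovery** — sparse k-means (weights w ≥ 0, ‖w‖₂ ≤ 1, ‖w‖₁ ≤ s,
  maximizing Σ w_j·BCSS_j) with gap-statistic tuning of s; consensus
  clustering over sample subsamples with PAC-based selection of the number
  of groups; the iterative peeling loop; ARI-based merging of redundant
  layers.
- **Group statistics** — SAM permutation differential expression (two-class
  and multiclass d with Tusher's s0, permutation FDR, Δ calibration);
  Kruskal–Wallis + Dunn post-hoc comparisons of node activities;
  hypergeometric gene-set overrepresentation (GMT input).
- **Survival** — Kaplan–Meier curves, log-rank tests, Mantel–Haenszel
  hazard ratios with 95% CIs (optional Cox check) on disease-free survival.
- **Synthetic cohorts** — a generator that plants adhesion/immune/molecular
  layer structure, batch offsets and group-dependent exponential survival,
  with ground truth for scoring every stage.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Generate a synthetic three-layer cohort, peel its layers, and test the
survival split of the strongest one:

```python
from layerscope import (CohortConfig, generate_cohort, remove_batch_effect,
                        peel_layers, merge_layers, score_partition,
                        SurvivalInput, hazard_ratio)
from layerscope.layers import PeelConfig

cfg = CohortConfig(seed=1)                       # 600 genes, 400 samples
expr, clinical, truth = generate_cohort(cfg)
expr = remove_batch_effect(expr)

layers = peel_layers(expr, PeelConfig(seed=1))
layers = merge_layers(layers, expression=expr, seed=1)
for ly in layers.merged:
    ari = {name: score_partition(ly.labels, truth, name)
           for name in ("adhesion", "immune", "molecular")}
    top = max(ari, key=ari.get)
    print(f"merged layer {ly.index}: {len(ly.genes)} genes, "
          f"k={ly.k}, best truth match {top} (ARI {ari[top]:.2f})")

adhesion_layer = layers.merged[0]
s = SurvivalInput.from_clinical(
    clinical.aligned_to(expr.sample_ids), adhesion_layer.labels)
hr = hazard_ratio(s)
print(f"log-rank p = {hr.p:.2e}, HR = {hr.hr:.2f} "
      f"(95% CI {hr.ci_low:.2f}-{hr.ci_high:.2f})")
```

Output:

```
merged layer 1: 119 genes, k=2, best truth match adhesion (ARI 1.00)
merged layer 2: 82 genes, k=2, best truth match immune (ARI 1.00)
merged layer 3: 83 genes, k=3, best truth match molecular (ARI 0.85)
log-rank p = 2.80e-09, HR = 2.86 (95% CI 2.00-4.09)
```

The three planted layers come back as three merged layers — the binary
adhesion and immune factors exactly (ARI 1.0), the 4-level molecular factor
nearly so — and the adhesion split carries the planted survival difference:
the generator gives adhesion-high tumors a 2.4-fold hazard, and the
estimated hazard ratio of 2.86 (CI 2.00–4.09) covers it. On real cohorts
the same loop runs from TSV/CSV inputs via the command line:

```bash
layerscope run --config analysis.yaml --out results/
```

with subcommands `simulate`, `preprocess`, `pgm`, `layers`, `sam`,
`survival` for the individual stages. Every run writes a JSON manifest
(config hash, seeds, per-stage gene/sample counts) that makes the outputs
reproducible byte-for-byte.

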