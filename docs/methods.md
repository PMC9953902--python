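# Methods

`layerscope` implements a layered molecular-characterization workflow for
multi-cohort tumor expression data: preprocessing, a decomposable Gaussian
graphical model over the most variable genes, iterative sparse k-means +
consensus-cluster discovery of information "layers", SAM differential
expression and nonparametric node-activity comparisons between the resulting
sample groups, and disease-free-survival stratification. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Preprocessing

Cohorts arrive as genes × samples log2 matrices. Merging keeps the probes
measured in *all* cohorts (row intersection) and concatenates samples,
labelling each by its source cohort. Probe-to-gene collapse keeps, per gene,
the probe with maximal variance across all samples; exact variance ties
break to the lexicographically smallest probe id so results are platform-
independent. Batch correction removes each batch's per-gene mean and adds
back the gene's grand mean — the least-squares fit of batch indicators with
no other covariates. It is idempotent and leaves every batch with identical
per-gene means (within 1e-10). The variability filter keeps genes with
sample SD strictly greater than the threshold (default 2.0 on the log2
scale, the conventional cut for building the network; synthetic runs use
lower thresholds matched to their simulated dynamic range). No quantile
renormalization is applied; input series are assumed normalized upstream.
Median follow-up is reported as the plain median of the follow-up times.

## Decomposable Gaussian graphical model

Pairwise association is Pearson correlation ρ and Gaussian mutual
information MI = −½·ln(1 − ρ²) (nats); |ρ| = 1 is clamped at
MI = ½·ln(1e12). The network is built in two steps:

1. **Maximum-likelihood spanning tree.** For Gaussian variables the
   spanning tree maximizing the likelihood is the maximum-weight tree under
   MI edge weights (the Chow–Liu construction). Kruskal's algorithm runs on
   edges sorted by (−MI, gene pair), so ties resolve deterministically.
2. **BIC forward search.** Starting from the tree, the search repeatedly
   adds the single edge that most decreases the Bayesian Information
   Criterion while keeping the graph chordal, stopping when no edge helps
   or `max_edges` is reached. A legal addition (u, v) creates exactly one
   new maximal clique S ∪ {u, v}; its BIC change has the closed form
   ΔBIC = n·ln(1 − r²_{uv·S}) + ln(n), with r the partial correlation of
   u, v given S. Data are standardized per gene; free parameters are
   #vertices + #edges, so each edge costs ln(n). The model BIC is also
   computable globally from clique/separator determinants of the junction
   tree, and the two routes agree to 1e-8 — this dual computation is tested
   on every accepted step.

Chordality is tested by maximum cardinality search with a perfect-
elimination check (lexicographic tie-breaks). Candidate edges default to
vertex pairs at graph distance ≤ 2 — a speed heuristic that keeps the
search near the tree backbone; `candidate_scope="all"` scans every pair and
is what the enumeration oracles exercise. The chordality test is quadratic
per candidate, so full-scale searches (thousands of genes) should bound
`max_edges`; the analysis itself only needs the network's branch structure.

Branches ("functional nodes") are obtained by cutting components larger
than `ceil(p / target_count)` at their highest edge-betweenness edge,
recursively, then folding fragments smaller than `min_size` back across
their cut edge. Node activity is the unweighted mean expression of a
node's genes (or of an annotated "main function" subset when provided);
single-gene nodes reproduce that gene's row exactly. Functional labels
come from hypergeometric overrepresentation against user-supplied GMT gene
sets rather than a web tool.

## Sparse k-means and tuning

Sparse k-means maximizes Σ_j w_j·BCSS_j over cluster labels and gene
weights w ≥ 0 with ‖w‖₂ ≤ 1 and ‖w‖₁ ≤ s, alternating (a) k-means on the
√w-scaled data and (b) the closed-form soft-threshold weight update, with
the threshold found by bisection so the l1 constraint binds. The previous
labeling is kept whenever a fresh k-means fit would lower the weighted
objective, which makes the objective path monotone non-decreasing by
construction (asserted per run). Degenerate cases are defined explicitly:
an all-zero BCSS vector yields uniform weights shrunk into both constraint
balls, and tied maximal BCSS values that make the l1 bound unreachable by
thresholding fall back to the first maximal gene alone.

The l1 bound s is tuned by the gap statistic: gap(s) = log O(s) − mean_b
log O*_b(s) over B datasets with each gene's values permuted independently
across samples (default B = 5, grid of 12 points geometric between 1.2 and
√p). The gap rises steeply while the dominant gene block accumulates weight
and then plateaus; the smallest s whose gap is within one standard error of
the maximum is selected, and exact ties resolve to the smallest s. On
structureless data the gap curve is flat up to Monte-Carlo noise, and the
tie rule returns a low grid value in the majority of runs — the loop-level
safeguard against null data is the PAC stopping rule below, not the tuner.

## Consensus clustering, PAC and the number of groups

For each candidate k, samples are subsampled without replacement (80% by
default), clustered by a single stochastic k-means++ run, and the consensus
matrix entry (i, j) is the fraction of co-clusterings among co-samplings
(resampling is extended, up to 10×, until every pair has been co-sampled).
The single-init stochastic clusterer is deliberate: subsampling plus
seeding noise is the perturbation that makes under-fitted k visible — with
a best-of-many clusterer an under-fitted merge of two true groups becomes
deterministic and its consensus spuriously crisp. PAC (proportion of
ambiguous clustering) is the fraction of off-diagonal consensus entries
strictly inside (0.1, 0.9); the consensus-CDF area and its relative
delta-area are reported as diagnostics. The number of groups is the k with
minimal PAC, ties to the smaller k. PAC above the no-structure threshold
(default 0.3) at the best k flags the absence of reproducible structure.

## Layer peeling and merging

Each round: tune s, fit sparse k-means with k = 2 (the cheapest structure
detector), take the strictly-positive-weight genes as the layer's gene set,
consensus-cluster the samples on those genes to fix the layer's k and
partition, then delete the genes and repeat. Because a layer must be a
*proper* gene subset, a tuned bound that zeroes nothing is stepped down the
tuning grid until soft-thresholding bites. The loop stops when fewer than
`min_genes` (20) genes are selected, after `max_layers` (9) rounds, when
the best PAC exceeds the no-structure threshold, or when the tuning gap
never exceeds `gap_threshold` (0.5 nats). The gap stop exists because the
PAC flag alone is circular on structureless data at realistic sample
sizes: sparse k-means selects exactly the genes that support one noise
split, and consensus clustering on those genes faithfully reproduces that
split (PAC well under 0.3 at n = 400). The permutation gap is computed on
all remaining genes *before* selection and is immune to this — signal
rounds measure gaps of roughly 1.2–2.0 nats, exhausted/noise rounds
−0.2–0.35 — so on a null cohort the first round stops the loop and no
layer is emitted.

Layers whose sample partitions agree (ARI ≥ 0.6) are merged with
transitive closure; a merged layer's gene set is the union of its members'
and its final partition and k are re-derived by consensus clustering on
that union. Redundant layers — two gene blocks driven by the same latent
factor — therefore collapse into one, while statistically orthogonal
layers stay separate.

## SAM differential expression

Two-class d is the mean difference over (pooled SE + s0); multiclass d is
√[Σ_k n_k(x̄_k − x̄)²/(K−1)] over (pooled SE + s0), with the pooled SE on
the scale of a class-mean contrast. The fudge factor s0 follows Tusher's
rule: the percentile of the gene-wise scatters (grid 0, 5, …, 100)
minimizing the coefficient of variation of the window-wise MADs of d. The
null distribution comes from label permutations — all distinct splits when
their number is below `n_perms`, otherwise sampled. Significance uses the
standard order-statistic rule: sort d, compare with the permutation-mean
order statistics d̄, and find the first crossings |d − d̄| > Δ from the
middle outward. Two numerical choices matter:

- **Cut placement.** The cuts sit at the midpoint of the margin between
  the first called and last uncalled gene, not on the calling gene itself.
  Evaluating permutation exceedances exactly at an observed order statistic
  understates the false-call count for the gene that defined the cut; the
  midpoint removes that selection bias without changing the called set.
- **FDR summary.** The estimated FDR at Δ is π0 · (mean permutation
  false-call count) / #called, and Δ is the smallest value with FDR at or
  below the target (default 5%). The integer-valued *median* false-call
  count collapses to zero for one-to-three-gene call sets and certifies a
  spurious gene on about half of null datasets; the mean does not, and
  `fdr_method="median"` remains available for comparison.

With these defaults, null datasets (200 genes, n = 10 + 10) produce zero
significant genes at FDR 5% in ≥ 95% of replicates while 2-SD spikes at
n = 30 + 30 are recovered with recall ≈ 1 and empirical FDR ≈ 2%.

## Rank statistics and enrichment

Kruskal–Wallis H is tie-corrected (scipy); Dunn's pairwise z uses the
rank-sum form with the tie term Σ(t³ − t)/(12(N − 1)) and Bonferroni
adjustment by default (Benjamini–Hochberg optional). Overrepresentation of
a gene list in named gene sets is the upper-tail hypergeometric probability
within the analysis universe, BH-adjusted across sets; the winning label
needs an overlap of at least 3 genes.

## Survival

Kaplan–Meier curves (simultaneous decrements at tied event times, Greenwood
variance) and the K-group log-rank chi-square delegate to lifelines. The
hazard ratio is Mantel–Haenszel, HR = (O₁/E₁)/(O₀/E₀) from the log-rank
observed/expected table computed in-package, with
CI = exp(ln HR ± 1.96·√(1/E₀ + 1/E₁)); a Cox partial-likelihood estimate
(Efron ties) is available alongside and agrees within ~15% on cohorts with
adequate events. All p-values are two-sided.

## Synthetic cohorts

The generator plants the structure the workflow assumes: gene blocks driven
by a binary adhesion factor, a binary immune factor, and a 4-level
molecular factor; background noise genes; additive per-batch gene offsets;
exponential survival whose hazard depends on the adhesion group, censored
at a follow-up horizon. Factors are sampled independently of each other and
of batch, so the planted layers are statistically orthogonal — the property
the peeling loop needs to separate them. Group prevalences default to
454:351 (adhesion), 364:441 (immune), 221:137:300:147 (molecular) and
cohort sizes 177:62:566, scaled to n, so synthetic runs are structurally
comparable to a three-cohort colorectal series of 805 tumors.

Group codes are ±1 for the binary factors and centered one-vs-rest marker
contrasts for the 4-level factor (each molecular sub-block up-regulated in
its own group), matching how molecular subtypes present in real cohorts —
stem-cell, Wnt, metabolic and extracellular groups each carry their own
marker genes. All codes are normalized to unit variance across levels so
that an effect size δ means the same thing for every layer: gene g in a
block gets loading β_g ~ N(δ_L, 0.2²) on its factor's code, in units of the
residual SD σ = 1. Defaults: n = 400 samples, 3 batches, 600 genes
(120 adhesion, 100 immune, 4 × 30 molecular, 260 noise), δ =
(1.5, 1.2, 1.0) for adhesion/immune/molecular, batch offset SD 0.5.
Survival defaults: baseline hazard 0.004 events/month, adhesion-high log
hazard ln 2.4, censoring at 60 months — event fractions of roughly 20% and
40% in the low and high groups, enough events for a stable hazard-ratio CI
at n = 400 while keeping the relapse rate realistic for resected disease.

What the generator does **not** emulate: probe-level microarray noise
(saturation, spatial artifacts), correlated layer factors, non-proportional
hazards, informative censoring, or annotation ambiguity in probe-gene maps.
Passing tests therefore establish that the pipeline recovers planted
additive block structure and group-dependent exponential hazards at
realistic sizes — not that real cohorts satisfy those assumptions.

## Problem sizes used in the test and acceptance runs

Oracle checks run at enumeration scale (4–6 genes, 16 labeled trees, all
≤ 6-vertex graphs, all 20 label splits of a 3 + 3 design). Clustering
recovery runs at n = 200 samples, 120 genes (single stage) and n = 400,
600 genes over 10 seeds (full peeling); consensus clustering uses 60–100
resamples in these runs — enough for PAC decisions at the planted
separations — while the library default remains 1000 for production use.
SAM operating characteristics use 100 null replicates and 20 spiked
replicates with 80–100 permutations; hazard-ratio coverage uses 100 cohorts
of n = 400. These sizes are the package's own verification scales, chosen
so the whole suite replays quickly while every property is measured at the
scale its claim names.

## Known limitations

- The forward search's chordality test is quadratic per candidate edge;
  building networks over thousands of genes requires bounding `max_edges`
  (the default distance-≤2 candidate scope mitigates but does not remove
  this).
- The gap-statistic tie rule is Monte-Carlo noisy on structureless data;
  the peeling loop's PAC threshold, not the tuner, is the guard against
  fabricating layers from noise.
- ARI-based layer merging cannot reunite fragments of a factor whose
  fragments induce genuinely different partitions (e.g. single-level
  marker subsets of a multi-level factor); recovery of such factors relies
  on the selection step capturing their blocks jointly.
- The Mantel–Haenszel CI is asymptotic; with very few events (a handful of
  relapses per group) its coverage degrades and the Cox alternative is no
  better.
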