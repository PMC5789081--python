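# Methods

This note documents the models, parameters, numerical choices and known
limitations of the pipeline. It describes what the code computes; every
empirical claim here is reproduced by the test suite or by
`scripts/acceptance.py`.

## Differential expression

Each treatment condition is contrasted against the **time-matched control**
at every timepoint, one contrast per timepoint. Within a contrast, for gene
g with group sizes n_A, n_B (≥2 each) and residual degrees of freedom
df = n_A + n_B − 2:

* pooled variance s²_g from both groups;
* an empirical-Bayes prior (d₀, s₀²) fitted **per contrast** across all
  genes (the per-timepoint layout keeps contrasts independent; a shared
  linear model across timepoints would borrow information between contrasts
  that the per-timepoint DE definition does not assume);
* posterior variance s̃² = (d₀s₀² + df·s²_g)/(d₀ + df);
* t_g = log2FC_g/(s̃_g √(1/n_A + 1/n_B)), two-sided p from t(df + d₀), the
  standard normal when d₀ = ∞; BH adjustment across genes within the
  contrast.

**Prior estimation.** With z = log s², the scaled-F marginal gives
E[z] = log s₀² + ψ(df/2) − log(df/2) − ψ(d₀/2) + log(d₀/2) and
Var[z] = ψ′(df/2) + ψ′(d₀/2). We solve ψ′(d₀/2) = Var̂[z] − ψ′(df/2) by a
Newton iteration on the trigamma inverse and back out s₀² from the location
equation. When the empirical dispersion is at or below the theoretical
minimum ψ′(df/2) — which happens in roughly half of genuinely homoscedastic
datasets by sampling noise alone — the prior is treated as exact: d₀ = ∞
and s₀² = exp(mean(z) − ψ(df/2) + log(df/2)), the d₀→∞ limit of the
location equation. Using the *raw* geometric mean here would be biased low
by exp(ψ(df/2) − log(df/2)) (a factor 0.56 at df = 2), inflating every
t-statistic and destroying FDR control; the corrected form keeps the
empirical FDR at the nominal level (measured ≈0.04–0.07 at nominal 0.05
with duplicate arrays).

**DE definition.** |log2FC| > 0.5 *and* adjusted p < 0.05, both required.
The thresholds are configuration (`DEConfig`); the defaults are the
conventional choices for two-replicate microarray time courses. "Early"
response = DE at any of 2/4/8 h (union semantics), "late" = DE at 24 h;
the sets may overlap.

**Moderation at n = 2.** With duplicate arrays the moderated t can be
slightly anti-conservative; the planted-truth tests bound the empirical
FDR at ≤ 0.10 rather than 0.05 for this reason, and measure ≈ 0.05.

## Clustering and the choice of K

Profiles are per-gene z-standardized log2FC vectors across timepoints
(constant rows map to all-zero rows). Standardization makes clustering
scale-free but identifies "rises late" with "falls early" up to shape —
see the generator notes below. The clustered quantity is the log2FC
profile, not absolute expression: the partition should group *response
shapes*, and fold change is the response.

Hierarchical clustering uses Euclidean distance with Ward-type
squared-distance linkage (the ward.D2 convention) and the tree is cut at
exactly K groups. k-means and a compact fuzzy c-means (hardened by maximum
membership) are provided for score comparison; hierarchical is the final
method because it gives genes singular cluster membership and is fully
deterministic.

**Partition score.** For each cluster, every TF's target set is tested for
over-representation by Fisher's exact test against the clustered genes as
background (the partition only covers DE genes, so the array-wide
background would misstate the sampling frame; it is available by flag).
The partition score is the mean over clusters of the best −log10 p, and
scores are normalized across candidates so the best (method, K) scores 1.0.
A "fraction of clusters with ≥1 enriched TF set at p < α" score is exposed
as an option (`score_method="fraction_enriched"`), but it is *not* the
default: a merged or split cluster still contains an over-represented
target set, so the fraction saturates at 1.0 across a wide range of K and
cannot select the cluster number; the mean −log10 p score peaks where
whole target sets are isolated. If no candidate shows any knowledge-base
signal, the midpoint of the candidate list is returned with a warning.

## TF enrichment and cascade assembly

Per-cluster TF enrichment is Fisher's exact test of each TF's targets in
each cluster, flagged at **uncorrected p < 0.05**; pathway
over-representation on GMT collections is BH-corrected at **FDR < 0.05**.
The asymmetry is deliberate and preserved from how the two analyses are
conventionally thresholded: TF enrichment feeds a rule-based graph where
downstream conditions (membership, regulatory support) provide the real
specificity filter, while pathway ORA is a stand-alone multiple-testing
problem.

Cascade rules, in order:

1. candidate upstream TFs per cluster = enriched TFs (p < α);
2. **TF-TF filter**: a cascade requires one TF to regulate another, so a
   candidate is retained only if it participates in a qualifying TF→TF pair
   (A enriched, B a knowledge-base target of A that is itself a TF; in the
   default strict mode B must additionally be DE in a cluster where A is
   enriched, so the pair is supported by the data). *Both* members of a
   pair are retained — the target side of a pair is exactly the connector
   situation. A permissive flag relaxes the in-cluster requirement to "any
   knowledge-base target that is a TF";
3. membership edges cluster → TF for every DE TF assigned to a cluster;
4. **connectors**: TF B links cluster I → II when B is DE in (a member of)
   cluster I, a target of some retained TF upstream of I, and enriched in
   II. Self-connectors (I = II) are annotated separately and never counted
   as connectors. Regulatory TF→TF edges record the knowledge-base edges
   justifying each connector.

Enriched TFs that are not themselves DE appear as upstream-only nodes
(regulated by other means than transcript abundance). Connector search is
exhaustive over (TF, cluster pair); cluster counts are small (K ≈ 6–12), so
no pruning is needed. The test suite verifies every emitted connector with
an independent brute-force enumerator.

Exports: Cytoscape SIF (edge type as interaction label) plus node/edge
attribute TSVs, GraphML, and a three-file TSV bundle (nodes, edges,
connectors) that round-trips.

## Input handling

* Expression TSV (first column `gene`) + sample sheet TSV
  (`sample_id, condition, time_h, replicate`); values are assumed already
  log2-scale and normalized — array preprocessing is upstream of this
  package. Doubles are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-exact.
* Probe-level tables are collapsed to one row per gene by the **per-sample
  median** across the gene's probes (default), which preserves sample-wise
  temporal structure for downstream clustering. The literal alternative —
  pick the single probe whose across-sample average is the median of the
  probe averages — is available as `method="median_average_probe"`; the
  phrase "median of the average expression" is genuinely ambiguous between
  the two readings.
* Knowledge base TSV (`tf, tg, rank`): edges above `max_rank` (default 2,
  i.e. the top evidence tiers) are dropped; duplicate pairs keep the best
  rank. Gene identifiers are case-preserved and matched exactly.
* Gene sets: standard GMT; sets below `min_size` (default 30 for signature
  analyses) are dropped and membership is deduplicated.

## Statistics details

* `fisher_overrep`: one-sided P(X ≥ k), X ~ Hypergeometric(N, m, n), via
  the survival function; validated against exact integer enumeration to
  1e−10 for all margins with small populations and randomized margins up
  to N = 60.
* `yates_chi_squared`: χ² = N(max(|ad−bc|−N/2, 0))²/((a+b)(c+d)(a+c)(b+d)),
  clamped at zero when the continuity correction exceeds |ad−bc|; 1 df.
  Degenerate cross-condition comparisons (0 DE vs 0 DE) are reported as
  χ² = 0, p = 1 by the bookkeeping layer rather than erroring.
* `mean_rank_gene_set_test`: genes ranked ascending by the statistic
  (absolute value in mixed mode), average ranks for ties; the set's mean
  rank is referred to z = (R̄ − (N+1)/2)/√((N−m)(N+1)/(12m)), one-sided for
  up/down. The normal approximation is accurate for the set sizes used
  (m ≥ 5); its null uniformity is checked against permutation (KS). Both
  one-sided p-values are reported per cluster because cluster direction is
  the quantity of interest, with direction = the smaller one.
* Reversal analysis: a model-DE gene counts as reversed when its
  model+AO-vs-model contrast at the same timepoint is DE *with the opposite
  log2FC sign* — the full DE definition is required by default
  (`require_significance=False` relaxes to sign opposition alone). The
  Jaccard column compares the model-vs-control and model+AO-vs-control DE
  sets when the latter contrast is supplied.

## The synthetic-data generator

`simulate_study` emulates a two-replicate microarray time course: 2
replicates × 4 timepoints (2, 4, 8, 24 h) × conditions {control, drugA,
drugB, both}, with the transcriptional response concentrated in the
combined condition. Defaults: 5000 genes, 50 TFs, K_true = 6 planted
clusters of 30–50 genes, effect size 2.0 log2 units at the template peak,
Gaussian noise sd 0.25 on the log2 scale (the standard microarray
approximation; a Student-t option provides heavier tails), baseline
intensities N(7, 1). Single-drug multipliers are 0.2 so single-perturbation
peak shifts (0.4 log2 units) sit below the 0.5 DE threshold — differential
expression then concentrates in the combined condition at every timepoint,
the pattern the generator exists to emulate. A strictly positive noise
floor is enforced: zero replicate variance breaks any t-statistic.

**Templates.** The six temporal templates are combinations of a monotone
axis and a transient early/late axis, placed 60° apart on the
standardized-profile sphere. This matters: clustering standardizes each
profile, and under standardization "rises late" and "falls early" collapse
onto the same shape — naive template sets silently lose planted clusters.
Flat ±1 templates are provided for calibration studies where a constant
|log2FC| at every timepoint is wanted.

**Planted cascade.** Each planted cluster is the complete target set of one
TF (rank 1). Two chains of three clusters are wired through member TFs:
chain head A (a gene with no planted effect — an upstream-only regulator)
targets cluster 1, whose first member B is itself a TF targeting cluster 2,
whose first member C targets cluster 3. The planted connectors are
therefore (B, 1→2) and (C, 2→3) per chain. Decoy TFs receive random target
sets at ranks 1–3, so the rank filter and enrichment specificity are both
exercised. Generation is bit-reproducible under a fixed seed, and the
planted regulators are genuinely enriched under exact Fisher computation at
the generated sizes (asserted in the tests).

**What the generator does not emulate:** probe-level structure, batch and
array effects, correlated noise between genes, TF combinatorics (each
planted gene has exactly one regulator), secondary/indirect regulation, and
incomplete or wrong knowledge-base annotation beyond random decoys. Passing
the planted-truth tests therefore demonstrates correctness of the
machinery, not performance on real arrays, where noise is heavier-tailed
and the knowledge base is both incomplete and organism-mismatched.

## Validation problem sizes

The test suite and acceptance script use these study conditions:

* DE power/FDR calibration: 5000 genes, 200 planted at |log2FC| = 2, noise
  sd 0.25, duplicate arrays, 20 seeds — per-timepoint recall ≥ 0.95,
  empirical FDR ≤ 0.10 (measured ≈ 0.05).
* Cluster-number and cascade recovery: 2000 genes, 6 planted clusters,
  noise sd 0.1 (the low-noise regime where between-cluster profile distance
  dominates noise), 20 seeds — best K = 6 in ≥ 80% of seeds (measured
  20/20), ARI ≥ 0.9 at K_true (measured 1.0), connector precision and
  recall ≥ 0.9 (measured 1.0). At the study-default noise sd 0.25,
  false-positive DE genes entering the clustered union blur the partition;
  recovery there is partial by construction, not a defect of the method.
* Mean-rank calibration: 1000 genes, 1000 null sets, KS uniformity at
  p > 0.01.
* Determinism: two full pipeline runs under one seed are byte-identical
  outside the manifest (which carries wall-clock timings).

## Known limitations

* One variance prior per contrast; no shared linear model, no covariates,
  no interaction contrasts.
* The mean-rank direction test uses the normal approximation, not the exact
  Wilcoxon null; for very small clusters (<5 covered genes) the cluster is
  flagged untested.
* Cluster enrichment and cascade rules treat the knowledge base as ground
  truth; edge signs (activation/repression) are not modelled.
* The optimal-K score is a heuristic over partitions, not a likelihood;
  ties are broken toward the first candidate in scan order.
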