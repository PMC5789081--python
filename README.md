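# txcascade

Time-resolved transcriptomics analysis for perturbation studies: moderated-t
differential expression against time-matched controls, knowledge-guided
clustering of temporal profiles with enrichment-based selection of the
cluster number, per-cluster transcription-factor (TF) enrichment, and
rule-based reconstruction of a temporal **transcriptional cascade** — plus a
synthetic-data generator that plants a known cascade so every stage of the
pipeline can be validated end to end.

## The problem

A cell responding to a perturbation (oxidative stress, a drug, an
inflammatory signal) rolls out waves of transcription: immediate-early
genes first, downstream programs later. Given a gene × sample log2
expression matrix over a time course (e.g. 2, 4, 8, 24 h; two replicates;
control, two single perturbations and their combination) and a ranked
repository of experimentally validated TF → target-gene (TG) interactions,
the pipeline answers: *which genes respond and when, which temporal
programs exist, which TFs drive each program, and which TFs hand the signal
from one program to the next?*

## Methods at a glance

**Differential expression.** Per timepoint, treatment vs time-matched
control with the moderated t-statistic: per-gene pooled variances s²_g
(df residual degrees of freedom) are shrunk toward a prior (d₀, s₀²)
estimated across all genes by moment matching on log s²_g under the
scaled-F marginal s²_g ~ s₀²·F(df, d₀):

    s̃²_g = (d₀·s₀² + df·s²_g) / (d₀ + df),
    t_g  = log2FC_g / (s̃_g·√(1/n_A + 1/n_B)),   t_g ~ t(df + d₀).

A gene is DE when |log2FC| > 0.5 and Benjamini–Hochberg adjusted p < 0.05.

**Clustering with knowledge-guided K.** DE-union genes are represented by
their z-standardized log2FC profile across timepoints and clustered
hierarchically (Euclidean distance, Ward-type squared-distance linkage,
i.e. ward.D2). The number of clusters K is chosen by scanning candidates
and scoring each partition by how strongly known TF target sets co-cluster
(Fisher's exact test per (cluster, TF); partition score = mean over
clusters of the best −log10 p), normalized so the best candidate scores 1.

**TF enrichment and the cascade.** Each TF's target set is tested for
over-representation in each cluster (hypergeometric, uncorrected p < 0.05,
background = clustered genes). The cascade graph has typed edges: an
enriched TF sits *upstream* of its cluster; a DE TF is a *member* of its
cluster; a **connector** TF B links cluster I → cluster II when B is DE in
cluster I, a known target of a TF upstream of cluster I, and enriched in
cluster II. Only TFs participating in a TF→TF regulatory pair are retained
(a cascade requires one TF to regulate another).

**Comparison statistics.** Hypergeometric overlap of DE sets with curated
signature gene sets (≥30 members, fixed symbol universe, default 41220);
Jaccard index of implicated TF sets; a mean-rank gene-set test for the
up/down direction of each cluster in an external contrast; and a reversal
analysis counting model-DE genes significantly regulated in the opposite
direction by an anti-oxidant co-treatment.

## Worked example

The `analysis/` scripts run the whole pipeline on a simulated study
(5000 genes, 4 conditions × 4 timepoints × 2 replicates, six planted
temporal clusters wired into two TF-connector chains):

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_cluster_temporal_profiles.py --seed 1
python analysis/04_tf_enrichment_and_cascade.py
python analysis/05_signatures_direction_reversal.py --seed 1
```

Selected output (seed 1):

```
both: DE per timepoint {'2h': 158, '4h': 233, '8h': 229, '24h': 166}; union 236, early 236, late 166
  4 h    both vs drugA  DE  233 vs 0    chi2=236.5 p=2.26e-53
best K = 6; cluster sizes: {1: 33, 2: 45, 3: 30, 4: 49, 5: 40, 6: 39}
adjusted Rand index vs planted clusters: 1.000
TF enrichment: 9 enriched (cluster, TF) pairs; 9 TFs across 6/6 clusters
  connector G0934: cluster 4 -> cluster 3
connector recovery vs planted truth: precision 1.00, recall 1.00 (4 predicted / 4 planted)
reversal: 117/234 model-DE genes reversed by AO (50.0%); JI of DE sets with/without AO = 0.500
```

Reading the numbers: the combined condition responds far more broadly than
either single perturbation (Yates chi-squared p ≈ 1e-53 at 4 h); the
TF-target enrichment score peaks at the planted K = 6 and the partition
matches the planted clusters exactly (ARI = 1.0); the cascade rules recover
all four planted connector TFs with no false positives; and the anti-oxidant
scenario, in which half the planted effects were neutralized, is read out
as 50% of model-DE genes reversed.

The same steps are available as a CLI (`txcascade simulate | de | cluster |
enrich | cascade | compare | run-all`), with `run-all` driven by a YAML
config; see `txcascade --help`.

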