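# netprox

Network-proximity analysis of drug targets against a disease protein
signature, built for the post-myocardial-infarction (post-MI) left-ventricular
remodeling setting: given a transcriptome-derived (or curated) set of
remodeling effector proteins and the targets of standard neurohormonal
therapies — ACE inhibitors (ACE), angiotensin receptor blockers (AGTR1),
beta-blockers (ADRB1) and mineralocorticoid receptor antagonists (NR3C2) —
the package asks how close each drug's targets sit to the disease signature
inside a confidence-thresholded protein–protein interaction (PPI) network,
and whether two drugs' network mechanisms overlap. The same question applies
to any disease signature / drug-target configuration.

It is aimed at computational biologists doing drug repurposing or
mechanism-overlap triage who want every stage of that argument to be an
explicit, testable computation rather than a chain of web-service calls.

## What it computes

**Disease signature.** Two-group log2 expression data are quantile
normalized, each gene gets an empirical-Bayes moderated t-statistic: with
pooled residual variance *s²* on *df* degrees of freedom and a scaled
inverse-chi-square prior (*d₀*, *s₀²*) fitted by method of moments on
log *s²*,

    s²_post = (d₀·s₀² + df·s²) / (d₀ + df),   t = logFC / √(s²_post·(1/n_A + 1/n_B))

referred to *t*(d₀+df). P-values are Benjamini–Hochberg adjusted and the
signature is the set with adj. p < 0.01 and |log₂FC| > 0.25 (both strict).
Cross-species sets are translated by reciprocal best hits (RBH) over scored
hit tables and mapped one-to-one onto proteins.

**Network statistics.** Interactions with combined score ≥ 0.9 (STRING-style
0–1 or 0–1000 dialects) induce a network on signature ∪ targets; isolated
members are kept, so the node count is pure set arithmetic. Edge enrichment
uses the degree-product (Chung–Lu) expectation
E = Σ_{i<j} min(1, kᵢkⱼ/2m) and an upper-tail Poisson p-value computed via
the regularized incomplete gamma function.

**Proximity.** The closest set distance
d(T,S) = |T|⁻¹ Σ_{t∈T} min_{s∈S} d(t,s) is calibrated against a
degree-matched permutation null (log₂ degree bins, merged upward under 10
candidates), giving z = (d_obs − μ_null)/σ_null and an add-one empirical p.
Scoring every protein as a singleton target yields the ranked
disease-association list; mechanism overlap between drugs is the Jaccard
index of their targets' radius-1 neighborhoods.

**Modules.** The network is partitioned by K-means on a row-normalized
spectral embedding, with K selected by the elbow criterion (maximum discrete
second difference of the inertia curve).

A `simulate` module generates every input with planted ground truth
(variance-heterogeneous expression with planted DE genes, ortholog hit
tables with decoys, a stochastic-block-model interactome, a module-confined
signature with targets at controlled distances), so the whole pipeline is
testable offline.

## Worked example

```sh
netprox simulate --outdir demo --seed 7 --n-genes 1000 --n-per-group 5 \
    --effect-size 1.5 --sig-size 20
netprox run --config demo/config.yaml
```

prints

```
pipeline complete; report at demo/results/report.json
  ACEi: z=-1.061 p=0.2787
  ARB: z=-1.066 p=0.2138
  MRA: z=-1.061 p=0.2787
  beta_blocker: z=-1.061 p=0.2787
```

All four planted targets were placed one hop from the 20-protein signature,
and all four come out *closer* than degree-matched chance (negative z; a
single-protein target set caps how extreme z can get). The report shows the
signature stage recovered exactly the 20 planted proteins
(`genes_passing_filter: 20`, `signature_proteins: 20`), the induced disease
network has 24 nodes and 53 edges against 8.9 expected at random
(enrichment p ≈ 8.4e-24 in `network_stats.json`), and
`ranked_proteins.tsv` lists all 230 non-signature proteins of the
interactome by ascending z — the head of that file is dominated by proteins
adjacent to the signature module. Clustering output (`clusters.tsv`,
`inertia_curve.tsv`) partitions the disease network with the elbow-selected
K.

Every stage is also exposed as a library function or sklearn-style
estimator (`ModeratedTTest`, `ProximityScorer`, `SpectralKMeans`) and as an
individual subcommand (`de`, `orthomap`, `net`, `prox`, `cluster`).

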