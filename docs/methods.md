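# Methods

This note records the models, defaults and design choices behind each stage,
what the synthetic generators do and do not emulate, and the package's known
limitations.

## Differential expression

The expression model is the standard two-group microarray contrast on log2
intensities. Normalization is quantile normalization only: full
`neqc`-style preprocessing also includes normexp background correction,
which requires negative-control probes that the package's data model (a
plain genes × samples matrix) does not carry, so the background-correction
half is deliberately out of scope.

Gene-wise variances are modeled as draws from a scaled inverse-chi-square
prior: s²_g ~ s₀²·d₀/χ²(d₀). The hyperparameters are fitted by method of
moments on e_g = log s²_g − ψ(df/2) + log(df/2), whose mean and variance
under the model are log s₀² − ψ(d₀/2) + log(d₀/2) and ψ′(df/2) + ψ′(d₀/2);
the trigamma equation is inverted by Newton iteration. When the sample
variance of e carries no excess over the sampling term ψ′(df/2), d₀ is
flagged infinite and the moderated t reduces to a z-test against s₀². At
d₀ = 0 the pipeline reduces exactly to the pooled two-sample t-test (tested
against `scipy.stats.ttest_ind`), and the full pipeline agrees with the R
`limma` reference implementation to ~1e-8 relative on hyperparameters,
t-statistics and p-values (tested).

Signature filter: adj. p < 0.01 (Benjamini–Hochberg) and |log₂FC| > 0.25,
both inequalities strict as printed in the source protocol; "log fold
change" is read as log base 2, the microarray convention, and as an
absolute value so down-regulated genes qualify. Ties in output ordering are
broken by gene id for byte-stable files.

Power behavior worth knowing: at the variance prior (d₀ = 4, s₀² = 0.05)
and n = 4 per group, a log₂FC of 1.0 sits near the detection boundary of
this filter — sensitivity is ≈ 0.6 and essentially independent of how many
genes are tested, because the typical moderated-t p-value lands at the same
order as the BH cutoff. Sensitivity exceeds 0.9 by n = 5–6 per group or
effect ≈ 1.5. The property tests therefore pin sensitivity at effect 1.5
with n = 5; near-boundary designs should not be expected to clear 80%.

## Orthology

Reciprocal best hits over externally produced scored hit tables; no
alignment engine is embedded, so any aligner's tabular output can be used.
Queries whose top score is tied between subjects are dropped entirely —
determinism is preferred over recall, and the output is then invariant to
row order. The gene→protein step is strictly one-to-one: genes with zero or
multiple protein images and proteins hit by multiple genes are dropped (and
logged). The permissive alternative (keep first) is intentionally not a
default; collisions in curated mapping tables are usually annotation
artifacts.

## Network construction and enrichment

The interaction parser auto-detects the score dialect (any value > 1 ⇒
0–1000 integers, divided by 1000), drops self-interactions, collapses
symmetric duplicates keeping the maximum score, and applies the confidence
threshold inclusively (≥ 0.9 by default: a stated "minimum score" is
attainable). The disease network is the induced subgraph on
signature ∪ targets with isolated members retained, so
n_nodes = |signature ∪ targets| by construction (a 222-protein signature
plus four disjoint targets is always a 226-node network). The full
thresholded interactome is retained as the *universe*.

The random-edge expectation among selected nodes is the degree-product
(Chung–Lu) value E = Σ_{i<j} min(1, kᵢkⱼ/2m) with degrees and m from the
universe; it matches a Monte-Carlo given-expected-degree resampling oracle
within sampling error (tested at 10%). The enrichment p-value treats the
observed count as Poisson(E) and evaluates the upper tail through the
regularized incomplete gamma function, which is accurate arbitrarily deep
in the tail (1,062 observed at E = 275 gives p ≈ 7e-284; results below
double-precision underflow are floored at the smallest positive float).
The Poisson tail is a deliberate, reproducible substitute for whatever null
a web platform uses internally; it is validated against the printed
arithmetic it must reproduce, not claimed to be that platform's null.

## Proximity

The default set distance is the "closest" form
d(T,S) = |T|⁻¹ Σ_t min_s d(t,s) on the unweighted graph (confidence gates
edge existence; it does not weight paths). The "average" form (mean over
all pairs) is available by configuration and never smaller than the closest
form. Unreachable pairs contribute a finite penalty equal to the node
count — larger than any realisable distance, keeping scores finite and
order-correct; penalized entries are visible as d_obs equal to the node
count.

The null redraws target-sized node sets matching observed degrees by
log₂-width degree bins (degree 0 in its own bin; bins under 10 candidates
merge upward, the top bin merges downward). z-scores use the permutation
mean and SD; the empirical p uses the add-one correction (r+1)/(n+1) and
counts permutations *at least as close*, so small p means proximity. A
degenerate null (SD = 0) yields z = NaN with p still reported. Calibration:
under uniform random target placement the z distribution is centred near 0
with unit-like spread, and p is conservative at the 5% level (both tested).

In the orchestrated pipeline, drug proximity and the ranked protein list
are computed over the universe graph — "test each protein against the
signature" only discriminates when candidates outside the disease network
are admitted — while the Figure-style descriptive statistics, mechanism
overlap and clustering operate on the induced disease network. Mechanism
overlap defaults to radius 1 (direct interactors); the radius is reported
alongside the Jaccard statistic because the statistic is not comparable
across radii.

## Clustering

Nodes are embedded with the eigenvectors of the symmetric normalized
Laplacian following the trivial leading one; additional zero-eigenvalue
eigenvectors of disconnected graphs are kept, since they indicate
components. Eigenvector signs are fixed (largest-magnitude entry positive)
and rows are scaled to unit length, making the embedding deterministic and
permutation-equivariant. The embedding dimension defaults to 12, which
comfortably spans the K range searched (2–20) on the network sizes this
package addresses; the orchestrated pipeline shrinks dim and K_max when the
network is smaller.

K-means uses k-means++ with 20 restarts and a fixed seed. The elbow is the
K maximizing the discrete second difference I(K−1) − 2I(K) + I(K+1), ties
to the smallest K — a parameter-free, affine-invariant operationalization
of the otherwise informal elbow rule. On planted ten-module
stochastic-block-model interactomes (10 × 25 nodes, p_in 0.25, p_out 0.01)
this selects K = 10 and recovers the planted modules with adjusted Rand
index > 0.9 across seeds (tested).

## Synthetic data

The generators emulate exactly the features downstream stages are sensitive
to: gene-wise variance heterogeneity from the same scaled inverse-chi-square
family the estimator assumes (making hyperparameter recovery a testable
contract); planted mean shifts applied before noise; hit tables whose
planted pairs are unique mutual top hits with strictly lower-scoring
decoys; a stochastic-block-model interactome with a high-confidence score
channel (uniform [0.9, 1] so the 0.9 threshold is non-destructive, with a
noisy [0, 1] option to exercise the filter); and signature/target placement
with BFS-verified distances, failing loudly when a requested distance is
infeasible. `simulate_study` links the layers end to end: planted DE genes
are the orthologs of genes mapping one-to-one onto the planted signature
proteins.

Not emulated: probe-level artifacts, dye or batch effects, control probes,
correlated expression between genes, scale-free degree structure, or
annotation noise in mapping tables. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
models, not robustness to real-data pathologies.

Default study conditions: 2 × 4–5 samples, ~1–5% planted DE genes at log₂
effect 1.0–1.5, variance prior d₀ = 4, s₀² = 0.05, interactome of 10 blocks
× 25 nodes at p_in = 0.25 / p_out = 0.01, signature of 10–20 proteins
inside one block, four single-protein targets. Test and acceptance runs use
these desk-scale sizes (up to 20,000 genes for hyperparameter recovery, 250
nodes for network stages) so the full suite completes in a few minutes on
one CPU.

## Degenerate inputs and numerical choices

- Genes with zero within-group variance are retained, flagged, and excluded
  from the prior fit; zero posterior variance gives t = ±∞, p = 0, flagged.
- Rows with missing values are dropped at ingestion and logged.
- Quantile normalization resolves ties by averaging the mean profile over
  the tied rank span.
- Trigamma inversion: Newton iteration with asymptotic initial guesses,
  relative tolerance 1e-10.
- Trivial-eigenvalue cutoff for the Laplacian: none needed — only the first
  eigenvector is skipped by position.
- All output tables are written with fixed float formatting and sorted,
  deterministic row order; one global seed is split into per-stage seeds
  via `numpy.random.SeedSequence` and recorded in the run report.

## Limitations

- The published headline counts this pipeline's design mirrors — a
  4,737-protein expression background, 1,062 observed vs 275 expected
  connections on a 222-protein curated signature — depend on an unpublished
  literature-curated protein list and on the version of an external
  interaction database, and are not reproducible from first principles
  here. The package asserts only their internal arithmetic (node-count set
  arithmetic; the Poisson tail of 1,062 vs 275).
- The ranked-association machinery replaces an unpublished neural-network
  scoring scheme with a transparent permutation-calibrated shortest-distance
  statistic; it reproduces the described output behavior (a
  shortest-distance-based ranked list), not the original model's scores.
- Which expression contrast (timepoint vs control) defines the signature in
  multi-timepoint designs is a user decision; the package models the
  two-group contrast.
- Proximity z-scores for single-protein target sets have limited resolution
  (|T| = 1 caps how extreme the permutation z can get); conclusions about
  single-target drugs should lean on ranks and empirical p across drugs
  rather than z magnitude alone.
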