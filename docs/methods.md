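# Methods

This note records the model, the numerical conventions and the design choices
behind `grnloop`, in the order the pipeline runs.

## Inputs and identity conventions

Expression matrices are genes × samples log2 intensities in TSV form with a
two-column sample → phenotype sidecar (`diseased` / `control`); missing values
are rejected rather than imputed, because the pipeline is defined on complete
normalized matrices. Gene identity is the case-sensitive symbol string — no
alias resolution is attempted, which keeps every stage deterministic. Probes
mapping to the same symbol are collapsed to their per-sample arithmetic mean;
rows with an empty symbol (unmapped probes) are dropped. The canonical key of
an undirected edge is the lexicographically sorted endpoint pair; every module
shares it, and network files list edges in that order so identical networks
serialize identically.

## Mutual information

Two estimators are exposed. `pearson` (default) is the Gaussian closed form
I = −½ ln(1 − r²) applied to the raw profiles; it is strictly increasing in
|r|, which is the only property the one-strongest-partner rule downstream
consumes, and r² is clamped at 1 − 1e−12 so perfectly correlated profiles map
to a large finite value. `empirical` is the maximum-likelihood plug-in sum on
equal-width-discretized profiles (half-open bins, last bin closed; default
bin count ⌈√m⌉ for m samples — the standard equal-width heuristic). Both
report nats. Zero-variance profiles get MI 0 to every partner rather than
NaN: matrices stay finite and such genes can never win an argmax. With the
`pearson` estimator the discretization parameters are accepted and ignored,
mirroring the parameter surface of the reference ensemble implementations.

## Edge significance

The null model is a pooled permutation null: each draw picks a uniformly
random gene pair and independently permutes each profile's sample order, so
the pooled MI sample approximates the no-association distribution for this
dataset's margins. The empirical p-value uses the add-one rule
p = (1 + #{null ≥ MI}) / (1 + N), and significance is Bonferroni-corrected
with factor p(p−1)/2 (all unordered pairs) at α₁ = 0.05.

One null is drawn per bagged run from the pre-bootstrap matrix and shared by
all B bootstrap C3Net calls — the null describes the dataset, and
per-bootstrap nulls would multiply the cost B-fold without changing the
test's meaning.

Because the add-one p-value has floor 1/(N+1), a null of the default size
10⁴ can never reject after Bonferroni correction once the gene count exceeds
~32. The bagged run therefore enlarges the null adaptively to
N = ⌈n_pairs/α₁⌉ − 1 draws (≈ 9 × 10⁵ for 300 genes), the smallest size at
which the floor exactly meets the corrected threshold; the user's `n_perm`
acts as a lower bound. Null generation is vectorized and chunked (10⁵ draws
per chunk) to bound memory.

## Ensemble construction

C3Net argmax ties break toward the lexicographically smallest partner symbol
(determinism). Bootstrap resampling draws samples with replacement at the
original sample count, keeping all genes. The ensemble binomial test uses
p₀ = observed mean edge density over bootstraps (self-calibrating) and
Bonferroni-corrects over the candidate-edge count at α₂ = 0.05. The
repeat-averaged ensemble runs R bagged runs on spawned RNG streams
(`Generator.spawn`), so results are reproducible from one master seed and
independent of evaluation order; absent edges average as 0, and provenance
records per-run presence. Single-run networks keep **all** input genes as
nodes (isolated where nothing was significant) — this is why the node-set
overlap between repeated runs on one dataset is structurally 100% while edge
sets fluctuate; the network-overlap statistic is intersection-over-union
after an optional `≥ cutoff` edge filter.

## Enrichment loop

Per dataset and iteration: restrict to the current seed, keep diseased
samples, infer, threshold at edge weight strictly > τ = 0.5 (the strict
inequality is the documented default; `ge` mode is available), and test the
subnetwork's **node set** with the one-sided hypergeometric tail. The
enrichment universe is the catalog universe intersected with the genes the
dataset measures — intersecting with measured genes avoids inflating
significance for platforms with narrow coverage. Significance is unadjusted
p < 0.05; no multiplicity correction is applied at this stage by design, and
the cross-dataset intersection of significant pathways acts as the de facto
filter. Pathway significance must hold in all datasets *in the same
iteration*. Each iteration re-infers on the full cumulative seed, not only
the new genes. Termination is guaranteed because the seed grows inside the
finite catalog universe; a 25-iteration guard catches misconfiguration.

Aggregation across iterations (and the consensus merge across datasets) is a
max-union: node and edge sets are unions, an edge keeps the maximum weight it
reached, provenance lists the contributing iterations/datasets. Max preserves
the strongest evidence and keeps weights in (0, 1]; the merge is associative
and commutative. The consensus enrichment background is the union of the
per-dataset universes, since the consensus mixes genes measured on different
platforms.

## Hubs and prioritization

Hub detection uses the linear-interpolation empirical quantile (the common
"type 7" estimator) of the full degree multiset, isolated nodes included, and
keeps genes strictly above it (default q = 0.95). Variant-based ranking
parses RegulomeDB-style categories (major 1–7, minor a–f for majors 1–3,
ordered lexicographically), scores each gene as the equal-weight sum of its
SNPs' per-source annotation scores (weights configurable; the sources arrive
as pre-computed numeric columns — no live annotation queries, since the
upstream snapshots are frozen), and sorts by best category, then score
descending, then symbol. The category cutoff "3" is read as ≤ 3a; curated
genes from external studies are appended regardless of the cutoff and
flagged. Pathway-category labels (comorbidity groupings and the like) are
manual curation and are accepted as an optional user file, never hard-coded.

## Synthetic data

The generator stands in for the multi-cohort microarray inputs at desk scale.
Expression: planted blocks are equicorrelated multivariate normal via a
shared latent factor, x = √ρ·z_block + √(1−ρ)·ε, which hits the target
correlation exactly in expectation and generates in O(n); off-block genes are
independent noise; values are scaled to a log2-plausible range (baseline 8,
SD 1). Block co-expression is planted in diseased samples only — the
inference stage only ever sees diseased samples, and disease-specific
co-regulation is the scenario of interest. Catalogs: one signal pathway per
block containing the block plus n_extra genes of the *next* block
(cyclically, so all signal pathways have identical size and relation to the
planted structure); the cyclic chaining is what lets the seed-expansion loop
walk from one block to the next. Decoy pathways partition the shuffled noise
pool, so the catalog universe covers every simulated gene, mirroring a
genome-wide catalog as enrichment background. Variants: Poisson SNP counts
per gene, categories drawn from a distribution skewed toward the
weak-evidence classes 4–7 (as in real annotation snapshots), exponential
non-negative source scores.

What the simulation does **not** emulate: platform/probe effects, batch
structure, outlier arrays, heavy-tailed intensity distributions, correlated
decoy pathways, and LD structure among SNPs. Passing tests therefore
demonstrate the correctness and stability of the algorithms under clean
planted structure, not performance on real cohort data.

Default study conditions used by the test suite and the reproduction script:
300 genes, four blocks of 20 at ρ = 0.8, 80 diseased / 40 control samples,
B = 25, R = 3, τ = 0.5 — a scaled-down analog of the full-size regime
(thousands of genes, B = 100, R = 10) chosen so the planted blocks are
comfortably detectable at these sample sizes. The equicorrelated design is
deliberately adversarial for edge-level stability: within a block every
partner is equally good in expectation, so bootstrap argmax nominations
wander and only a minority of pairs exceed weight 0.5. Edge-level agreement
between repeated runs is accordingly partial while node participation is
complete — the same qualitative picture the full-size regime shows.

At full scale, the corresponding stability experiment is: run the bagged
ensemble (B = 100) three times on one cohort's diseased samples restricted to
a literature seed, and compare edge sets with `network_overlap` at cutoffs
0 and 0.5 (`grnloop infer` three times, then the library call). This needs
the cohort expression download and several CPU-hours; it is documented here
rather than run in the test suite.

## Numerical and degenerate-input conventions

Hypergeometric and binomial tails come from scipy (`hypergeom.sf`,
`binom.sf`) and are cross-checked in the tests against exact rational
summation; the plug-in MI is cross-checked against an independent library
implementation. Zero-overlap enrichment reports p = 1. Empty networks are
legal everywhere (thresholding an empty network, precision of an empty edge
set is 0 by convention). Constant expression profiles discretize to a single
bin and contribute MI 0. All file formats are plain text; the edge-list
writer appends isolated nodes in a trailing section so the node set
round-trips exactly.

## Known limitations

- The Gaussian closed form for `pearson` MI is a convention; the source
  material names the estimator without a formula. Any strictly monotone
  transform of |r| yields identical networks, so the choice is inert for
  edge selection but matters if MI values are compared across estimators.
- The empirical estimator's O(p²) pairwise loop is pure Python and intended
  for small seed-restricted matrices.
- The cumulative-score arithmetic (equal source weights) is a declared
  convention; upstream scales of the annotation sources are heterogeneous
  and a user wanting calibrated weights must supply them.
- Edge-overlap semantics across more than two networks are
  intersection-over-union over all supplied networks; pairwise-average
  overlap is a different statistic and can be computed by calling
  `network_overlap` on pairs.
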