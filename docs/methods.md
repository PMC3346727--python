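# Methods

## The tests

**Two-stage random-forest pathway test (TRF-pathway).** For a pathway's SNP
set (all SNPs within a window of the pathway's gene bodies, default 20 kb,
boundaries inclusive, coordinates 1-based):

1. Grow a classification random forest on all pathway SNPs (dosage
   predictors, case/control outcome) and compute each SNP's standardized
   permutation importance `Z_j = mean_t(d_tj) / (sd_t(d_tj) / sqrt(T))`,
   where `d_tj` is tree *t*'s out-of-bag (OOB) accuracy drop after permuting
   SNP *j* within its OOB set, and `T` is the number of trees.  `Z_j = 0`
   when `sd_t(d_tj) = 0` (e.g. constant SNPs).
2. Keep SNPs with `Z_j` **strictly greater** than a threshold (default 1.64,
   the one-tailed standard-normal 5% point) and grow a second forest on
   them.  Its OOB error is the pathway score `R`.
3. Permute the case/control labels `K` times (default 2000); within each
   permutation **both** stages are re-run — selection is part of the
   statistic, which is what keeps the null distribution exchangeable and
   the test free of the selection bias a frozen stage-1 list would cause.
4. `p = (1 + #{R_i <= R}) / (K + 1)` (add-one estimator: always in
   `[1/(K+1), 1]`, ties count as at-least-as-extreme).  We chose the add-one
   form as the standard strictly-valid permutation estimator; it differs
   from the plain count by `O(1/K)`.

With no threshold the two stages collapse into the single-stage
**RF-pathway** test (one forest, its OOB error, same permutation scheme).
Setting the threshold to −∞ reproduces the RF-pathway result bit-for-bit,
because the stage-2 forest reuses the stage-1 seed and a selection equal to
the full set short-circuits to the stage-1 fit.

If no SNP clears the threshold (possible in permuted null fits), the
default `fallback_policy="all_snps"` scores that fit on the full stage-1
set — applied identically to observed and permuted data, so exchangeability
is preserved; `top_one` (keep only the highest-Z SNP) is available.

**Set-based comparator (PLINK-style).** Per-SNP 1-df allelic chi-square on
the 2×2 allele-count table (no continuity correction; monomorphic SNP →
statistic 0, p 1); greedy tag selection by significance with LD pruning at
pairwise dosage `r² >= 0.5` (ties toward the smaller column index); pathway
statistic = mean chi-square over tag SNPs with p < 0.05, or 0 if none
qualifies; significance from phenotype permutation with tagging and
statistic recomputed inside every permutation (`p = (1 + #{S_i >= S}) /
(K+1)` — larger statistic = more signal, the opposite direction to the OOB
error).  `r²` is the squared Pearson correlation of dosage vectors; it does
not involve the phenotype, so the pairwise matrix is computed once per set.
We chose the allelic (not genotypic) chi-square and phenotype-aware greedy
tagging re-run per permutation: the former is the comparator's default
single-SNP test, the latter keeps the permutation valid by symmetry.

## The forest

Implemented from scratch (no installed library exposes the scaled per-tree
permutation-importance Z, OOB majority voting with deterministic
tie-breaks, or the throughput a permutation-of-permutations study needs):

* n-out-of-n bootstrap with replacement per tree; duplicate draws are
  carried as integer sample weights (identical arithmetic, fewer rows).
* CART with Gini impurity; dosage features only need the two cut points
  `<=0` and `<=1`.  Nodes are grown to purity (`min_node_size = 1`);
  defaults `T = 500` trees, `mtry = floor(sqrt(p))` follow
  randomForest/Random Jungle conventions.
* Per node, `mtry` candidate features are sampled without replacement
  (Floyd's algorithm) from the features in *canonical order* — sorted by a
  stable 64-bit hash of the SNP identifier.  All randomness is
  counter-based (splitmix64 of key + counter), so a fit is bit-reproducible
  and **exactly invariant under permuting the SNP columns** of the input;
  importance-permutation streams are keyed by (seed, tree, SNP-id hash) for
  the same reason.
* Exact split-score ties break toward the smaller identity hash; the two
  cut points of one feature tie toward the lower cut; OOB majority-vote
  ties predict control.  If no sampled candidate yields an impurity
  decrease, all features are scanned once before declaring a leaf (matters
  only for very small stage-2 SNP sets).
* OOB error = misclassified / samples with at least one OOB vote.  The
  importance pass re-traverses only OOB samples whose decision path crosses
  the permuted SNP (tracked with per-sample feature bitmasks); other
  predictions cannot change.

`Z_j` is computed over all `T` trees, with `d_tj = 0` for trees that never
split on *j* (permuting an unused feature changes nothing).

## The simulator

Genotypes: a Gaussian-copula block model.  Each gene is one block; within a
block a latent exchangeable-correlation normal (default `rho = 0.7`, giving
mean within-block dosage `r²` around 0.4–0.5 — a realistic within-gene LD
level) is thresholded at each SNP's MAF quantile to produce a haplotype;
two independent haplotypes sum to the dosage.  Marginal HWE holds; blocks
are independent.  Non-causal MAFs are drawn once per panel from
U(0.05, 0.45); causal loci sit mid-block in distinct blocks with pinned
MAFs.

Phenotypes: logistic penetrance on dominant-coded causal indicators
(`X_i = 1` iff at least one minor allele),

    logit P(case | X) = a + b1 X1 + b2 X2 + b3 X3 + b4 X1X2 + b5 X1X3
                        + b6 X2X3 + b7 X1X2X3 [+ b_x X4]

with the intercept solved by bisection so the prevalence (average
penetrance over the 2^L HWE carrier configurations) hits its target to
1e-10.  Case-control samples come from rejection sampling to exact quotas.
Effect models: `M1` main-only (`b1..3 = 0.92`), multiplicative `M2/M3/M4`
(`b1..3 = phi`, `b4..6 = 2 phi`, `b7 = 3 phi`, `phi = 0.18/0.22/0.26`),
`null` all zero.  Scenario frames: S1 = 1000/1000 samples, 50 genes, 1038
SNPs, prevalence 1%, causal MAFs .25/.15/.15; S2 halves the samples; S3
uses 5% prevalence; S4 is a 100-gene, 1527-SNP pathway with a fourth,
main-effect-only locus at MAF .25 whose coefficient defaults to the
model's main-effect value (0.92 under M1, phi under M2–M4, 0 under the
null) — its size is a package choice, flagged as overridable.

What the generator does **not** emulate: forward-time demography
(recombination gradients, drift, allele-frequency spectra), population
stratification, genotyping error or missingness patterns, and inter-block
LD leakage.  Passing tests therefore demonstrate the tests' operating
characteristics under clean block-LD HWE data, not robustness to those
real-data complications.

## Monte-Carlo problem sizes

The full-scale study (5000 null replicates × K = 2000 permutations × two
forests per permutation on 2000×1038 data) is cluster-scale.  The package's
own evaluation runs scaled replicas; the permutation construction makes the
type-I-error property scale-free, so the scaled cells estimate the same
operating characteristic with Monte-Carlo error quantified by exact
binomial CIs:

* `scripts/acceptance.py`: 1/20 sample sizes and ~1/10 SNP panels
  (S1-style: 50/50 samples, 100 SNPs in 10 blocks; S2-style 25/25;
  S4-style 50/50 with 148 SNPs in 20 blocks and 4 loci), 60-tree forests,
  120–200 replicates per cell; K = 199 for the cell that reports the 0.01
  level (p-value grid 1/200 … 1, both levels exactly attainable) and
  K = 99 for cells reporting 0.05 only.  Rejection is `p <= level`.
* the acceptance test suite uses slightly smaller cells (80/80 and 40/40
  samples, 64–80 SNPs, 40-tree forests, K = 19–99, 80–200 replicates).

One scale floor is worth naming: the OOB error lives on a grid of
multiples of ~1/n, so at very small n the permutation scores tie heavily
and the add-one estimator (which counts ties as at-least-as-extreme)
becomes visibly conservative — at 20/20 samples the single-stage test's
rejection rate at nominal 0.05 drops to nearly zero.  This is a real
property of the method at such sizes, not an artifact of the
implementation; the evaluation cells therefore keep n >= 80, where the
grid is fine enough for rejection rates to sit near nominal.

The scaled **power** comparison (150/150 samples, 128 SNPs in 32 blocks,
3 causal blocks, 80-tree forests, K = 19) preserves the full study's
causal-gene fraction, and its ordering assertions are framed as inequality
hypotheses: they fail only on statistically significant contrary evidence
(paired one-sided sign test, alpha = 0.01).  Unlike the type-I-error
property, the *power ordering* between the two-stage and single-stage
tests is **not** scale-free.  Two effects penalize the two-stage design at
reduced scale: stage-1 retention of the causal SNPs at the 1.64 cut is
incomplete when n and the tree count are small (importance Z grows roughly
with sqrt(T) and with n), and under permutation the stage-2 refit on
whatever noise SNPs cleared the cut is optimistically biased, inflating
the null distribution the observed score must beat.  Both penalties
vanish toward the full scale (2000 samples, ~1000 SNPs, hundreds of
trees), which is where the ordering claim lives; at desk scale the
single-stage forest and the main-effects comparator can genuinely match
or exceed the two-stage test.  Measured examples at 100/100 samples,
200 SNPs: two-stage 0.43–0.66 vs single-stage 0.60–0.80 at the strongest
epistatic model, depending on tree count.  The acceptance checks therefore
verify the absence of a significant reversal rather than a strict
advantage, and this limitation is flagged here deliberately.

## Numerical and interface conventions

* Missing genotypes: per-SNP mode imputation, ties toward the smaller
  dosage; deterministic and idempotent.  (Model-based imputation is data
  preprocessing, not part of the method.)
* Phenotype coding auto-detected ({1,2} PLINK vs {0,1}), explicit override
  available; mixed codings are an error.
* Gene windows: `[start − w, end + w]`, inclusive, `w = round(kb × 1000)`;
  a SNP joins a pathway once however many of its genes it hits; strand is
  ignored.
* One user seed expands through `numpy.random.SeedSequence` into every
  per-replicate, per-permutation and per-forest seed; permutations may be
  evaluated in any order without changing results.
* Bonferroni-adjusted pathway p-values are reported but flagged
  conservative: pathways share genes, so tests are dependent.

## Known limitations

* No covariate adjustment, no stratified permutation (designs are assumed
  unstratified, as in the simulation frames).
* The stage-2 OOB error `R` is a test statistic, not an unbiased
  prediction-error estimate — stage-1 selection biases it downward;
  cross-validated error estimation is deliberately out of scope.
* Gene-size or LD corrections and gene-level scores are out of scope.
* The set-based comparator reimplements the tag-prune/mean-chi-square
  semantics, not the comparator tool's file formats or its other set-test
  variants.
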