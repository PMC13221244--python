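# Methods

## Model and procedure

The framework infers functional similarity between genes from the
correlation of their knockout-fitness profiles across cancer cell lines and
exploits the resulting network three ways: to test whether known gene sets
(pathways, driver genes) form modules; to propagate driver signal to
nearby genes; and to score drugs by how much propagated signal their
associated genes collect.

### CLR network construction

Given a gene × cell-line matrix with missing entries, the pipeline is

1. KNN imputation, k = 10. Cell lines are the observations: a missing
   value of gene g in cell line c is the mean of g over the k cell lines
   nearest to c by (nan-)Euclidean distance on shared genes. Fully missing
   genes or cell lines are an error.
2. Absolute Pearson correlation r_ij for all gene pairs. Absolute values
   keep anti-correlated partners (e.g. a negative regulator of a pathway).
   Zero-variance genes get correlation 0 and fall out at the weight filter.
3. CLR background correction. The background of gene i is the set of its
   off-diagonal correlations {r_ik, k ≠ i}; the self-correlation of 1 is
   excluded so it cannot inflate the background mean. z_ij = (r_ij − μ_i)/σ_i
   is kept when ≥ t (default 2.0, with ≥ as the comparison) and set to 0
   otherwise; σ_i uses the sample (ddof = 1) standard deviation; a constant
   background (σ_i = 0) contributes z = 0. The link weight is
   sqrt(z_ij² + z_ji²).
4. Links with weight 0 are removed and only the largest connected
   component is kept (ties between equally large components broken by the
   lexicographically smallest member gene, for determinism).

### Modularity with degree-matched nulls

Cohesiveness W_in/(W_in + W_out) uses link weights; the clustering
coefficient averages the unweighted local coefficient 2T_v/(k_v(k_v − 1))
over the set, with nodes of degree ≤ 1 contributing 0 (the denominator is
otherwise undefined). Because both statistics grow with member degree, the
observed value is Z-scored against 100 random sets that match the query
set's size and degree-bin histogram. Bins are log2-spaced (1, 2–3, 4–7, …):
exact-degree matching frequently leaves singleton bins in real networks,
while log2 bins keep the null sampleable and still track the degree
distribution; an exhausted bin falls back to the nearest non-empty one with
a warning. A null with zero variance yields an explicit undefined-Z flag
rather than an infinity.

Pathway-collection analysis converts per-pathway Z-scores to rank
percentiles (ties share the average rank), splits at the median with a
strict ">" (an even collection then splits exactly in half), and tests
over-representation of cancer-related pathways above the split with a
two-sided Fisher exact test; on the published summary counts
(186 pathways, 31 CRPs, 24 above the split) this gives odds ratio
24·86/(7·69) = 4.27, p = 1.34 × 10⁻³, with 31·93/186 = 15.5 CRPs expected
by chance. A preranked GSEA on the percentile ranking is the
threshold-free counterpart.

### Propagation

Personalized PageRank solves p = (1 − d)·v + d·Wᵀp with d = 0.85, v uniform
over the seed (driver) genes and W the weight-normalised transition matrix,
by power iteration to an L1 residual below 1e−9. The implementation
delegates to networkx's PageRank; the test suite pins it against a direct
linear solve on ≤ 50-node graphs at 1e−8.

Guided propagation (uKIN-style) runs a first PageRank from prior-knowledge
genes, converts the network to a directed graph with out-weights
w_ij = p_j / Σ_{k∈N(i)} p_k (a node whose neighbours all scored zero gets
uniform out-weights), and runs a second PageRank with restart mass
proportional to the new information (e.g. mutation frequency, normalised to
sum 1). Dangling mass goes to the restart distribution. The evaluation
harness hides a subset of known positives, seeds from a disjoint prior
subset, keeps the top-k stage-2 scores (all other genes tied at 0) and
reports the mean AUROC over iterations; negatives are all non-hidden
network genes.

Guilt-by-association scores gene g as the weighted fraction
ΣW_driver/ΣW_all of incident link weight reaching driver genes; since the
graph has no self-loops, leaving g out of the driver set when scoring g is
automatic. AUROC uses the Mann–Whitney tie convention (ties count 1/2).

### Enrichment and survival

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum
(weight 1 by default), descending scores with lexicographic tie-breaks,
gene-label permutation for the null, NES = ES over the mean same-sign
permuted ES, and the sign-stratified pooled-permutation FDR when run over a
collection. ssGSEA ranks a single sample's genes, weights hits by
rank^0.25, integrates the hit-minus-miss running sum, and divides by the
score range across samples when applied to a cohort. Driver modules are
the pathways with FDR < 0.001 and NES > 0 against the propagation ranking.
Patients are split 50/50 on their module ssGSEA score (the median patient
of an odd cohort goes to the lower group) and compared with the two-group
log-rank test (via lifelines, cross-checked against a pooled O−E/V tally
in the tests), with BH correction across cancer types.

### Drug scoring

The TC score is the root mean square of the propagation values of the
drug's in-network DAGs; out-of-network DAGs are dropped (not zero-scored)
and a drug with no in-network DAG is unscorable. Significance is the
add-one empirical p (1 + #{null ≥ observed})/(1 + n_perm) against
degree-matched random DAG sets, BH-adjusted within each cancer type;
adjusted p ≤ 0.05 calls a candidate. The add-one estimator is never zero,
so a finite permutation count bounds attainable significance: the
pipeline default is 1000 permutations, giving a minimum p of ~10⁻³ — at
100 permutations the minimum (~10⁻²) cannot survive BH adjustment unless
discoveries are plentiful, which makes sparse true signal undetectable by
construction.

The reversal-gene-expression effect uses the Zhang rank connection score:
signed magnitude ranks of both signatures on their shared genes, dot
product normalised by the maximal (descending-|rank| paired) product, so
the score lies in [−1, 1] and is antisymmetric under negating one
signature. Reversal strength is max(0, −connection); per cell line the
maximum over dose/time profiles is kept and the median across cell lines
represents the drug.

The proximity baseline is the closest-distance measure: the mean over DAGs
of the unweighted shortest-path distance to the nearest driver, Z-scored
against 1000 draws where both sets are replaced by size/degree-matched
random sets, with candidate flags at Z < −0.15, −0.1, −0.05. Distances are
unweighted deliberately — that is the baseline method's own formulation —
even though the network carries weights.

## Synthetic data: what it emulates and what it does not

`synthdata` uses a Gaussian single-factor model: each module m has latent
activity a_mc ~ N(0, 1) per cell line; member genes load with coefficient
β plus N(0, σ) noise; background genes are pure noise. The expected
within-module correlation is β²/(β² + σ²) — 0.8 at the default β = 1,
σ = 0.5, comparable to tight complexes in real screens. Missingness is
uniform at random, enough to exercise imputation. Drivers are drawn from
one designated module per cancer type; effective drugs draw DAGs from the
driver module, null drugs from the whole gene universe; drug response is
−log10 IC50 = α·z(true effect) + N(0, σ_r); patient expression loads on a
per-patient module activity whose exponential event-time rate is
λ₀·exp(γ·activity) under independent exponential censoring.

The generator deliberately omits several features of real screens: lineage-
specific essentiality covariance, copy-number artifacts, heavy-tailed and
batch-structured noise, overlapping pathway membership, and hub-dominated
degree distributions. Passing recovery tests therefore shows the machinery
is correct and calibrated under the assumed generative process, not that
real-data performance will match.

A zero-signal dataset is defined as β = 0 **and** no planted effective
drugs. Drawing "effective" drugs from the driver module at β = 0 would
still plant a detectable association — their DAGs contain literal driver
genes, which carry PageRank restart mass with no network signal at all —
so DAG/driver identity overlap is treated as signal in its own right.
Under the corrected definition the 20-repeat null calibration yields zero
candidates in ≥ 18/20 repeats; the residual exceptions are null drugs
whose random DAGs contain the single most-propagated driver gene by
chance, a real association by construction rather than a calibration
failure.

## Problem sizes and numerical choices

Recovery experiments run at 2000 genes × 80 cell lines with 5 planted
modules of 40 genes, 10 drivers, and 50 drugs (5 effective), a size at
which the CLR background, degree binning and BH correction all behave as
they do at biobank scale while a full pipeline run stays in the tens of
seconds. Propagation tolerance is 1e−9 (L1); CLR and correlation
computations are exact linear algebra; permutation counts default to 100
for modularity, 1000 for GSEA, TC significance and proximity. All
stochastic steps take explicit seeds (numpy Generator or SeedSequence
spawning inside the pipeline), making every table bit-reproducible.

Degenerate inputs fail loudly rather than silently: all-missing rows,
empty networks, isolated query sets, zero-event survival tables, constant
stratification scores and sub-minimal driver sets raise errors naming the
offending entity.

## Known limitations

- The CLR background definition excludes the diagonal; implementations
  that include the self-correlation shift μ_i upward and produce slightly
  sparser networks at the same t.
- Degree matching by log2 bin is coarse when a network's degree
  distribution is narrow (a noise network can collapse into one bin, making
  the null effectively uniform); exact-degree matching is the stricter
  alternative but is frequently unsampleable.
- ssGSEA exponent (0.25) and range normalisation follow common defaults;
  other choices change absolute scores but rarely the median split.
- The guided-propagation evaluation treats prior genes as negatives when
  they are not hidden, which slightly deflates AUROC; protocols that
  exclude them score higher.
- F1 against a positive drug set treats unlabelled drugs as negatives, so
  it underestimates precision when the label set is incomplete.
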