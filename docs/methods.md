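# Methods

## Model and procedure

`phasecall` treats a synchronized cell-cycle experiment as a gene × sample
matrix of integer counts y_gj with per-sample library sizes L_j, a phase
label per sample from the ordered cycle G1 → G1/S → S → G2 → M → G1, and a
replicate index. Counts are modeled as negative binomial,
Var(y) = μ + φμ², with a common dispersion φ per two-phase comparison.

### Quantifiable-expression gate

CPM_gj = y_gj / L_j × 1e6 on the *raw* library sizes; a gene is kept when
CPM ≥ `cpm_threshold` (default 0.075) in at least `min_samples` (default 2)
samples, both comparisons inclusive. Filtering precedes normalization so
that the gate does not depend on the normalization model; TMM is then
computed on the filtered matrix. This ordering is the conventional one for
count-based differential-expression workflows and makes the filter
invariant under joint rescaling of counts and library sizes.

### TMM normalization

For sample j against a reference r, per-gene log-ratios
M = log2((y_gj/L_j)/(y_gr/L_r)) and abundances A = ½·log2 of the product are
computed over genes positive in both samples; the 30% tails of M and the 5%
tails of A are trimmed (rank-based, double trimming); the factor is
2^(Σ M/v / Σ 1/v) with v the asymptotic binomial variance of M (inverse-
variance weighting). The reference under `auto` is the sample whose
upper-quartile count fraction is closest to the mean. Factors are rescaled
to geometric mean 1, so downstream results do not depend on the reference
choice; effective library size = L_j × factor_j. The implementation is
cross-checked in the test suite against an independent implementation of
the same recipe (edgeR's `calcNormFactors(method="TMM")`) to 1e-8 on a
frozen matrix. With fewer than ~10 genes the trimmed set can be empty; the
factor then falls back to 1.

### Exact test between two phases

Counts of the two phases are scaled to pseudo-counts at a common library
size (the geometric mean of the effective sizes). A common φ is estimated
by conditional maximum likelihood: conditioning each group of n equal-mean
NB draws on its total gives a Dirichlet-multinomial likelihood free of μ;
the summed log-likelihood is maximized on a 31-point log grid over
φ ∈ [1e-4, 4] refined by golden-section search on log φ to relative
tolerance 1e-3. Estimating per pair (2+2 samples) rather than globally
follows from testing each pair independently; a global estimate can be
passed explicitly. Below 50 genes a warning is emitted.

For a gene with rounded group totals (s_a, s_b), s = s_a + s_b, the null
conditional distribution of the split is obtained from the two group-total
NB laws (mean ∝ group size, dispersion φ/n); it is free of the mean because
both share the success parameter 1/(1+φμ). The two-sided p-value is the
probability-mass rule: the sum of P(k) over all splits k = 0…s with
P(k) ≤ P(s_a), ties included within relative 1e-12. At φ = 0 the
conditional law is binomial(s, n_a/(n_a+n_b)) and, with equal group sizes,
the rule reproduces the exact two-sided binomial test. Enumeration is O(s)
per gene with vectorized log-pmf evaluation, which is fast at desk scale;
p-values are clipped to (0, 1].

Fold changes are log2((CPM̄_to + c)/(CPM̄_from + c)) on phase-mean CPM with
prior count c = 0.5 CPM, which keeps zeros finite and shrinks low-count
fold changes; the 1.5-fold DEG threshold is applied to this shrunken value.
FDR is Benjamini–Hochberg within each pair's gene list (DEG counts are
reported per pair, implying per-pair correction).

### Phase-specific classification

Criterion 1: the gene's phase-mean CPM (TMM-effective sizes) is strictly
maximal in one phase; exact ties disqualify — "highest" is strict and ties
have measure zero outside constructed fixtures. Criterion 2: against both
circular neighbors of the peak phase, FDR < 0.05 and fold change ≥ 1.5
toward the peak, reusing the adjacent-pair tests (the predecessor pair
contributes its log2fc as-is, the successor pair with flipped sign; the
M↔G1 test thus serves both M and G1 calls). A gene is assigned its peak
phase iff both criteria hold; assignments are mutually exclusive by
construction and monotone in both thresholds. Only the two neighbor
comparisons are required — the criteria as stated do not involve
non-adjacent pairs. Phase-mean CPM is used as the expression measure for
criterion 1 for internal consistency with the filter (transcript lengths,
hence TPM, are out of scope).

### Auxiliary statistics

* Over-representation: one-sided hypergeometric upper tail
  P(X ≥ k) for overlap k between query and set within the quantifiable-gene
  universe, BH across sets; sets smaller than 3 after universe intersection
  are dropped.
* Spearman screen: tie-corrected (average-rank) correlation against an
  anchor gene; p by the t approximation for n ≥ 10 samples and exact
  enumeration of all anchor-rank permutations below that (the switch point
  trades exactness against n! growth); significance requires both p < 0.01
  and BH FDR < 0.05, conjunctively. Constant gene rows are flagged and
  excluded from the FDR.
* Survival: samples split at the median expression, ties to the low group;
  Kaplan–Meier curves and the standard log-rank χ² (1 df) via lifelines,
  verified against an explicit risk-set computation in the tests.
* 3C: interaction frequency = 2^(ΔCt_sample − ΔCt_control), a direct
  formula evaluation.

## Synthetic data

The generator emulates the synchronized design: five phases × two
replicates, NB counts with common φ, log-normal library sizes
(mean 2e6, CV 0.2), log-normal gene baselines in CPM units, and a planted
fraction of genes with a single multiplicative peak (step profile) in one
phase — the minimal structure the discrete two-criterion rule detects.
Default conditions: 5000 genes, 4% planted at 4-fold, φ = 0.05. The number
of planted genes is exact and allocated round-robin over phases; biotypes
are drawn at proportions 0.65/0.33/0.015/0.005
(protein_coding/lncRNA/pseudogene/other), mirroring the composition of a
quantifiable human transcriptome in which roughly a third of expressed
genes are long noncoding.

Baseline log2-CPM is Normal(5, 1.5) (median 32 CPM, central 95% about
4–256 CPM): the generator models a panel of moderately expressed genes so
that planted 4-fold effects sit above the detection floor of a
two-replicate exact test at 2e6-read depth, and recovery therefore measures
classifier correctness rather than sequencing power. Real transcriptomes
have a much heavier low-expression tail (genes down to the 0.075-CPM
filter boundary); phase-specific genes expressed near that boundary are
genuinely undetectable with two replicates at this depth, so passing
recovery tests here says nothing about sensitivity in that regime. The
generator also omits batch effects, smooth cyclic (cosine) profiles,
isoform structure and correlated genes; a planted step profile is exactly
the classifier's alternative hypothesis, which makes recovery an upper
bound on real-data performance.

Problem sizes used by the tests and the acceptance script — 2000 null genes
for type-I and dispersion checks, the 5000-gene default simulation for
recovery, totals ≤ 30 for the enumeration sweep — were chosen as the
smallest sizes at which the Monte-Carlo margins in the assertions are
meaningful; all complete in well under a minute each on one core.

## Numerical choices

* Exact-test enumeration works in log space with a log-sum-exp
  normalization; tie detection at relative 1e-12.
* Group totals are rounded half-up to integers for enumeration (the
  conditional law needs integer support).
* Dispersion grid bounds [1e-4, 4] cover Poisson-like to very noisy data;
  estimates at the lower bound are reported as-is (near zero).
* Strict equality defines mean ties in criterion 1; the packaged fixture
  places tie genes in adjacent phases so their rejection is robust to
  sub-ppm normalization jitter in phase means.
* Result tables are written with `%.10g` floats and stable sorts, making
  reruns byte-identical.

## Known limitations

* Common dispersion only (no tagwise/trended shrinkage, no GLM framework,
  no batch covariates); p-values on overdispersed data with gene-specific
  variability can be mildly miscalibrated.
* The exact test's discreteness makes it conservative at small totals.
* No periodicity scoring (Fourier/cosinor) or pseudotime; only the
  discrete-phase rule.
* Biotype collapse follows conventional Ensembl groupings and is
  configurable via an override table; other annotation vocabularies may
  need overrides.
* Gene identifiers are opaque strings; versioned vs unversioned Ensembl ids
  are not reconciled automatically.
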