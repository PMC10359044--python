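# Methods

This note documents the models and numerical choices behind hervscope, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where more than one defensible option existed.

## 1. The quantification model (EM reassignment)

Endogenous retroviral loci are repetitive: a sequencing fragment frequently
aligns acceptably to several insertions of the same family, so naive
counting either discards the ambiguous fragments or double-counts them.
hervscope treats the observed alignments of each fragment as draws from a
mixture over loci with unknown mixing proportions π (a simplex over the
annotated loci plus a reserved `no_feature` component for alignments that
overlap no locus).

Alignment scores are converted to relative candidate likelihoods

    L(f, k) = exp(score(f, k) / score_scale),    score_scale = 10 by default,

zero for non-candidate loci. No aligner publishes a calibrated likelihood;
any positive monotone map preserves the argmax structure, and the
exponential keeps the EM algebra standard. The E-step sets posterior
weights w(f, k) ∝ π_k · L(f, k); the M-step is the MAP update

    π_k ∝ Σ_f w(f, k) + θ/K,

i.e. a symmetric Dirichlet prior whose *total* pseudo-weight θ
(`theta_prior`, default 200,000 — large enough to dominate reassignment of
near-ties toward the overall mixture at cohort scale) is spread evenly
over the K components. Iteration stops when max |Δπ| < 1e-6 (the `tol`
knob) or after `max_iter` = 200 rounds. The penalized log-likelihood

    ℓ(π) = Σ_f log Σ_k π_k L(f, k) + (θ/K) Σ_k log π_k

is concave in π, so EM converges to the global maximum; the test suite
verifies monotone traces on random instances and agreement with a dense
grid-search oracle to 5e-3 per coordinate.

Count reduction offers three modes: `best` (argmax posterior; exact
posterior ties exclude the fragment and are reported, keeping the pipeline
deterministic without a seed), `fractional` (posterior weights), and
`unique` (single-candidate fragments only). Overlap matching is
strand-agnostic by default (`stranded` flips it); an alignment is a
candidate for every locus it overlaps by ≥ 1 bp, with the best score kept
per (fragment, locus).

## 2. Preprocessing

* **Y-chromosome removal** applies to annotated *genes* only; features
  without a gene annotation (retroviral loci among them) are retained
  regardless of their position, since the rule exists to remove
  sex-specific host-gene variance.
* **Size factors** are median-of-ratios: features with any zero are
  excluded from the geometric-mean reference. Note the estimator is
  invariant to a global rescaling of all samples (the reference absorbs
  the constant); scaling one sample by c splits the factors as
  (c^-1/2, c^1/2) in the two-sample case.
* **Batch adjustment** removes batch effects from NB counts by quantile
  matching, per feature: a source NB per (batch, condition) cell (cell
  mean; per-batch method-of-moments dispersion, floor 1e-4) and a
  batch-free target NB (condition mean pooled over batches with
  batch-size weights; pooled dispersion). Each count maps through the
  source CDF to a quantile and back through the target inverse CDF; the
  mid-quantile (average of F(y−1) and F(y)) keeps the discrete map
  approximately unbiased, zeros map to zero or near-zero, and output
  stays integral. Condition effects are retained by construction. A batch
  lacking one of the conditions makes the adjustment unidentifiable and
  is refused.
* **Adaptive filtering** binarizes size-factor-normalized counts at each
  candidate threshold and picks the threshold maximizing the mean Jaccard
  similarity over within-condition sample pairs. The candidate grid is 0
  plus the distinct positive normalized values strictly below the global
  maximum, capped at the 95th percentile and 200 points (bounds runtime;
  any dense grid gives the same optimum on realistic data). Features
  exceeding the chosen threshold in at least one sample survive.
* **VST** is log2(count / factor + 1): monotone, zero-preserving, and
  flattens the NB mean–variance relation enough for correlation and PCA
  work downstream.
* **PCA QC** is feature-centered SVD in sample space, reporting scores and
  variance-explained fractions; it is how batch structure is inspected
  before/after adjustment.

## 3. Differential expression

Per feature, an NB GLM with log link, intercept + condition coefficient,
and log size-factor offsets (factors renormalized to geometric mean 1, so
the fit is invariant to their absolute scale). Dispersion is a
method-of-moments estimate on normalized counts using the pooled
within-condition variance, floored at 1e-8, then shrunk 50/50 toward the
mean raw estimate of the feature's expression decile — a deliberately
simple stand-in for full empirical-Bayes machinery, validated by the
type-I-error simulation (null rejection at p < 0.05 lands in
[0.03, 0.07] at 10+10 samples, dispersion 0.1). The Wald statistic
coefficient/SE is referred to a standard normal; coefficients are fit on
the natural-log scale and reported as log2. All-zero features are flagged
with p = 1 and log2FC = 0; fits that fail (e.g. one group entirely zero)
fall back to a pseudo-count moment ratio and are flagged. BH step-up
controls FDR; classification uses strict inequality (q equal to the
threshold is non-significant), with defaults of 0.2 for retroviral loci
and 0.05 for genes, both exposed.

## 4. Family enrichment and locus names

Locus names follow the FAMILY_band+letter convention (`MER101_6q27d`).
Family membership comes from the annotation's family field, falling back
to name parsing; the per-family ratio is
(n_de/total_de) / (n_db/total_db), which equals 1 under proportional
sampling — that algebraic identity is the expected-ratio reference line.
An alternative reference sometimes quoted, total database size divided by
total DE count, is *not* 1 and is not a frequency ratio; we report ratios
of frequencies and the constant 1 as their null expectation. The ratios
are descriptive; an optional hypergeometric over-representation p per
family (BH-adjusted) is available behind a flag.

## 5. Proximal genes and pathway enrichment

Upstream/downstream are genomic (left/right of the locus), since
regulatory reach of an LTR is not transcript-strand-specific a priori; a
`stranded` mode flips the roles for minus-strand loci. Distances are
between interval ends; adjacency (distance 0 without overlap) is flanking,
not intersecting; ties break toward the smaller gene id. Each DE locus'
log2FC is transferred to its flanking and intersecting genes; a gene hit
by several loci keeps the largest-|score| coefficient (mean available),
on the view that the strongest nearby dysregulation dominates.

Pathway enrichment is a two-sample Wilcoxon rank-sum of member vs
non-member scores over the scored universe, two-sided: exact enumeration
over all member-set assignments when the universe has ≤ 10 scored genes,
the normal approximation with tie correction otherwise. The two-sample
member-vs-nonmember framing (rather than one-sample against all ranks) is
the standard competitive test and is invariant to monotone transforms of
the scores.

## 6. Correlation analyses

Pearson r with the exact t-test p on n−2 df, refusing zero-variance input
explicitly rather than returning NaN. Locus-level correlations are
BH-adjusted within a table, and the summary counts significant and
positive-among-significant loci; family-level analysis sums the family's
VST rows first, which dilutes signal carried by a minority of loci — the
tests quantify this dilution directly. Gene–locus association ranking
scores all gene × locus pairs by squared Pearson correlation: a
deterministic, dependency-free substitute for tree-ensemble importance
scores that preserves the contract (rank cross-class pairs by association
strength, never emit within-class pairs); the importance function is a
plug-in for users who want a model-based score.

## 7. The synthetic world

The generator states one fixed world rather than tunable difficulty:

* **Genome/annotation**: ≤ 5 chromosomes of 1 Mb; genes 3–12 kb laid with
  random gaps; loci 0.5–3 kb, ~30% intragenic by default; family labels
  drawn from a skewed weight distribution; names follow the
  FAMILY_band+letter convention with copy letters only on band collisions.
* **Fragments**: single-end, 75 bp, score 100 at the locus of origin; with
  probability `ambiguity_rate` (default 0.3) 1–3 decoy alignments at other
  loci whose score deficit is Poisson(`score_gap`), so `score_gap = 0`
  produces exact ties. Output SAM is byte-identical per seed.
* **Counts**: NB with Var = μ + αμ², baselines log-uniform on [20, 500],
  planted log2 fold changes of ± `lfc_magnitude` on a `frac_de` fraction of
  features, and a per-feature random-sign batch shift of exactly
  2^`batch_log2_shift` per batch step. The random sign matters: a
  sign-uniform multiplicative batch shift is indistinguishable from a
  library-size factor and would be absorbed silently by median-of-ratios
  normalization, leaving nothing for batch adjustment to do. Library-size
  distributions are free parameters (default 1.0 per sample).

What the generator does **not** emulate: read sequences and errors,
splicing, paired-end bookkeeping, gene-length effects, correlated
features, dropout structure, or outlier samples. A green test therefore
establishes correctness of the statistical machinery under its stated
model, not robustness to the full messiness of real RNA-seq.

## 8. Known limitations

* The dispersion estimator is moment-based with decile shrinkage, not a
  full empirical-Bayes fit; at very small sample sizes (< 4 per group) the
  Wald test will drift from nominal calibration.
* Batch adjustment assumes each batch contains both conditions; partially
  confounded designs are refused rather than approximated.
* The EM consumes alignment scores as given; garbage scores produce
  garbage proportions (`score_scale` only rescales).
* Exact pathway enumeration is limited to 10 scored genes; between ~10 and
  ~20 genes the normal approximation is conservative.
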