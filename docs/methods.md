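# Methods

## The score and its invariance

For an ordered gene pair (G_a, G_b) and a sample s, the pair score is
1 if expr[G_a, s] > expr[G_b, s] and 0 otherwise; equality scores 0 (a pair
is "on" only when its first gene is strictly higher). A signature of K pairs
gives each sample an integer score in [0, K]. Since the score consumes only
the within-sample order of two values, it is invariant under any strictly
increasing per-sample transform of the expression scale — log vs linear,
array intensity vs sequencing quantification, sample-wise scaling. The
package therefore records no expression scale and performs no normalisation.

Stratification is either by a fixed integer threshold t (high iff score > t;
the bundled 18-pair signature uses t = 9) or by the cohort median (high iff
score strictly exceeds the median; samples at the median go low, keeping the
strict-inequality convention of the fixed rule). A cohort whose scores are
all identical cannot be median-stratified and raises.

## The discovery pipeline

Seven stages, run by `discover_signature`:

1. **Clustering.** k-means (k = 2 by default, 10 seeded restarts, Euclidean
   distance) over samples, using genes as features. Cluster "A" is the one
   with the higher mean immune-gene rank when an immune list is supplied,
   else the larger cluster (ties resolved towards the cluster holding the
   lexicographically first sample). The A/B naming never changes the final
   pair set — the diversity filter accepts both orientations.
2. **Differential expression.** Per-gene Welch t-test between the clusters
   with Benjamini–Hochberg FDR control; significant iff FDR < 0.05 (default)
   and |logFC| ≥ `deg_abs_logfc` (default 0; the fold-change threshold is
   exposed but off by default).
3. **Immune list restriction** to genes present on the platform
   (case-insensitive symbol match, no alias mapping).
4. **IRDEGs**: intersection of the significant genes with the immune list.
5. **Pair enumeration and scoring.** Every IRDEG is paired with every other
   gene on the platform. When both members are IRDEGs only the canonical
   orientation (lexicographically smaller first gene) is emitted, since the
   reversed pair carries the same information for untied values; the pair
   count is m(n−1) − C(m,2) for m IRDEGs among n genes.
6. **Survival screen.** Per pair, a Mantel–Haenszel log-rank test of
   score-1 vs score-0 samples; candidates have p < 0.05. Pairs with a
   constant score or a score group of fewer than 2 samples are excluded
   outright (not assigned p = 1), so degenerate pairs cannot inflate the
   candidate set; the run report tallies them.
7. **Diversity filter.** A pair passes at diversity factor α when ≥ α of one
   cluster's samples score 1 and ≥ α of the other cluster's samples score 0
   ("≥" implements "or more"; both orientations accepted). Starting from
   α = 0.8, α is raised in 0.05 steps (capped at 1.0) while the retained set
   still reaches the signature-size cap (`max_pairs`, default 50). Final
   pairs are ordered by screening p-value, ties broken lexicographically,
   and carry the median stratification rule.

Any stage that comes up empty halts the pipeline cleanly: the signature is
`None` and the report names the stage.

### Rank-based internals

Clustering and differential expression operate on **within-sample ranks**
(midranks for ties) rather than raw values. This is a deliberate design
choice: it makes every stage — and hence the discovered signature — a
function of within-sample orderings only, so the entire pipeline inherits
the score's invariance under strictly increasing per-sample transforms
(verified bit-identically in the test-suite). Group means and log-fold-
changes in the DE table remain descriptive statistics of the supplied values
(their difference is the log fold change when the input is log-scale); with
the default `deg_abs_logfc = 0` they do not affect selection. If a non-zero
fold-change threshold is configured, that part of the selection is no longer
transform-invariant.

Two consequences of the rank representation are worth knowing:

- **Compositional spillover.** A gene can only be rank-differential by
  crossing other genes, and every crossed gene genuinely changes rank
  between the groups. DE on ranks therefore flags genes adjacent (in
  expression) to a strongly shifted gene. These extra flags are true
  positives *of the rank representation*; downstream, the diversity filter
  still isolates pairs with genuine cluster-separating order flips.
- **Cluster-then-test circularity.** k-means picks the best-separated split
  of the cohort, so DE between the resulting clusters is anti-conservative
  even on pure noise — a handful of "significant" genes on a null cohort is
  expected. The later stages are what protect specificity: across 40 null
  cohorts the pipeline produced 0 signatures (most halted before pairing,
  the rest at the survival screen or diversity filter).

## Evaluation statistics

- **Log-rank** (Mantel–Haenszel): at each distinct event time t, observed
  group-1 events are compared with d·n₁/n under the hypergeometric draw;
  χ² = (ΣO − ΣE)² / ΣV on 1 df. The implementation is vectorised over many
  binary groupings of one cohort, which is what makes screening tens of
  thousands of candidate pairs cheap. Verified against an independent
  risk-table accumulation and against `lifelines`.
- **Kaplan–Meier**: product-limit estimator; censored subjects leave the
  risk set without a step.
- **Odds ratio** on the high/low × responder/non-responder table:
  OR = ad/bc, no continuity correction (b·c = 0 raises), Woolf 95% CI
  log OR ± 1.96·√(1/a+1/b+1/c+1/d), omitted when any cell is zero.
  Reported to 2 decimals in the CLI, raw in the API.
- **Rank-sum** (Wilcoxon–Mann–Whitney, two-sided): exact enumeration for
  pooled n ≤ 20 (full permutation enumeration when ties are present),
  tie-corrected normal approximation otherwise.
- **Cox regression**: Newton–Raphson on the Breslow partial likelihood with
  internal covariate standardisation and step-halving; convergence when the
  largest score-gradient component < 1e−8 (max 50 iterations). Monotone
  likelihood (|β| escaping beyond 10 on the standardised scale) or
  non-convergence flags the fit and suppresses hazard ratios. Breslow ties
  were chosen as the simplest well-defined convention; without ties the
  estimates agree with Efron-based implementations (checked against
  `lifelines` and a grid-search maximisation of an independently coded
  partial likelihood).
- **Cross-platform concordance**: per pair, the fraction of matched samples
  with identical 0/1 score on both platforms; the summary reports the
  fraction of pairs exceeding 0.7 (configurable reporting threshold).
- **Score–marker correlation**: Spearman ρ between the signature score and
  each marker gene, BH-adjusted across testable markers; missing or constant
  markers are reported with a reason instead of a coefficient.

## The synthetic generator

`simulate_cohort` draws log2-scale expression
x[g, s] = μ_g + shift_g·1[s ∈ A] + N(0, σ²), with three gene classes:

- **Informative immune genes** (default 10): shift_g = δ (default 2),
  baselines evenly spaced with spacing 0.275·δ so that neighbouring
  informative genes do not share discriminative partners.
- **Planted partners**: one non-immune gene per informative gene, placed
  exactly midway between the informative gene's two cluster means — margin
  δ/2 on each side, so the planted pair flips orientation between clusters
  with high probability at the default σ = 0.5.
- **Weakly shifted block** (default 120 genes, shift 0.4·δ, drawn
  preferentially from the immune list): this mimics the broad
  transcriptional difference between real patient clusters. It is what the
  k-means stage clusters on and what populates the DEG/IRDEG stages, yet a
  0.4·δ shift is too small for any pair built on such a gene to pass the
  diversity filter at α = 0.8 — the best possible partner leaves a margin of
  only 0.2·δ = 0.566·σ per side, i.e. an expected one-cluster score fraction
  of Φ(0.57) ≈ 0.72 < 0.8. The planted pairs therefore remain the
  identifiable final-stage ground truth.
- All remaining genes sit in baseline bands outside every informative gene's
  discriminative window, so pairs built on them are (near-)constant across
  the cohort and are excluded by the survival screen.

Survival is exponential with hazard λ₀·exp(β·planted_score) (λ₀ = 0.02 per
month, β = 2), independently exponentially censored (rate 0.015); the
response label is Bernoulli(logistic(−1.5 + 3·planted_score)). Covariates
age/sex/stage/node are drawn independently of survival, providing null
covariates for Cox checks. Everything is reproducible from a single seed.

`apply_platform_distortion` re-measures a cohort: `monotone` applies a
per-sample strictly increasing map a + b·x^p (b, p > 0), preserving every
pair score exactly; `noisy` first adds i.i.d. Gaussian noise on the input
scale so that a pair with gap g flips with probability Φ(−|g|/(σ_n·√2)),
then applies the monotone map.

**What the generator does not emulate** — and hence what passing tests do
not show about real cohorts: realistic microarray intensity or RNA-seq count
distributions, gene–gene correlation beyond the cluster structure, any
guarantee that true prognostic pairs are identifiable (the band layout that
makes planted pairs unique ground truth has no counterpart in real data),
proportional-hazards violations, or informative censoring. Results on real
cohorts depend on the data meeting the pipeline's assumptions, not on these
tests.

## Problem sizes and numerical choices

The test-suite and the acceptance script use scaled-down cohorts chosen as
the package's own study conditions: 600 genes × 200–300 samples for recovery
and calibration runs (20 seeds for recovery; 1000 replicates for type-I
error rates; ≥1000 pairs with 10 independent permutations for the survival
screen's null candidate rate), and 250 genes × 120 samples for the
bit-identity invariance suite (20 random transforms × 3 cohorts). Duplicate
gene rows collapse by element-wise maximum by default (the mean of two
probes can invert within-sample order relative to either probe; `first` is
available). Gene symbols match case-insensitively after trimming, with no
alias mapping. Ties in expression score 0 everywhere. A score of 0 is a
valid signature score.

## Known limitations

- The fold-change filter (`deg_abs_logfc` > 0) breaks full order-invariance
  of discovery, as it must — fold changes are a property of the scale.
- The survival screen tests each pair marginally; strongly correlated pairs
  rise and fall together, and no multiplicity correction is applied at the
  screening stage (mirroring the screen-then-filter design).
- Cox regression assumes proportional hazards and numeric (binary-coded)
  covariates; no stratified or time-varying extensions.
- k-means with k > 2 is supported at the clustering stage, but the DE stage
  and diversity filter require exactly two groups.
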