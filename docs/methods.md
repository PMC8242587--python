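# Methods

This note documents the models behind each stage, the tunable parameters
that matter, the world the synthetic generator emulates (and what it does
not), and the numerical choices made where the design was genuinely open.

## Single-sample enrichment (ssGSEA)

For one sample, genes are ranked by expression descending; ties are broken
by gene identifier ascending so the ranking is deterministic across
platforms.  The gene at position *i* (1-based) carries rank value
*v* = *N* − *i* + 1.  The score of a gene set *G* is the sum over all
positions of the difference between the weighted in-set empirical CDF
(weights *v*ᵅ, normalised over the set) and the unweighted out-of-set ECDF.
The sum-over-the-walk form is used, not the max-deviation form of two-group
GSEA.  Scores are reported unnormalised; an optional post-hoc rescaling
divides every entry by the global max − min of the score matrix (a monotone
map, guarded by a flag because it is deliberately not idempotent).

* `alpha` (default 0.25): rank-weight exponent.  0 weights all set members
  equally; larger values emphasise the top of the ranking.  0.25 is the
  long-standing ssGSEA convention.
* A set covering the entire gene universe leaves the out-of-set ECDF
  undefined and is rejected; a set with no genes in the matrix is dropped
  with a warning (or rejected in strict mode).

Because the score depends only on ranks, it is invariant under any strictly
increasing per-sample transform — which is also why the FPKM→TPM conversion
(a positive per-sample rescaling) never changes downstream enrichment.

## Microenvironment scores and purity

The stromal and immune scores are the unnormalised ssGSEA scores of two
signature gene lists supplied by the caller (the canonical 141-gene lists
are not redistributed; the synthetic meta-sets stand in during testing).
Their sum is the combined microenvironment score *E*, a proxy for total
non-tumor content, and purity is the calibrated cosine

purity = cos(0.6049872018 + 0.0001467884 · *E*),

clamped to [0, 1] with a logged warning when clamping occurs (the raw
cosine leaves the valid range for extreme scores).  The constants are the
published calibration of this transform and are exposed as arguments for
recalibration; note they were fitted to a particular enrichment scale, so
absolute purity values on other scales are indicative only — downstream
use here is rank-based.

## Phenotype classification

Each gene-set row of the enrichment matrix is z-scored across samples
(constant rows dropped with a warning), and samples are clustered
agglomeratively with Ward linkage on Euclidean distance — deterministic,
with no random initialisation.  The three clusters are labelled
immune-H / immune-M / immune-L by descending mean z-scored enrichment over
all signatures; ties between cluster means are broken by cluster size,
then cluster id, and logged.  Ward linkage is the package's choice: the
source analyses state only "hierarchical clustering", and Ward is the
conventional, deterministic pick for immune-subtype work.  Whether raw or
normalised scores are clustered is immaterial here because the global
rescaling is monotone and affine; z-scoring removes it entirely.

PCA diagnostics centre feature rows and project samples on the top
right-singular directions, with each component's sign fixed so its
largest-magnitude loading is positive.

## Deconvolution

Per sample, the bulk column and each signature column are restricted to
shared genes and z-scored; non-negative weights are fitted by NNLS
(default) or by linear ν-SVR over ν ∈ {0.25, 0.5, 0.75} keeping the
lowest-RMSE fit with negative coefficients truncated.  Because the fitted
weights live on the z-scored scale (weight = fraction × σ_column / σ_bulk),
each weight is divided by its signature column's standard deviation before
renormalising onto the simplex.  This back-transform is what makes
noiseless mixtures recover exactly and keeps the result invariant to the
bulk sample's overall scale; renormalising the z-scale weights directly
would bias fractions toward high-variance cell types.  A degenerate
all-zero fit falls back to uniform fractions with a warning.  Relative
(simplex) mode only; no per-sample permutation p-value.

## Mutation statistics

* **TMB** = somatic records / capture size.  The capture size defaults to
  38 Mb (a common whole-exome figure) and is logged, since burden is only
  comparable at a fixed denominator.  All variant classes count by default;
  an include-list is available.  log₂(TMB) uses pseudocount 0, so
  zero-mutation samples are missing on the log scale rather than −∞.
* **MATH** = 100 · MAD / median of a sample's VAFs, MAD with the 1.4826
  normal-consistency factor.  Invariant under positive VAF scaling,
  undefined below 2 VAFs, 0 for identical VAFs.
* **Recurrent sites** are keyed by (chromosome, 1-based position) with a
  strict count > N threshold (N = 5 by default).
* **Contingency tests** are Pearson chi-square without continuity
  correction, expected counts from the product of margins; this exactly
  reproduces the published CGGA phenotype × IDH/type/grade statistics from
  their printed counts.

## Exhaustion (GET) signature

Each candidate gene is Pearson-correlated with the anchor gene's
expression — PDCD1 by default — across the samples of each cohort;
p-values are Benjamini–Hochberg adjusted within cohort over the candidates
actually tested there; a candidate passes at adjusted p < 0.05 and
|r| > 0.25; the signature is the intersection of passing sets across
cohorts.  Anchoring on PDCD1 expression is this package's reading of a
procedure described only as correlation against a PD-1-derived gene list;
the anchor is a parameter, and per-cohort (not pooled) adjustment is the
implemented convention.  Scoring is plain ssGSEA of the signature set with
a cohort-median split; ties go to the low group.

## Survival

Kaplan–Meier curves and the (k−1)-df log-rank test come from lifelines,
with all pairwise contrasts emitted for three groups.  Cox models maximise
lifelines' Efron partial likelihood; Efron rather than Breslow is used
because it is the only tie convention lifelines implements, and the two
coincide on the continuous-time synthetic cohorts (which have no tied event
times).  Collinear design columns are detected by a greedy rank check and
reported as NA-flagged rows rather than aborting — mirroring how published
multivariable tables mark levels confounded with another covariate — and
non-convergence flags the block instead of raising.  Categorical covariates
are dummy-coded against a stated (default first-seen) reference level.

## Drug response

Genes below the 0.2 variance quantile are removed; the rest are
standardised by training mean/sd; the ridge penalty λ is chosen to minimise
mean 10-fold cross-validated RMSE over 25 log-spaced points in [10⁻³, 10³]
(fold assignment seeded and recorded on the model); final coefficients are
the closed form (XᵀX + λI)⁻¹Xᵀy with an unpenalised intercept (the mean of
y on centred data).  Tumor samples are standardised with the *training*
parameters; model genes missing from the tumor matrix are imputed at the
training mean (standardised 0), refused below 50% gene overlap.  No
cross-cohort homogenisation beyond this standardisation is attempted.
Phenotype comparisons use one-way ANOVA or Kruskal–Wallis; in "auto" mode a
Shapiro–Wilk check (α = 0.05, per group) gates the choice.

Coefficient recovery is only identifiable when training lines outnumber
genes; the recovery tests therefore run in that regime, while the pipeline
itself accepts p > n (where ridge predictions remain defined but
coefficients are not individually interpretable).

## The synthetic world

`generate_cohort` draws, per cohort:

| quantity | default | rationale |
| --- | --- | --- |
| genes × samples | 500 × 300 | mid-sized cohort, enough genes for stable ranks |
| cell types | 5 (last one stromal), 15 markers each | disjoint marker blocks, deterministic from the config |
| marker fold | 8× | markers comparable to tumor genes in bulk, so ranks move with infiltration; much larger folds pin markers to the top of every ranking and *destroy* the signal a rank-based score can see |
| infiltration levels | 0.10 / 0.30 / 0.60 (L/M/H) | non-tumor fraction per phenotype, equal proportions |
| infiltration jitter | sd 0.02 | within-level biological spread; keeps adjacent levels ≥ 10 sd apart |
| composition | Dirichlet(10) per sample | moderately stable immune composition across tumors |
| measurement noise | exp(N(0, 0.2)) multiplicative | typical log-scale bulk noise |
| VAFs | Beta(2, 8), depth 100, alt = round(depth·VAF) | mean VAF 0.2 (impure tumors); deterministic counts keep the VAF spread equal to the Beta spread, so a near-degenerate Beta yields MATH ≈ 0 |
| survival | exponential, baseline median 24 months, hazard × (1, 1.5, 2.5) for L/M/H | high infiltration carries the worst prognosis; administrative censoring at the 75th-percentile time guarantees both events and censorings |
| cell lines | log IC50 = intercept + βᵀx + N(0, 0.1), 10 effect genes | linear response with a recorded coefficient vector |

Expression is generated on the linear scale, non-negative; log transforms
are the consumer's choice since every rank-based stage is invariant to
them.  Gene identifiers are synthetic ("G000001"…), with the five reference
exhaustion genes aliased in when the GET-recovery scenario is requested;
`generate_correlated_cohorts` builds candidates at an exact population
correlation r with the anchor for derivation testing.

What the generator does **not** emulate: platform batch effects
(microarray vs RNA-seq), gene–gene correlation beyond the mixture
structure, copy-number or subclonal structure behind the VAFs, informative
censoring, and any real drug's mechanism.  A green recovery test therefore
establishes that each estimator inverts its own generative model at
realistic noise — not that it reproduces any real cohort's values, which
would require the original data.

## Numerical conventions

- Ranking ties: stable sort by (expression desc, gene id asc).
- Duplicate gene rows on input: collapsed by per-sample maximum (logged) —
  deterministic and scale-free for rank-based use; missing values are
  rejected outright because ranks are undefined on them.
- MAF positions are 1-based inclusive; zero-depth records are excluded
  from VAF views with a warning.
- Simplex and sum identities are enforced at 1e-9; the ssGSEA
  implementation is tested against an independent direct-summation oracle
  at 1e-12 (float summation order differs between the vectorised walk and
  the loop).
- All randomness flows from integer seeds through `numpy.random.default_rng`;
  identical config + seed reproduces outputs bitwise.

## Known limitations

- Purity calibration constants are carried, not refitted; purity is
  meaningful as a ranking on other enrichment scales.
- The real 22-type leukocyte signature matrix and the 141-gene
  stromal/immune lists are not redistributed; callers supply their own.
- No consensus clustering or cluster-stability bootstrap; the three-group
  cut is taken as given.
- Published cohort-level results (hazard-ratio tables, per-drug p-values,
  the 5-gene signature itself) depend on the original TCGA/CGGA/GEO/GDSC
  data and are reproduced here only as procedure, on synthetic stand-ins —
  except the CGGA contingency statistics, which recompute exactly from
  printed counts.
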