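# immunophen

Immunogenomic phenotyping of bulk tumor cohorts, built around the analysis
style used in glioma microenvironment studies: quantify immune infiltration
from bulk expression, stratify samples into immune-high / -middle / -low
phenotypes, and characterise the phenotypes genomically and clinically.

## What it computes

- **ssGSEA** — for each sample and gene set *G* in a ranking of *N* genes
  (expression descending, rank value *v* = *N* … 1):

  score = Σᵢ [ P_in(i) − P_out(i) ],
  P_in(i) = Σ_{k≤i, g_k∈G} v_kᵅ ⁄ Σ_{g∈G} v_gᵅ,
  P_out(i) = |{k ≤ i : g_k ∉ G}| ⁄ (N − |G|),

  with rank-weight exponent α = 0.25 by default.  Rank-based, hence
  invariant to any monotone transform of a sample's values.
- **Microenvironment scores & purity** — stromal and immune signature
  scores, their sum (the combined "ESTIMATE-style" score *E*), and tumor
  purity = cos(c₀ + c₁·E) with the published calibration constants.
- **Immune phenotypes** — Ward/Euclidean hierarchical clustering of
  z-scored enrichment profiles into three clusters, labelled immune-H/M/L
  by mean enrichment; PCA separation diagnostics; Wilcoxon / Kruskal-Wallis
  score contrasts.
- **Deconvolution** — per-sample non-negative least squares (or linear
  ν-SVR) against a cell-type signature matrix, fractions on the simplex.
- **Mutation statistics** — TMB (mutations/Mb), MATH intratumor
  heterogeneity (100 · 1.4826 · median(|VAF − median|) / median),
  recurrent sites (N > 5), and Pearson chi-square contingency tests.
- **Exhausted-CD8 (GET) signature** — candidates Pearson-correlated with
  the PD-1 gene (PDCD1) per cohort, kept when BH-adjusted p < 0.05 and
  |r| > 0.25, intersected across cohorts; samples scored by ssGSEA and
  median-split.
- **Survival** — Kaplan-Meier / log-rank contrasts (overall + pairwise)
  and uni/multivariable Cox proportional-hazards tables (via lifelines).
- **Drug response** — ridge regression of log IC50 on standardised
  cell-line expression, penalty chosen by 10-fold CV, closed-form
  coefficients; predictions compared across phenotypes with an
  ANOVA/Kruskal-Wallis normality gate.
- **Synthetic cohorts** — a generator that plants purity, cell fractions,
  phenotype labels, Beta-distributed VAFs, hazard multipliers, and a linear
  IC50 model, so every stage can be tested for parameter recovery without
  any external download.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
300-sample cohort (seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_phenotypes.py
```

prints

```
cohort: 300 samples x 500 genes, phenotypes {'M': 100, 'H': 100, 'L': 100}
phenotype sizes: {'immune-H': 101, 'immune-L': 101, 'immune-M': 98}
ARI vs planted infiltration levels: 0.960
mean immune enrichment by planted level: H=117.1, L=47.2, M=83.6
immune score K-W across phenotypes: H=264.5 p=3.63e-58
```

i.e. the classifier recovers the three planted infiltration levels almost
perfectly (adjusted Rand index 0.96) and the immune enrichment score orders
the planted levels L < M < H.  Continuing with `03`–`08` adds
microenvironment scores (combined score vs planted non-tumor content,
Spearman ρ = 0.92), deconvolved cell fractions, TMB/MATH and the published
CGGA contingency statistics (e.g. the IDH-status table gives χ² = 110.855,
df = 2), the exhaustion-signature derivation (all planted PD-1-correlated
genes recovered, no false positives), survival contrasts (immune-H vs
immune-L multivariable HR ≈ 2.9, matching the planted 2.5× hazard), and
drug-response prediction (no phenotype difference planted, none detected:
ANOVA p = 0.81).

The same stages are available as a CLI (`immunophen simulate | enrich |
estimate | classify | deconvolve | genomics | get-signature | get-score |
survival | drugs | run`) and as one YAML-driven pipeline
(`immunophen run --config pipeline.yaml`) that writes a manifest with input
hashes, parameters and seeds alongside the per-stage tables.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic cohort from the seed, runs every pipeline stage on
it end to end, recomputes the published CGGA contingency statistics from
their printed counts, and writes the summary JSON.

See `docs/methods.md` for the model assumptions, parameter defaults, and
the limits of what the synthetic cohorts can establish.
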