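"""Synthetic cohorts with the statistical structure the analysis assumes.

Real immunogenomic cohorts (bulk expression + somatic mutations + clinical
follow-up) cannot be shipped, so this module generates stand-ins in which
every quantity the pipeline estimates is *planted* and returned as ground
truth:

* Bulk expression is a purity-weighted mixture of one tumor profile and a
  panel of cell-type profiles, ``x_gj = p_j T_g + (1 - p_j) sum_c f_cj C_gc``,
  multiplied by multiplicative log-normal noise.  Each cell type has a
  block of marker genes elevated by a known fold in its own profile.
* Samples carry one of three planted infiltration phenotypes (L < M < H
  mean non-tumor fraction), the quantity the immune-H/M/L classifier is
  meant to recover.
* Variant allele fractions are Beta-distributed and read counts are taken
  at fixed depth, so mutation-burden and heterogeneity statistics have
  known moments.
* Survival times are exponential with a per-phenotype hazard multiplier,
  with administrative censoring at a quantile of the drawn times.
* Cell-line training data follow a linear-in-expression log-IC50 model
  with a recorded coefficient vector.

Everything is driven by one integer seed; identical config + seed gives
bitwise-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSetCollection, MutationTable
from .get_signature import REFERENCE_GET_SIGNATURE

logger = logging.getLogger(__name__)

PHENOTYPE_CODES = ("L", "M", "H")


@dataclass
class SyntheticConfig:
    """Parameters of the generated world.

    Defaults describe a mid-sized bulk cohort: 300 samples, 500 genes, five
    cell types (the last one stromal) with 15 markers each elevated 8-fold,
    three infiltration levels (10% / 30% / 60% non-tumor content) in equal
    proportion with small within-level jitter, cell-type composition from a
    symmetric Dirichlet with concentration 10 (moderately stable
    composition across tumors), 20% multiplicative log-normal noise,
    Beta(2, 8) allele
    fractions (mean VAF 0.2, typical for impure tumors), and hazard
    multipliers 1 / 1.5 / 2.5 for L / M / H (high infiltration carries the
    worst prognosis, as seen in glioma cohorts).
    """

    n_genes: int = 500
    n_samples: int = 300
    n_cell_types: int = 5
    markers_per_type: int = 15
    phenotype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    infiltration_levels: tuple[float, float, float] = (0.10, 0.30, 0.60)
    infiltration_jitter_sd: float = 0.02
    dirichlet_concentration: float = 10.0
    marker_fold: float = 8.0
    noise_sd: float = 0.2
    vaf_beta_params: tuple[float, float] = (2.0, 8.0)
    read_depth: int = 100
    hazard_multipliers: tuple[float, float, float] = (1.0, 1.5, 2.5)
    baseline_hazard: float = np.log(2) / 24.0  # median survival 24 months at multiplier 1
    censor_quantile: float = 0.75
    plant_get_scenario: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_cell_types, self.markers_per_type) < 1:
            raise ValueError("sizes must be positive integers")
        props = np.asarray(self.phenotype_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("phenotype_proportions must be a 3-vector summing to 1")
        levels = np.asarray(self.infiltration_levels, dtype=float)
        if levels.shape != (3,) or (levels <= 0).any() or not (levels[0] < levels[1] < levels[2]):
            raise ValueError("infiltration_levels must be 3 positive scalars, strictly increasing")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("markers_per_type * n_cell_types must not exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        a, b = self.vaf_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("vaf_beta_params must be positive shape parameters")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValueError("hazard_multipliers must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    purity: pd.Series  # per sample, in [0, 1]
    fractions: pd.DataFrame  # cell type x sample, columns on the simplex
    phenotype_label: pd.Series  # "L" | "M" | "H"
    tumor_profile: pd.Series  # T_g
    cell_profiles: pd.DataFrame  # C_gc
    signature_genes: list[str] = field(default_factory=list)
    hazard_multiplier: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.fractions.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1")
        if ((self.purity < 0) | (self.purity > 1)).any():
            raise ValueError("purity out of [0, 1]")


def _gene_names(config: SyntheticConfig) -> list[str]:
    names = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    if config.plant_get_scenario:
        # alias the first markers of immune cell type 1 to the reference
        # exhaustion genes so the signature stage can be tested by name
        for i, alias in enumerate(REFERENCE_GET_SIGNATURE[: config.markers_per_type]):
            names[i] = alias
    return names


def _marker_blocks(config: SyntheticConfig) -> dict[str, list[int]]:
    """Deterministic marker-gene index block per cell type (disjoint)."""
    blocks = {}
    for c in range(config.n_cell_types):
        start = c * config.markers_per_type
        blocks[_cell_type_name(config, c)] = list(range(start, start + config.markers_per_type))
    return blocks


def _cell_type_name(config: SyntheticConfig, c: int) -> str:
    # the last planted type is the stromal compartment
    if c == config.n_cell_types - 1:
        return "stromal_cells"
    return f"immune_type_{c + 1:02d}"


def _phenotype_assignment(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic group sizes from the proportions, shuffled by the rng."""
    props = np.asarray(config.phenotype_proportions, dtype=float)
    counts = np.floor(props * config.n_samples).astype(int)
    for i in np.argsort(-(props * config.n_samples - counts)):
        if counts.sum() == config.n_samples:
            break
        counts[i] += 1
    labels = np.repeat(np.array(PHENOTYPE_CODES), counts)
    rng.shuffle(labels)
    return labels


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth, ClinicalTable]:
    """Generate one bulk cohort: expression, planted truth, clinical table.

    Expression follows the purity-weighted mixture formula exactly when
    ``noise_sd = 0``; otherwise each entry is multiplied by an independent
    ``exp(Normal(0, noise_sd))`` factor.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    samples = [f"S{j + 1:04d}" for j in range(config.n_samples)]
    type_names = [_cell_type_name(config, c) for c in range(config.n_cell_types)]

    # profiles: log-normal baselines; marker blocks elevated by marker_fold
    tumor = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes)
    cell = rng.lognormal(mean=2.0, sigma=1.0, size=(config.n_genes, config.n_cell_types))
    for c, (_, idx) in enumerate(_marker_blocks(config).items()):
        cell[idx, c] *= config.marker_fold

    labels = _phenotype_assignment(config, rng)
    level_of = dict(zip(PHENOTYPE_CODES, config.infiltration_levels))
    infil = np.array([level_of[l] for l in labels])
    if config.infiltration_jitter_sd > 0:
        infil = infil + rng.normal(0.0, config.infiltration_jitter_sd, size=config.n_samples)
    infil = np.clip(infil, 0.0, 0.95)
    purity = 1.0 - infil
    fractions = rng.dirichlet(
        np.full(config.n_cell_types, config.dirichlet_concentration),
        size=config.n_samples,
    ).T

    mixture = purity[None, :] * tumor[:, None] + infil[None, :] * (cell @ fractions)
    if config.noise_sd > 0:
        mixture = mixture * np.exp(
            rng.normal(0.0, config.noise_sd, size=mixture.shape)
        )

    expr = ExpressionMatrix(
        pd.DataFrame(mixture, index=genes, columns=samples), unit="TPM"
    )
    multipliers = pd.Series(
        [config.hazard_multipliers[PHENOTYPE_CODES.index(l)] for l in labels],
        index=samples,
        name="hazard_multiplier",
        dtype=float,
    )
    raw_times = rng.exponential(
        1.0 / (config.baseline_hazard * multipliers.to_numpy())
    )
    horizon = float(np.quantile(raw_times, config.censor_quantile))
    observed = np.minimum(raw_times, horizon)
    event = (raw_times <= horizon).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": observed,
                "event": event,
                "age": np.round(rng.normal(55.0, 12.0, size=config.n_samples), 1),
                "sex": rng.choice(["female", "male"], size=config.n_samples),
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    truth = SyntheticTruth(
        purity=pd.Series(purity, index=samples, name="purity"),
        fractions=pd.DataFrame(fractions, index=type_names, columns=samples),
        phenotype_label=pd.Series(labels, index=samples, name="phenotype"),
        tumor_profile=pd.Series(tumor, index=genes, name="tumor"),
        cell_profiles=pd.DataFrame(cell, index=genes, columns=type_names),
        signature_genes=(
            [g for g in REFERENCE_GET_SIGNATURE if g in genes]
            if config.plant_get_scenario
            else []
        ),
        hazard_multiplier=multipliers,
    )
    return expr, truth, clinical


def generate_gene_sets(config: SyntheticConfig) -> GeneSetCollection:
    """Marker set per planted cell type plus stromal and immune meta-sets.

    Marker membership is a deterministic function of the config (no rng),
    so the sets match any cohort generated from the same config.  The
    stromal meta-set holds the stromal compartment's markers; the immune
    meta-set is the union of all immune types' markers.
    """
    genes = _gene_names(config)
    sets: dict[str, list[str]] = {}
    immune_union: list[str] = []
    stromal: list[str] = []
    for name, idx in _marker_blocks(config).items():
        members = [genes[i] for i in idx]
        sets[name] = members
        if name == "stromal_cells":
            stromal.extend(members)
        else:
            immune_union.extend(members)
    sets["stromal"] = stromal
    sets["immune"] = immune_union
    return GeneSetCollection(sets)


def generate_maf(
    config: SyntheticConfig,
    mutations_per_sample: int | Callable[[np.random.Generator, int], np.ndarray] = 30,
    samples: Sequence[str] | None = None,
    hotspots: Sequence[tuple[str, int, int]] | None = None,
) -> MutationTable:
    """Generate a MAF-like mutation table with Beta-distributed VAFs.

    ``mutations_per_sample`` is either a Poisson mean (minimum 1 per
    sample) or a callable ``(rng, n_samples) -> counts``.  Read counts are
    taken at fixed depth with ``alt = round(depth * VAF)``, so the VAF
    spread comes from the Beta draw alone.  ``hotspots`` plants recurrent
    sites as ``(chromosome, position, n_records)`` triples spread over the
    cohort.
    """
    a, b = config.vaf_beta_params
    rng = np.random.default_rng(config.seed + 1)  # independent of the cohort stream
    if samples is None:
        samples = [f"S{j + 1:04d}" for j in range(config.n_samples)]
    samples = list(samples)
    if callable(mutations_per_sample):
        counts = np.asarray(mutations_per_sample(rng, len(samples)), dtype=int)
    else:
        counts = np.maximum(1, rng.poisson(float(mutations_per_sample), size=len(samples)))

    rows = []
    for sample, n_mut in zip(samples, counts):
        vafs = rng.beta(a, b, size=n_mut)
        alts = np.round(config.read_depth * vafs).astype(int)
        chroms = rng.integers(1, 23, size=n_mut)
        positions = rng.integers(1, 100_000_000, size=n_mut)
        for i in range(n_mut):
            rows.append(
                {
                    "Tumor_Sample_Barcode": sample,
                    "Hugo_Symbol": f"G{rng.integers(1, config.n_genes + 1):06d}",
                    "Chromosome": str(chroms[i]),
                    "Start_Position": int(positions[i]),
                    "Variant_Classification": "Missense_Mutation",
                    "t_ref_count": int(config.read_depth - alts[i]),
                    "t_alt_count": int(alts[i]),
                }
            )
    for chrom, pos, n_rec in hotspots or []:
        carriers = rng.choice(samples, size=n_rec, replace=n_rec > len(samples))
        for sample in carriers:
            vaf = rng.beta(a, b)
            alt = int(round(config.read_depth * vaf))
            rows.append(
                {
                    "Tumor_Sample_Barcode": str(sample),
                    "Hugo_Symbol": "HOTSPOT",
                    "Chromosome": str(chrom),
                    "Start_Position": int(pos),
                    "Variant_Classification": "Missense_Mutation",
                    "t_ref_count": config.read_depth - alt,
                    "t_alt_count": alt,
                }
            )
    return MutationTable(pd.DataFrame(rows))


@dataclass
class CellLineTruth:
    """True linear model behind the generated cell-line response."""

    coefficients: pd.Series  # per gene, zero outside the effect genes
    intercept: float
    noise_sd: float


def generate_cellline_training(
    config: SyntheticConfig,
    n_lines: int = 120,
    drug_effect_genes: int = 10,
    effect_sd: float = 0.5,
    noise_sd: float = 0.1,
) -> tuple[ExpressionMatrix, pd.Series, CellLineTruth]:
    """Cell-line expression with a linear-in-expression log-IC50 response.

    ``log IC50 = intercept + sum_g beta_g x_g + Normal(0, noise_sd)`` with
    non-zero ``beta_g`` on ``drug_effect_genes`` randomly chosen genes
    (coefficients ~ Normal(0, effect_sd)).  The true coefficient vector is
    returned so regression stages can be checked for recovery.
    """
    if drug_effect_genes > config.n_genes:
        raise ValueError("drug_effect_genes exceeds n_genes")
    rng = np.random.default_rng(config.seed + 2)
    genes = _gene_names(config)
    lines = [f"CL{j + 1:04d}" for j in range(n_lines)]
    expr = rng.lognormal(mean=2.0, sigma=0.8, size=(config.n_genes, n_lines))

    beta = np.zeros(config.n_genes)
    effect_idx = rng.choice(config.n_genes, size=drug_effect_genes, replace=False)
    beta[effect_idx] = rng.normal(0.0, effect_sd, size=drug_effect_genes)
    intercept = float(rng.normal(1.0, 0.5))
    ic50 = intercept + expr.T @ beta + rng.normal(0.0, noise_sd, size=n_lines)

    return (
        ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=lines), unit="TPM"),
        pd.Series(ic50, index=lines, name="log_ic50"),
        CellLineTruth(
            coefficients=pd.Series(beta, index=genes, name="beta"),
            intercept=intercept,
            noise_sd=noise_sd,
        ),
    )


def generate_correlated_cohorts(
    n_planted: int = 3,
    n_null: int = 2,
    r: float = 0.6,
    n_samples: int = 200,
    n_cohorts: int = 2,
    anchor_gene: str = "PDCD1",
    seed: int = 0,
) -> tuple[list[str], dict[str, ExpressionMatrix], list[str]]:
    """Cohorts for testing the correlation-filtered signature derivation.

    Planted candidates are built as ``r * anchor + sqrt(1 - r^2) * noise``
    (population Pearson correlation exactly ``r`` with the anchor); null
    candidates are independent noise.  Values live on the log2-intensity
    scale (may be negative).  Returns (candidate list, cohorts, planted
    gene names).
    """
    if not 0 < abs(r) < 1:
        raise ValueError("r must be in (0, 1) in magnitude")
    rng = np.random.default_rng(seed)
    planted = [f"PLANTED_{i + 1}" for i in range(n_planted)]
    nulls = [f"NULL_{i + 1}" for i in range(n_null)]
    cohorts: dict[str, ExpressionMatrix] = {}
    for k in range(n_cohorts):
        anchor = rng.normal(size=n_samples)
        rows = {anchor_gene: anchor}
        for g in planted:
            rows[g] = r * anchor + np.sqrt(1 - r**2) * rng.normal(size=n_samples)
        for g in nulls:
            rows[g] = rng.normal(size=n_samples)
        df = pd.DataFrame(
            rows, index=[f"P{j + 1:04d}" for j in range(n_samples)]
        ).T
        cohorts[f"cohort_{k + 1}"] = ExpressionMatrix(df, unit="LOG2_INTENSITY")
    return [anchor_gene, *planted, *nulls], cohorts, planted
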