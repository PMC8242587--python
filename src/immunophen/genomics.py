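"""Mutation-level statistics: TMB, MATH heterogeneity, recurrent sites,
and contingency-table tests across phenotypes.

TMB (tumor mutation burden) is mutations per megabase of surveyed genome;
the capture size defaults to 38 Mb (a common whole-exome convention — the
denominator is a config choice and is logged).  The MATH score measures
intratumor heterogeneity as the spread of a sample's variant allele
fractions: 100 * 1.4826 * median(|VAF - median|) / median(VAF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MutationTable
from .phenotype import PHENOTYPE_ORDER

logger = logging.getLogger(__name__)

#: MAD consistency factor for normality, fixed by the MATH convention.
MAD_CONSTANT = 1.4826


@dataclass
class TmbResult:
    """Per-sample mutation counts and burden (mutations / Mb)."""

    table: pd.DataFrame  # columns: mutation_count, tmb, log2_tmb
    capture_size_mb: float
    pseudocount: float


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with row/column labels."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if not np.array_equal(arr, arr.astype(int)):
            raise ValueError("contingency counts must be integers")
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")
        self.counts = self.counts.astype(int)


def compute_tmb(
    muts: MutationTable,
    samples: Sequence[str] | None = None,
    capture_size_mb: float = 38.0,
    pseudocount: float = 0.0,
    variant_classes: Sequence[str] | None = None,
) -> TmbResult:
    """Tumor mutation burden per sample.

    Parameters
    ----------
    muts
        Mutation table; every record counts unless ``variant_classes``
        restricts to an include-list (e.g. nonsynonymous classes only).
    samples
        Sample universe; samples absent from the table get count 0.
        Defaults to the samples present in the table.
    capture_size_mb
        Surveyed genome size in megabases (denominator of the burden).
    pseudocount
        Added inside the log2: log2(tmb + pseudocount).  With the default 0
        a sample with no mutations has log2_tmb = -inf, reported as NaN
        (missing on the log scale).
    """
    if capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be positive")
    rec = muts.records
    if variant_classes is not None:
        rec = rec[rec["Variant_Classification"].isin(list(variant_classes))]
    counts = rec.groupby("Tumor_Sample_Barcode").size()
    universe = pd.Index(samples) if samples is not None else counts.index
    counts = counts.reindex(universe, fill_value=0).astype(int)
    tmb = counts / capture_size_mb
    with np.errstate(divide="ignore"):
        log2_tmb = np.log2(tmb + pseudocount)
    log2_tmb = log2_tmb.replace(-np.inf, np.nan)
    logger.info("TMB computed over %.1f Mb for %d sample(s)", capture_size_mb, len(universe))
    return TmbResult(
        table=pd.DataFrame(
            {"mutation_count": counts, "tmb": tmb, "log2_tmb": log2_tmb}
        ),
        capture_size_mb=capture_size_mb,
        pseudocount=pseudocount,
    )


def math_score(vafs: Sequence[float]) -> float:
    """Mutant-allele tumor heterogeneity: 100 * MAD / median of the VAFs.

    MAD uses the 1.4826 normal-consistency factor.  Invariant under positive
    scaling of the VAFs; 0 when all VAFs are identical.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size < 2:
        raise ValueError("MATH needs at least 2 VAFs")
    if ((v <= 0) | (v > 1)).any():
        raise ValueError("VAFs must lie in (0, 1]")
    med = float(np.median(v))
    mad = MAD_CONSTANT * float(np.median(np.abs(v - med)))
    return 100.0 * mad / med


def math_scores_per_sample(muts: MutationTable, min_vafs: int = 2) -> pd.Series:
    """MATH score for every sample with at least ``min_vafs`` usable VAFs."""
    out = {}
    for sample in muts.samples:
        v = muts.vafs(sample)
        v = v[(v > 0) & (v <= 1)]
        if len(v) >= min_vafs:
            out[sample] = math_score(v.to_numpy())
    return pd.Series(out, name="math", dtype=float)


def recurrent_site_counts(muts: MutationTable, min_n: int = 5) -> pd.DataFrame:
    """Sites mutated in strictly more than ``min_n`` records.

    Keyed by (chromosome, 1-based position); the threshold is strict
    (count > min_n), matching the convention of reporting sites with N > 5.
    """
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    counts = (
        muts.records.groupby(["Chromosome", "Start_Position"])
        .size()
        .reset_index(name="count")
    )
    hits = counts[counts["count"] > min_n]
    return hits.sort_values(
        ["count", "Chromosome", "Start_Position"], ascending=[False, True, True]
    ).reset_index(drop=True)


def chi_square_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, upper-tail p).  Expected counts
    come from the product of the margins over the grand total; df is
    (r - 1)(c - 1).
    """
    counts = table.counts.to_numpy()
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def phenotype_feature_table(
    labels: pd.Series,
    feature: pd.Series,
) -> ContingencyTable:
    """Cross-tabulate phenotype labels against a categorical feature.

    Rows are phenotypes in L, M, H order; columns are feature levels in
    first-seen order.  Samples missing the feature are dropped with the
    exclusion count logged.
    """
    common = labels.index.intersection(feature.index)
    if len(common) == 0:
        raise ValueError("labels and feature share no samples")
    labels, feature = labels.loc[common], feature.loc[common]
    missing = feature.isna()
    if missing.any():
        logger.warning("excluding %d sample(s) with missing feature value", int(missing.sum()))
        labels, feature = labels[~missing], feature[~missing]
    level_order = list(dict.fromkeys(feature))
    row_order = [p for p in PHENOTYPE_ORDER if p in set(labels)] + [
        p for p in dict.fromkeys(labels) if p not in PHENOTYPE_ORDER
    ]
    counts = pd.crosstab(labels, feature).reindex(
        index=row_order, columns=level_order, fill_value=0
    )
    return ContingencyTable(counts)
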