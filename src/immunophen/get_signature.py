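"""Derivation and scoring of an exhausted-CD8+ T-cell (GET) signature.

Starting from a candidate list of PD-1-associated genes, each candidate is
Pearson-correlated with the anchor gene's expression (PDCD1, encoding PD-1,
by default) across the samples of each cohort.  Candidates with
Benjamini-Hochberg adjusted p < 0.05 and |r| > 0.25 pass within a cohort;
the final signature is the intersection of the passing sets across all
cohorts.  On real glioma cohorts this procedure yields a 5-gene signature
(PDCD1, CD27, ICOS, RUNX2, CXCR6).  Samples are then scored by ssGSEA of
the signature set and split into high/low groups at the cohort median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection
from .enrichment import ssgsea_scores

logger = logging.getLogger(__name__)

#: The published 5-gene exhausted-CD8 signature, for reference / defaults.
REFERENCE_GET_SIGNATURE = ("PDCD1", "CD27", "ICOS", "RUNX2", "CXCR6")


@dataclass
class GetDerivationResult:
    """Per-cohort correlation tables and the cross-cohort signature."""

    per_cohort: dict[str, pd.DataFrame]  # columns: gene, pearson_r, p, adjusted_p, passed
    final_signature: list[str]
    r_min: float
    adj_p_max: float

    def __post_init__(self) -> None:
        for name, tab in self.per_cohort.items():
            passed = set(tab.loc[tab["passed"], "gene"])
            if not set(self.final_signature) <= passed:
                raise ValueError(f"final signature not a subset of cohort {name!r} passed set")


@dataclass
class GetScoreVector:
    """Per-sample GET score with median-split high/low group."""

    scores: pd.Series
    groups: pd.Series  # "high" | "low"
    cutoff: float

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.groups.index):
            raise ValueError("scores and groups must share sample index")


def derive_get_signature(
    candidates: list[str],
    cohorts: dict[str, ExpressionMatrix] | list[ExpressionMatrix],
    anchor_gene: str = "PDCD1",
    r_min: float = 0.25,
    adj_p_max: float = 0.05,
) -> GetDerivationResult:
    """Correlation-filter candidates against the anchor gene in every cohort.

    A candidate passes in a cohort when its BH-adjusted p < ``adj_p_max``
    and |Pearson r| > ``r_min``; the final signature is the intersection of
    passing sets over cohorts.  Adjustment is within-cohort, over the
    candidates actually tested there.  A candidate absent from a cohort is
    treated as failed in that cohort (logged).  The anchor itself, if
    listed, passes trivially (r = 1).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if isinstance(cohorts, list):
        cohorts = {f"cohort_{i + 1}": c for i, c in enumerate(cohorts)}

    per_cohort: dict[str, pd.DataFrame] = {}
    passed_sets: list[set[str]] = []
    for name, expr in cohorts.items():
        if anchor_gene not in expr.genes:
            raise ValueError(f"anchor gene {anchor_gene!r} absent from cohort {name!r}")
        anchor = expr.values.loc[anchor_gene].to_numpy(dtype=float)
        rows = []
        for gene in candidates:
            if gene not in expr.genes:
                logger.warning("candidate %r absent from cohort %r; treated as failed", gene, name)
                rows.append({"gene": gene, "pearson_r": np.nan, "p": np.nan})
                continue
            x = expr.values.loc[gene].to_numpy(dtype=float)
            if gene == anchor_gene:
                r, p = 1.0, 0.0
            elif np.std(x) == 0 or np.std(anchor) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, anchor)
            rows.append({"gene": gene, "pearson_r": float(r), "p": float(p)})
        tab = pd.DataFrame(rows)
        tested = tab["p"].notna()
        adjusted = pd.Series(np.nan, index=tab.index)
        if tested.any():
            adjusted[tested] = multipletests(tab.loc[tested, "p"], method="fdr_bh")[1]
        tab["adjusted_p"] = adjusted
        tab["passed"] = (
            tested & (tab["adjusted_p"] < adj_p_max) & (tab["pearson_r"].abs() > r_min)
        )
        per_cohort[name] = tab
        passed_sets.append(set(tab.loc[tab["passed"], "gene"]))

    final = set.intersection(*passed_sets) if passed_sets else set()
    # keep candidate-list order for determinism
    final_signature = [g for g in candidates if g in final]
    return GetDerivationResult(
        per_cohort=per_cohort,
        final_signature=final_signature,
        r_min=r_min,
        adj_p_max=adj_p_max,
    )


def get_score(expr: ExpressionMatrix, signature: list[str]) -> GetScoreVector:
    """ssGSEA score of the signature set per sample, median-split into groups.

    The cutoff is the cohort median of the scores; samples at or below it
    are "low" (ties go to low), above it "high".  If every score equals the
    median the split degenerates and all samples are "low" (warned).
    """
    present = [g for g in signature if g in expr.genes]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    enrich = ssgsea_scores(expr, GeneSetCollection({"GET": signature}), on_empty="error")
    scores = enrich.scores.loc["GET"]
    cutoff = float(scores.median())
    groups = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="get_group")
    if (groups == "low").all():
        logger.warning("degenerate median split: all samples assigned to the low group")
    return GetScoreVector(scores=scores.rename("get_score"), groups=groups, cutoff=cutoff)


def correlate_scores(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform, n - 2 df) between two scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
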