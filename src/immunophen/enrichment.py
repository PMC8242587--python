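"""Single-sample gene set enrichment (ssGSEA) and microenvironment scoring.

The ssGSEA score of a gene set in one sample measures how synchronously the
set's members sit near the top (or bottom) of that sample's expression
ranking.  Genes are ranked by expression, descending, and the score is the
sum over all ranks of the difference between a weighted in-set empirical
CDF and an unweighted out-of-set one:

    score = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{k<=i, g_k in G} v_k^alpha / sum_{g in G} v_g^alpha
    P_out(i) = |{k<=i : g_k not in G}| / (N - |G|)

where v_k = N - pos_k + 1 is the rank value (top gene gets N) and alpha is
the rank-weight exponent (0.25 by convention).  Being rank-based, the score
is invariant under any strictly increasing transform of a sample's values.

The microenvironment ("ESTIMATE"-style) scores are the unnormalised ssGSEA
scores of a stromal and an immune signature; their sum is a proxy for total
non-tumor content, and tumor purity is recovered from it by a calibrated
cosine transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

#: Published calibration constants of the purity-from-ESTIMATE cosine fit.
PURITY_C0 = 0.6049872018
PURITY_C1 = 0.0001467884


@dataclass
class EnrichmentMatrix:
    """Gene-set x sample enrichment scores.

    ``normalized`` records whether the post-hoc global rescaling has been
    applied; ``alpha`` records the rank-weight exponent used.
    """

    scores: pd.DataFrame
    normalized: bool = False
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("enrichment matrix contains non-finite scores")

    @property
    def set_names(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns


@dataclass
class EstimateScores:
    """Per-sample stromal, immune and combined microenvironment scores plus purity."""

    table: pd.DataFrame  # columns: stromal_score, immune_score, estimate_score, purity

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(
            t["estimate_score"], t["stromal_score"] + t["immune_score"], atol=1e-9
        ):
            raise ValueError("estimate_score must equal stromal_score + immune_score")
        if ((t["purity"] < 0) | (t["purity"] > 1)).any():
            raise ValueError("purity out of [0, 1]")


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    on_empty: str = "drop",
) -> EnrichmentMatrix:
    """Unnormalised ssGSEA scores for every gene set and sample.

    Parameters
    ----------
    expr
        Expression matrix; only gene ranks within each sample matter.
    sets
        Gene sets; each is intersected with the matrix's gene universe
        before scoring.
    alpha
        Rank-weight exponent (>= 0).  ``alpha = 0`` weights every in-set
        gene equally; larger values emphasise top-ranked genes.
    on_empty
        What to do with a set whose intersection with the gene universe is
        empty: ``"drop"`` (warn and omit the row) or ``"error"``.

    Raises
    ------
    ValueError
        If ``alpha < 0``, a set covers the whole gene universe (the
        out-of-set ECDF is then undefined), or an empty intersection occurs
        with ``on_empty="error"``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if on_empty not in ("drop", "error"):
        raise ValueError("on_empty must be 'drop' or 'error'")

    genes = expr.genes.to_numpy()
    values = expr.values.to_numpy(dtype=float)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    memberships: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if idx.size == 0:
            if on_empty == "error":
                raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
            logger.warning("dropping gene set %r: no genes in the expression matrix", name)
            continue
        if idx.size == n_genes:
            raise ValueError(
                f"gene set {name!r} covers every gene; out-of-set ECDF is undefined"
            )
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        memberships[name] = mask

    if not memberships:
        raise ValueError("no gene set overlaps the expression matrix")

    # rank values shared by every sample: position i (0-based) gets N - i
    rank_values = np.arange(n_genes, 0, -1, dtype=float)
    weights = rank_values**alpha
    gene_sort_key = np.argsort(genes, kind="stable")  # for deterministic tie-break
    gene_rank_of = np.empty(n_genes, dtype=int)
    gene_rank_of[gene_sort_key] = np.arange(n_genes)

    out = np.empty((len(memberships), expr.n_samples), dtype=float)
    set_names = list(memberships)
    for j in range(expr.n_samples):
        order = np.lexsort((gene_rank_of, -values[:, j]))
        for s, name in enumerate(set_names):
            in_set = memberships[name][order]
            size = int(in_set.sum())
            w = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (n_genes - size)
            out[s, j] = float(np.sum(p_in - p_out))

    scores = pd.DataFrame(out, index=set_names, columns=expr.samples)
    return EnrichmentMatrix(scores, normalized=False, alpha=alpha)


def normalize_enrichment(m: EnrichmentMatrix) -> EnrichmentMatrix:
    """Rescale all scores by the global (max - min) range.

    A monotone rescaling: sample orderings within each set are preserved.
    Not idempotent — re-applying rescales again — so the ``normalized`` flag
    guards accidental double application.
    """
    if m.normalized:
        raise ValueError("enrichment matrix is already normalized")
    arr = m.scores.to_numpy(dtype=float)
    span = arr.max() - arr.min()
    if span <= 0:
        raise ValueError("cannot normalize a constant enrichment matrix")
    return EnrichmentMatrix(m.scores / span, normalized=True, alpha=m.alpha)


def tumor_purity(
    estimate_score: float | np.ndarray,
    c0: float = PURITY_C0,
    c1: float = PURITY_C1,
) -> float | np.ndarray:
    """Tumor purity from the combined microenvironment score.

    purity = cos(c0 + c1 * estimate_score), clamped to [0, 1] with a logged
    warning when clamping occurs.  The default constants are the published
    calibration of the cosine fit; they are exposed for recalibration.
    """
    raw = np.cos(c0 + c1 * np.asarray(estimate_score, dtype=float))
    clipped = np.clip(raw, 0.0, 1.0)
    if np.any(raw != clipped):
        logger.warning(
            "tumor purity clamped to [0, 1] for %d value(s)", int(np.sum(raw != clipped))
        )
    if np.isscalar(estimate_score) or np.ndim(estimate_score) == 0:
        return float(clipped)
    return clipped


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: list[str],
    immune_set: list[str],
    alpha: float = 0.25,
) -> EstimateScores:
    """Stromal/immune/combined microenvironment scores and purity per sample.

    The stromal and immune scores are unnormalised ssGSEA scores of the two
    signatures; their sum is the combined score, mapped to purity by
    :func:`tumor_purity`.
    """
    sets = GeneSetCollection({"stromal": stromal_set, "immune": immune_set})
    enrich = ssgsea_scores(expr, sets, alpha=alpha, on_empty="error")
    stromal = enrich.scores.loc["stromal"]
    immune = enrich.scores.loc["immune"]
    est = stromal + immune
    table = pd.DataFrame(
        {
            "stromal_score": stromal,
            "immune_score": immune,
            "estimate_score": est,
            "purity": tumor_purity(est.to_numpy()),
        }
    )
    return EstimateScores(table)
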