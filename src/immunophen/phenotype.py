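"""Immune-phenotype classification from enrichment profiles.

Samples are hierarchically clustered on their immune-signature enrichment
profiles (each signature row z-scored across samples, Ward linkage on
Euclidean distance) and the three clusters are labelled immune-H / immune-M
/ immune-L by descending mean z-scored enrichment.  PCA projection and
rank-based score comparisons provide the separation diagnostics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .enrichment import EnrichmentMatrix

logger = logging.getLogger(__name__)

PHENOTYPE_ORDER = ("immune-L", "immune-M", "immune-H")


@dataclass
class PhenotypeAssignment:
    """Per-sample immune-phenotype label with cluster provenance."""

    labels: pd.Series  # sample -> "immune-L" | "immune-M" | "immune-H"
    cluster_ids: pd.Series  # sample -> raw cluster integer
    linkage: str
    mean_enrichment_per_cluster: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.cluster_ids.index):
            raise ValueError("labels and cluster_ids must share sample index")
        means = self.mean_enrichment_per_cluster
        if means:
            ordered = [means[l] for l in PHENOTYPE_ORDER if l in means]
            if any(a > b for a, b in zip(ordered, ordered[1:])):
                raise ValueError("phenotype labels must be ordered by mean enrichment (H highest)")

    def groups(self) -> dict[str, pd.Index]:
        return {lab: self.labels.index[self.labels == lab] for lab in self.labels.unique()}


def _zscore_rows(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene-set row across samples; drop constant rows with warning."""
    sd = scores.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "dropping %d constant enrichment row(s) before clustering: %s",
            int(constant.sum()),
            scores.index[constant].tolist()[:5],
        )
        scores = scores.loc[~constant]
        sd = sd[~constant]
    if scores.empty:
        raise ValueError("no non-constant enrichment rows left for clustering")
    return scores.sub(scores.mean(axis=1), axis=0).div(sd, axis=0)


def classify_phenotypes(enrich: EnrichmentMatrix, k: int = 3) -> PhenotypeAssignment:
    """Cluster samples into ``k`` immune phenotypes (default 3: H/M/L).

    Rows are z-scored across samples, samples are clustered agglomeratively
    (Euclidean distance, Ward linkage — deterministic, no random
    initialisation), and clusters are ranked by their mean z-scored
    enrichment over all signatures, descending, to assign immune-H, then
    immune-M, then immune-L.  Ties between cluster means are broken by
    cluster size (larger first), then by cluster id.
    """
    if k < 2:
        raise ValueError("k must be >= 2; the phenotype analysis uses 3")
    n_samples = enrich.scores.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    if k != 3:
        logger.info("classifying with k=%d clusters (standard analysis uses 3)", k)

    z = _zscore_rows(enrich.scores)
    X = z.to_numpy(dtype=float).T  # samples x sets
    model = AgglomerativeClustering(n_clusters=k, linkage="ward", metric="euclidean")
    cluster_ids = model.fit_predict(X)

    samples = enrich.samples
    means: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for cid in range(k):
        members = cluster_ids == cid
        means[cid] = float(X[members].mean())
        sizes[cid] = int(members.sum())
    # descending mean; ties by size descending then cluster id
    ranked = sorted(means, key=lambda c: (-means[c], -sizes[c], c))
    if len(set(means.values())) < k:
        logger.warning("tied cluster means; ties broken by cluster size then id")
    if k == 3:
        label_by_rank = ["immune-H", "immune-M", "immune-L"]
    else:
        label_by_rank = [f"cluster-{i + 1}-of-{k}" for i in range(k)]
    label_of = {cid: label_by_rank[rank] for rank, cid in enumerate(ranked)}

    labels = pd.Series([label_of[c] for c in cluster_ids], index=samples, name="phenotype")
    return PhenotypeAssignment(
        labels=labels,
        cluster_ids=pd.Series(cluster_ids, index=samples, name="cluster_id"),
        linkage="ward",
        mean_enrichment_per_cluster={label_of[c]: means[c] for c in means},
    )


def pca_projection(matrix: pd.DataFrame, n_components: int = 3) -> pd.DataFrame:
    """Project samples onto the top principal components of a feature x sample table.

    Rows (features) are centered; coordinates are the projections of samples
    onto the top right-singular directions.  Each component's sign is fixed
    so that its largest-magnitude feature loading is positive, making the
    output deterministic.
    """
    n_components = int(n_components)
    if n_components < 1 or n_components > min(matrix.shape):
        raise ValueError(
            f"n_components must be in [1, {min(matrix.shape)}], got {n_components}"
        )
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(n_components):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    coords = (s[:n_components, None] * Vt[:n_components]).T  # samples x components
    return pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def compare_scores_by_phenotype(
    scores: pd.Series,
    labels: pd.Series,
    test: str = "kruskal-wallis",
) -> dict:
    """Compare a per-sample score across phenotype groups.

    ``test="kruskal-wallis"`` returns the K-W H statistic and asymptotic p
    over all groups; ``test="wilcoxon-pairwise"`` returns the two-sided
    rank-sum (Mann-Whitney) statistic and p for every pair of groups.
    """
    common = scores.index.intersection(labels.index)
    if len(common) < len(scores):
        logger.warning("dropping %d sample(s) without labels", len(scores) - len(common))
    scores, labels = scores.loc[common], labels.loc[common]
    groups = {lab: scores[labels == lab].to_numpy(dtype=float) for lab in labels.unique()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs at least one observation")

    ordered = [lab for lab in PHENOTYPE_ORDER if lab in groups] + [
        lab for lab in groups if lab not in PHENOTYPE_ORDER
    ]
    if test == "kruskal-wallis":
        if all(np.array_equal(v, next(iter(groups.values()))) for v in groups.values()):
            stat, p = 0.0, 1.0  # scipy raises on all-identical inputs
        else:
            stat, p = stats.kruskal(*[groups[lab] for lab in ordered])
        return {"test": "kruskal-wallis", "statistic": float(stat), "p": float(p)}
    if test == "wilcoxon-pairwise":
        rows = []
        for a, b in itertools.combinations(ordered, 2):
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "statistic": float(res.statistic), "p": float(res.pvalue)})
        return {"test": "wilcoxon-pairwise", "pairs": pd.DataFrame(rows)}
    raise ValueError(f"unknown test {test!r}")
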