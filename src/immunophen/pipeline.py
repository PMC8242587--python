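"""End-to-end orchestration of the immunogenomic analysis.

One YAML config drives the whole chain — enrichment scoring, phenotype
classification, microenvironment/purity scores, deconvolution, mutation
statistics, exhaustion-signature scoring, survival contrasts and drug
response — and every run writes a results bundle: per-stage tables plus a
manifest recording input hashes, parameters, seeds and package version, so
a bundle is self-describing and reproducible.  Failure of an optional
stage is logged and does not abort the mandatory ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .deconvolution import SignatureMatrix, cell_fraction_correlations, deconvolve
from .drugs import compare_response, predict_ic50, train_ridge_model
from .enrichment import estimate_scores, normalize_enrichment, ssgsea_scores
from .genomics import compute_tmb, math_scores_per_sample, recurrent_site_counts
from .get_signature import get_score
from .io import read_clinical, read_expression_matrix, read_gmt, read_maf
from .phenotype import classify_phenotypes
from .survival import cox_regression, km_logrank

logger = logging.getLogger(__name__)

MANDATORY_STAGES = ("enrich", "classify")
OPTIONAL_STAGES = ("estimate", "deconvolve", "genomics", "get", "survival", "drugs")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    expression: str
    output_dir: str
    expression_unit: str = "TPM"
    gene_sets: str | None = None
    signature_matrix: str | None = None
    maf: str | None = None
    clinical: str | None = None
    train_expression: str | None = None
    train_ic50: str | None = None
    get_signature_genes: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: list(MANDATORY_STAGES))
    alpha: float = 0.25
    normalize: bool = True
    k: int = 3
    stromal_set: str = "stromal"
    immune_set: str = "immune"
    deconv_method: str = "nnls"
    capture_size_mb: float = 38.0
    recurrent_min_n: int = 5
    folds: int = 10
    var_quantile: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(MANDATORY_STAGES) - set(OPTIONAL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage in MANDATORY_STAGES:
            if stage not in self.stages:
                self.stages.insert(0, stage)
        requirements = {
            "enrich": ["gene_sets"],
            "estimate": ["gene_sets"],
            "deconvolve": ["signature_matrix"],
            "genomics": ["maf"],
            "get": [],
            "survival": ["clinical"],
            "drugs": ["train_expression", "train_ic50"],
        }
        for stage in self.stages:
            for attr in requirements.get(stage, []):
                if getattr(self, attr) is None:
                    raise ValueError(f"stage {stage!r} requires config field {attr!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {
        name: getattr(config, name)
        for name in (
            "expression", "gene_sets", "signature_matrix", "maf",
            "clinical", "train_expression", "train_ic50",
        )
        if getattr(config, name) is not None
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if k not in ("output_dir",)
        },
        "input_hashes": {name: _sha256(path) for name, path in inputs.items()},
        "stages": {},
    }

    expr = read_expression_matrix(config.expression, unit=config.expression_unit)
    sets = read_gmt(config.gene_sets) if config.gene_sets else None

    enrich = None
    labels = None
    for stage in [s for s in (*MANDATORY_STAGES, *OPTIONAL_STAGES) if s in config.stages]:
        try:
            if stage == "enrich":
                enrich = ssgsea_scores(expr, sets, alpha=config.alpha)
                table = (
                    normalize_enrichment(enrich).scores if config.normalize else enrich.scores
                )
                table.to_csv(out / "enrichment.tsv", sep="\t", index_label="gene_set")
                manifest["stages"]["enrich"] = {"output": "enrichment.tsv", "alpha": config.alpha}
            elif stage == "classify":
                assignment = classify_phenotypes(enrich, k=config.k)
                labels = assignment.labels
                pd.DataFrame(
                    {"phenotype": assignment.labels, "cluster_id": assignment.cluster_ids}
                ).to_csv(out / "phenotypes.csv", index_label="sample")
                manifest["stages"]["classify"] = {
                    "output": "phenotypes.csv",
                    "k": config.k,
                    "linkage": assignment.linkage,
                    "sizes": assignment.labels.value_counts().to_dict(),
                }
            elif stage == "estimate":
                est = estimate_scores(
                    expr, sets[config.stromal_set], sets[config.immune_set], alpha=config.alpha
                )
                est.table.to_csv(out / "estimate.tsv", sep="\t", index_label="sample")
                manifest["stages"]["estimate"] = {"output": "estimate.tsv"}
            elif stage == "deconvolve":
                sig = SignatureMatrix(
                    pd.read_csv(config.signature_matrix, sep="\t", index_col=0)
                )
                fr = deconvolve(expr, sig, method=config.deconv_method)
                fr.fractions.to_csv(out / "fractions.tsv", sep="\t", index_label="cell_type")
                cell_fraction_correlations(fr).to_csv(
                    out / "cell_correlations.tsv", sep="\t", index_label="cell_type"
                )
                manifest["stages"]["deconvolve"] = {
                    "output": "fractions.tsv",
                    "method": config.deconv_method,
                }
            elif stage == "genomics":
                muts = read_maf(config.maf)
                tmb = compute_tmb(
                    muts, samples=expr.samples, capture_size_mb=config.capture_size_mb
                )
                genomics = tmb.table.copy()
                genomics["math"] = math_scores_per_sample(muts).reindex(genomics.index)
                genomics.to_csv(out / "genomics.tsv", sep="\t", index_label="sample")
                recurrent_site_counts(muts, min_n=config.recurrent_min_n).to_csv(
                    out / "recurrent_sites.tsv", sep="\t", index=False
                )
                manifest["stages"]["genomics"] = {
                    "output": "genomics.tsv",
                    "capture_size_mb": config.capture_size_mb,
                }
            elif stage == "get":
                signature = list(config.get_signature_genes) or None
                if signature is None:
                    from .get_signature import REFERENCE_GET_SIGNATURE

                    signature = list(REFERENCE_GET_SIGNATURE)
                gs = get_score(expr, signature)
                pd.DataFrame({"get_score": gs.scores, "group": gs.groups}).to_csv(
                    out / "get_scores.csv", index_label="sample"
                )
                manifest["stages"]["get"] = {
                    "output": "get_scores.csv",
                    "signature": signature,
                    "cutoff": gs.cutoff,
                }
            elif stage == "survival":
                clin = read_clinical(config.clinical)
                contrast = km_logrank(clin, labels)
                hazards = cox_regression(
                    clin, clin.covariate_names(), multivariable=False
                )
                hazards.table.to_csv(out / "hazards_uni.tsv", sep="\t", index=False)
                summary = {
                    "logrank_statistic": contrast.logrank_statistic,
                    "df": contrast.df,
                    "p": contrast.p,
                }
                if contrast.pairwise is not None:
                    summary["pairwise"] = contrast.pairwise.to_dict(orient="records")
                (out / "survival.json").write_text(json.dumps(summary, indent=2))
                manifest["stages"]["survival"] = {"output": "survival.json", **summary}
            elif stage == "drugs":
                train = read_expression_matrix(config.train_expression)
                ic50 = pd.read_csv(config.train_ic50, index_col=0).iloc[:, 0]
                model = train_ridge_model(
                    train, ic50, folds=config.folds,
                    var_quantile=config.var_quantile, cv_seed=config.seed,
                )
                preds = predict_ic50(model, expr)
                result = compare_response(preds, labels, test="auto")
                preds.to_frame().assign(phenotype=labels).to_csv(
                    out / "drug_predictions.csv", index_label="sample"
                )
                manifest["stages"]["drugs"] = {
                    "output": "drug_predictions.csv",
                    "lambda": model.lam,
                    "cv_rmse": model.cv_rmse,
                    "comparison": result,
                }
        except Exception:
            if stage in MANDATORY_STAGES:
                raise
            logger.exception("optional stage %r failed; continuing", stage)
            manifest["stages"][stage] = {"error": "stage failed; see log"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
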