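"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as gene x sample TSV/CSV (first column = gene
identifiers, header row = sample identifiers), gene sets as GMT, somatic
mutations as tab-separated MAF-like text, and clinical data as CSV.  All
I/O is UTF-8.  Unit normalisation (FPKM -> TPM) lives here too since it is
a property of the file-level representation, not of any analysis stage.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MAF_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

logger = logging.getLogger(__name__)


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    if not head.strip():
        raise ValueError(f"{path}: file is empty")
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(path: str | Path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a gene x sample expression table (TSV or CSV, auto-detected).

    Duplicate gene rows are collapsed by taking the per-sample maximum (the
    usual rule for multi-probe microarray genes) with a logged warning.
    Duplicate sample headers and non-numeric cells are errors.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delim)
    samples = header[1:]
    if len(set(samples)) < len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample header(s): {dupes}")
    df = pd.read_csv(path, sep=delim, index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row(s) {bad[:3]}"
            ) from exc
    if df.index.has_duplicates:
        n_dupes = int(df.index.duplicated().sum())
        logger.warning(
            "%s: collapsing %d duplicate gene row(s) by per-sample maximum", path, n_dupes
        )
        df = df.groupby(level=0, sort=False).max()
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep=sep, index_label="gene")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6.

    Every output column sums to 1e6; within-sample gene ranks are preserved
    exactly since the map is a per-sample positive rescaling.
    """
    if matrix.unit not in ("FPKM", "TPM"):
        raise ValueError(f"fpkm_to_tpm expects FPKM input, got {matrix.unit}")
    colsums = matrix.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {zero.index.tolist()}")
    tpm = matrix.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(tpm, unit="TPM")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then >=1 gene per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected name, description and >=1 gene")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# case-insensitive aliases for the standard MAF headers
_MAF_ALIASES = {c.lower(): c for c in MAF_COLUMNS}


def read_maf(path: str | Path) -> MutationTable:
    """Read a tab-separated MAF-like mutation table.

    Matching on the required columns is case-insensitive; extra columns are
    ignored.  Positions are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for col in df.columns:
        canon = _MAF_ALIASES.get(str(col).lower())
        if canon is not None:
            rename[col] = canon
    df = df.rename(columns=rename)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF column(s): {missing}")
    return MutationTable(df[list(MAF_COLUMNS)])


def write_maf(table: MutationTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.records.to_csv(path, sep="\t", index=False)


def read_clinical(
    path: str | Path,
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
) -> ClinicalTable:
    """Read a clinical CSV/TSV keyed by sample identifier.

    Covariate columns keep their file order; categorical levels are
    preserved as strings in first-seen order.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    if sample_col not in df.columns:
        raise ValueError(f"{path}: missing sample identifier column {sample_col!r}")
    df = df.set_index(sample_col)
    return ClinicalTable(df, time_col=time_col, event_col=event_col)


def write_clinical(table: ClinicalTable, path: str | Path, sample_col: str = "sample") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index_label=sample_col)
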