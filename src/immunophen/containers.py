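"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on four tabular objects: a gene x sample expression
matrix with a unit tag, a named collection of gene sets, a per-variant
somatic-mutation table with allele read counts, and a per-sample clinical
table (survival time, event indicator, covariates).  All of them are thin,
validated wrappers around pandas structures so that downstream stages can
rely on their invariants instead of re-checking them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised expression units.  Values must be non-negative except for
#: log2-scale microarray intensities, which may be negative after background
#: correction.
EXPRESSION_UNITS = ("FPKM", "TPM", "COUNTS", "LOG2_INTENSITY")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  All entries must be finite, and non-negative unless
        ``unit == "LOG2_INTENSITY"``.
    unit
        One of :data:`EXPRESSION_UNITS`.
    """

    values: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(
                f"unknown expression unit {self.unit!r}; expected one of {EXPRESSION_UNITS}"
            )
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if vals.columns.has_duplicates:
            dupes = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite or missing values")
        if self.unit != "LOG2_INTENSITY" and (arr < 0).any():
            raise ValueError(f"negative values are not allowed for unit {self.unit}")
        # normalise dtypes once so every consumer sees float64
        self.values = vals.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], unit=self.unit)


class GeneSetCollection:
    """Ordered mapping of set name -> unique gene list (+ optional description)."""

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if name in self._sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %r: dropped %d duplicate gene(s)", name, len(genes) - len(deduped)
                )
            self._sets[name] = deduped
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: object) -> bool:
        return name in self._sets

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)


#: Required columns of a mutation table, in canonical order.
MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Variant_Classification",
    "t_ref_count",
    "t_alt_count",
)


@dataclass
class MutationTable:
    """Per-variant somatic mutation records with allele read counts.

    Positions are 1-based inclusive (standard MAF convention); recurrent-site
    statistics key on ``(Chromosome, Start_Position)``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAF_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing required columns: {missing}")
        rec = self.records.copy()
        rec["Chromosome"] = rec["Chromosome"].astype(str)
        rec["Start_Position"] = rec["Start_Position"].astype(int)
        rec["t_ref_count"] = rec["t_ref_count"].astype(int)
        rec["t_alt_count"] = rec["t_alt_count"].astype(int)
        if (rec["t_ref_count"] < 0).any() or (rec["t_alt_count"] < 0).any():
            raise ValueError("negative read counts in mutation table")
        self.records = rec.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return self.records["Tumor_Sample_Barcode"].unique().tolist()

    def vafs(self, sample: str | None = None) -> pd.Series:
        """Variant allele fractions alt/(ref+alt).

        Records with zero total depth cannot yield a VAF and are excluded
        with a logged warning.
        """
        rec = self.records
        if sample is not None:
            rec = rec[rec["Tumor_Sample_Barcode"] == sample]
        depth = rec["t_ref_count"] + rec["t_alt_count"]
        bad = depth == 0
        if bad.any():
            logger.warning("excluding %d record(s) with zero read depth from VAF view", int(bad.sum()))
        rec = rec[~bad]
        return rec["t_alt_count"] / (rec["t_ref_count"] + rec["t_alt_count"])


@dataclass
class ClinicalTable:
    """Per-sample survival time, binary event indicator and covariates.

    The index is the sample identifier; ``time`` is in the units of the
    source file (days or months — the analysis never mixes cohorts), and
    ``event`` is 1 for an observed death and 0 for censoring.
    """

    data: pd.DataFrame
    time_col: str = "time"
    event_col: str = "event"

    def __post_init__(self) -> None:
        df = self.data
        for col in (self.time_col, self.event_col):
            if col not in df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        times = df[self.time_col].astype(float)
        if (times < 0).any():
            raise ValueError("negative survival times in clinical table")
        events = df[self.event_col]
        if not events.isin([0, 1]).all():
            bad = sorted(set(events) - {0, 1})
            raise ValueError(f"event indicator must be 0/1; found {bad}")
        df = df.copy()
        df[self.time_col] = times
        df[self.event_col] = events.astype(int)
        self.data = df

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data[self.time_col]

    @property
    def event(self) -> pd.Series:
        return self.data[self.event_col]

    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in (self.time_col, self.event_col)]
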