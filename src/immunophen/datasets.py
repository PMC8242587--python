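"""Small published summary tables used as fixed inputs.

The cross-tabulations below are the published counts of IDH mutation
status, glioma type (primary vs recurrent) and WHO-grade group (LGG vs
GBM) against the three immune phenotypes in the CGGA RNA-seq and CGGA
microarray cohorts.  They serve as exact inputs for the contingency-table
statistics; the underlying per-sample cohorts are not distributed.
"""

from __future__ import annotations

import pandas as pd

from .genomics import ContingencyTable

_PHENOTYPES = ["immune-L", "immune-M", "immune-H"]

_TABLES: dict[str, dict] = {
    "cgga_rnaseq_idh": {
        "levels": ["IDH_MT", "IDH_WT"],
        "counts": [[280, 109], [203, 192], [45, 133]],
    },
    "cgga_rnaseq_type": {
        "levels": ["primary", "recurrent"],
        "counts": [[314, 94], [249, 153], [85, 86]],
    },
    "cgga_rnaseq_grade": {
        "levels": ["LGG", "GBM"],
        "counts": [[322, 86], [240, 161], [61, 110]],
    },
    "cgga_microarray_idh": {
        "levels": ["IDH_MT", "IDH_WT"],
        "counts": [[62, 42], [47, 43], [25, 80]],
    },
    "cgga_microarray_type": {
        "levels": ["primary", "recurrent"],
        "counts": [[92, 9], [83, 4], [88, 11]],
    },
    "cgga_microarray_grade": {
        "levels": ["LGG", "GBM"],
        "counts": [[82, 23], [53, 38], [39, 64]],
    },
}


def cgga_phenotype_contingency_tables() -> dict[str, ContingencyTable]:
    """Phenotype x clinical-feature count tables for the two CGGA cohorts.

    Keys name the cohort and feature (e.g. ``"cgga_rnaseq_idh"``); rows are
    the immune-L/M/H phenotypes, columns the feature levels.
    """
    out = {}
    for name, spec in _TABLES.items():
        df = pd.DataFrame(spec["counts"], index=_PHENOTYPES, columns=spec["levels"])
        out[name] = ContingencyTable(df)
    return out
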