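"""Mutation statistics per sample and published contingency tests.

Computes TMB and MATH for every sample, lists planted recurrent sites
(N > 5), compares log2(TMB) across immune phenotypes, and reproduces the
published CGGA phenotype x clinical-feature chi-square statistics from
their printed counts.
"""

from pathlib import Path

import pandas as pd

import immunophen as ip
from immunophen.datasets import cgga_phenotype_contingency_tables
from immunophen.genomics import math_scores_per_sample
from immunophen.io import read_maf

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    muts = read_maf(ROOT / "cohort" / "mutations.maf")
    labels = pd.read_csv(ROOT / "phenotypes" / "labels.csv", index_col=0)["phenotype"]

    tmb = ip.compute_tmb(muts, samples=labels.index, capture_size_mb=38.0)
    table = tmb.table.copy()
    table["math"] = math_scores_per_sample(muts).reindex(table.index)
    out = ROOT / "genomics"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "per_sample.tsv", sep="\t", index_label="sample")

    sites = ip.recurrent_site_counts(muts, min_n=5)
    sites.to_csv(out / "recurrent_sites.tsv", sep="\t", index=False)
    print(f"recurrent sites (N > 5): {len(sites)}")
    print(sites.to_string(index=False))

    med = table["log2_tmb"].groupby(labels).median()
    kw = ip.compare_scores_by_phenotype(
        table["log2_tmb"].dropna(), labels, test="kruskal-wallis"
    )
    print(
        "median log2(TMB) by phenotype: "
        + ", ".join(f"{k}={v:.3f}" for k, v in med.items())
        + f"; K-W p = {kw['p']:.3g}"
    )

    rows = []
    for name, ctable in cgga_phenotype_contingency_tables().items():
        stat, df, p = ip.chi_square_test(ctable)
        rows.append({"table": name, "chi2": round(stat, 3), "df": df, "p": p})
        print(f"{name}: chi2 = {stat:.3f}, df = {df}, p = {p:.3g}")
    pd.DataFrame(rows).to_csv(out / "published_contingency.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
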