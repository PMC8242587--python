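"""Survival contrasts between phenotypes and GET-score groups.

Kaplan-Meier / log-rank across the three immune phenotypes (with pairwise
contrasts), the same for the GET-score median split, and univariable plus
multivariable Cox models over phenotype and clinical covariates.
"""

import json
from pathlib import Path

import pandas as pd

import immunophen as ip
from immunophen.io import read_clinical

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    clin = read_clinical(ROOT / "cohort" / "clinical.csv")
    labels = pd.read_csv(ROOT / "phenotypes" / "labels.csv", index_col=0)["phenotype"]
    get_groups = pd.read_csv(ROOT / "get_signature" / "scores.csv", index_col=0)["group"]

    out = ROOT / "survival"
    out.mkdir(parents=True, exist_ok=True)

    contrast = ip.km_logrank(clin, labels)
    print(
        f"phenotype log-rank: chi2 = {contrast.logrank_statistic:.2f}, "
        f"df = {contrast.df}, p = {contrast.p:.3g}"
    )
    for _, row in contrast.pairwise.iterrows():
        print(f"  {row['group_a']} vs {row['group_b']}: p = {row['p']:.3g}")

    get_contrast = ip.km_logrank(clin, get_groups)
    print(f"GET high vs low log-rank p = {get_contrast.p:.3g}")

    clin_cov = ip.ClinicalTable(clin.data.assign(phenotype=labels))
    uni = ip.cox_regression(clin_cov, ["age", "sex", "phenotype"], multivariable=False)
    multi = ip.cox_regression(
        clin_cov, ["age", "sex", "phenotype"], multivariable=True,
        reference_levels={"phenotype": "immune-L"},
    )
    uni.table.to_csv(out / "cox_univariable.tsv", sep="\t", index=False)
    multi.table.to_csv(out / "cox_multivariable.tsv", sep="\t", index=False)
    print("multivariable hazard ratios:")
    show = multi.table[multi.table["HR"].notna()]
    for _, row in show.iterrows():
        print(
            f"  {row['covariate']}: HR = {row['HR']:.2f} "
            f"({row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.3g}"
        )

    payload = {
        "phenotype_logrank": {
            "statistic": contrast.logrank_statistic, "df": contrast.df, "p": contrast.p,
        },
        "get_logrank": {"statistic": get_contrast.logrank_statistic, "p": get_contrast.p},
    }
    (out / "logrank.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
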