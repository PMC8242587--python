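"""Generate the synthetic study cohort and write its input files.

Produces a 300-sample bulk cohort with three planted infiltration levels,
marker gene sets, a MAF-like mutation table, clinical follow-up and the
planted ground truth, under results/cohort/.  Every later analysis script
reads from there.
"""

from pathlib import Path

import yaml

import immunophen as ip
from immunophen.io import write_clinical, write_expression_matrix, write_gmt, write_maf

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    cfg = ip.SyntheticConfig(seed=SEED)
    expr, truth, clin = ip.generate_cohort(cfg)
    sets = ip.generate_gene_sets(cfg)
    muts = ip.generate_maf(cfg, hotspots=[("7", 55242464, 12), ("17", 7577121, 9)])
    lines, ic50, line_truth = ip.generate_cellline_training(cfg, n_lines=120)

    OUT.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(expr, OUT / "expression.tsv")
    write_gmt(sets, OUT / "gene_sets.gmt")
    write_maf(muts, OUT / "mutations.maf")
    write_clinical(clin, OUT / "clinical.csv")
    write_expression_matrix(lines, OUT / "cellline_expression.tsv")
    ic50.to_frame().to_csv(OUT / "cellline_ic50.csv", index_label="line")
    truth.cell_profiles.to_csv(OUT / "cell_profiles.tsv", sep="\t", index_label="gene")
    truth.fractions.to_csv(OUT / "true_fractions.tsv", sep="\t", index_label="cell_type")
    yaml.safe_dump(
        {
            "seed": SEED,
            "purity": {k: float(v) for k, v in truth.purity.round(6).items()},
            "phenotype": truth.phenotype_label.to_dict(),
            "cellline_intercept": line_truth.intercept,
        },
        (OUT / "truth.yaml").open("w"),
    )
    n_by = truth.phenotype_label.value_counts().to_dict()
    print(f"cohort: {expr.n_samples} samples x {expr.n_genes} genes, phenotypes {n_by}")
    print(f"mutations: {len(muts)} records across {len(muts.samples)} samples")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
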