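import numpy as np
import pandas as pd
import pytest

import immunophen as ip


@pytest.fixture(scope="session")
def small_config() -> ip.SyntheticConfig:
    """A quick cohort: 120 samples, 200 genes, 4 cell types."""
    return ip.SyntheticConfig(
        n_genes=200, n_samples=120, n_cell_types=4, markers_per_type=12, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ip.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_sets(small_config):
    return ip.generate_gene_sets(small_config)


@pytest.fixture(scope="session")
def small_enrichment(small_cohort, small_sets):
    expr, _, _ = small_cohort
    return ip.ssgsea_scores(expr, small_sets)


@pytest.fixture()
def tiny_expr() -> ip.ExpressionMatrix:
    """4 genes x 3 samples with distinct values (no ties)."""
    df = pd.DataFrame(
        {
            "s1": [4.0, 3.0, 2.0, 1.0],
            "s2": [1.0, 2.0, 3.0, 4.0],
            "s3": [2.0, 4.0, 1.0, 3.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ip.ExpressionMatrix(df, unit="TPM")


def naive_ssgsea(values: pd.Series, members: set[str], alpha: float) -> float:
    """Direct-summation ssGSEA oracle: explicit walk in pure Python.

    Ranks genes by (value descending, name ascending), assigns rank value
    N - position, and accumulates the weighted in-set ECDF minus the
    uniform out-of-set ECDF.  Independent of the vectorised implementation.
    """
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ordered)
    size = sum(1 for g, _ in ordered if g in members)
    assert 0 < size < n
    denom = sum((n - pos) ** alpha for pos, (g, _) in enumerate(ordered) if g in members)
    score = 0.0
    p_in = p_out = 0.0
    for pos, (g, _) in enumerate(ordered):
        if g in members:
            p_in += (n - pos) ** alpha / denom
        else:
            p_out += 1.0 / (n - size)
        score += p_in - p_out
    return score
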