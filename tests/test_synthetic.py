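"""Generator invariants: mixture formula, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

import immunophen as ip


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phenotype_proportions": (0.5, 0.5, 0.5)},
            {"infiltration_levels": (0.3, 0.2, 0.6)},
            {"infiltration_levels": (0.0, 0.2, 0.6)},
            {"markers_per_type": 100, "n_cell_types": 10, "n_genes": 500},
            {"noise_sd": -0.1},
            {"vaf_beta_params": (0.0, 1.0)},
            {"hazard_multipliers": (1.0, -1.0, 2.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ip.SyntheticConfig(**kwargs)


class TestCohort:
    def test_mixture_formula_round_trip_noiseless(self):
        """With noise_sd = 0 the matrix equals
        purity*T + (1-purity) * C @ f, entrywise."""
        cfg = ip.SyntheticConfig(
            n_genes=100, n_samples=30, n_cell_types=3, markers_per_type=10,
            noise_sd=0.0, seed=5,
        )
        expr, truth, _ = ip.generate_cohort(cfg)
        p = truth.purity.to_numpy()
        recon = (
            p[None, :] * truth.tumor_profile.to_numpy()[:, None]
            + (1 - p)[None, :]
            * (truth.cell_profiles.to_numpy() @ truth.fractions.to_numpy())
        )
        assert np.allclose(expr.values.to_numpy(), recon, atol=1e-9)

    def test_degenerate_pure_tumor(self):
        """Near-zero infiltration levels and zero noise: every column is
        the tumor profile."""
        cfg = ip.SyntheticConfig(
            n_genes=80, n_samples=10, n_cell_types=2, markers_per_type=5,
            noise_sd=0.0, infiltration_jitter_sd=0.0,
            infiltration_levels=(1e-13, 2e-13, 3e-13), seed=2,
        )
        expr, truth, _ = ip.generate_cohort(cfg)
        assert np.allclose(truth.purity, 1.0, atol=1e-12)
        T = truth.tumor_profile.to_numpy()
        assert np.allclose(expr.values.to_numpy(), T[:, None], rtol=1e-9)

    def test_seed_determinism(self, small_config, small_cohort):
        expr, truth, clin = small_cohort
        expr2, truth2, clin2 = ip.generate_cohort(small_config)
        pd.testing.assert_frame_equal(expr.values, expr2.values)
        pd.testing.assert_series_equal(truth.purity, truth2.purity)
        pd.testing.assert_frame_equal(clin.data, clin2.data)

    def test_truth_invariants(self, small_cohort):
        _, truth, _ = small_cohort
        assert np.allclose(truth.fractions.sum(axis=0), 1.0, atol=1e-9)
        assert truth.purity.between(0, 1).all()

    def test_planted_order_of_marker_expression(self, small_cohort, small_sets, small_config):
        """Mean immune-marker expression increases L -> M -> H."""
        expr, truth, _ = small_cohort
        for name in small_sets.names():
            if not name.startswith("immune_type") and name != "immune":
                continue
            mean_by = (
                expr.values.loc[small_sets[name]].mean(axis=0)
                .groupby(truth.phenotype_label).mean()
            )
            assert mean_by["L"] < mean_by["M"] < mean_by["H"]

    def test_survival_reflects_hazard_multipliers(self, small_cohort):
        _, truth, clin = small_cohort
        med = clin.time.groupby(truth.phenotype_label).median()
        assert med["H"] < med["L"]  # highest hazard, shortest survival
        assert 0 < clin.event.mean() < 1  # both events and censorings


class TestGeneSets:
    def test_count_and_membership(self, small_config, small_sets, small_cohort):
        expr, _, _ = small_cohort
        assert len(small_sets) == small_config.n_cell_types + 2
        universe = set(expr.genes)
        for name in small_sets.names():
            assert set(small_sets[name]) <= universe

    def test_marker_sets_disjoint(self, small_config, small_sets):
        per_type = [
            set(small_sets[n]) for n in small_sets.names()
            if n not in ("stromal", "immune")
        ]
        assert sum(len(s) for s in per_type) == len(set().union(*per_type))

    def test_markers_elevated_in_own_profile(self, small_cohort, small_sets):
        """Each marker set's mean expression in its own cell-type profile
        exceeds its mean in every other profile."""
        _, truth, _ = small_cohort
        C = truth.cell_profiles
        for ct in C.columns:
            members = small_sets[ct]
            own = C.loc[members, ct].mean()
            others = C.loc[members].drop(columns=ct).mean()
            assert (own > others).all()

    def test_22_types_gives_24_sets(self):
        cfg = ip.SyntheticConfig(n_genes=500, n_cell_types=22, markers_per_type=10)
        assert len(ip.generate_gene_sets(cfg)) == 24


class TestMaf:
    def test_determinism_and_beta_moment(self):
        cfg = ip.SyntheticConfig(n_samples=50, vaf_beta_params=(2.0, 8.0), seed=9)
        a = ip.generate_maf(cfg, mutations_per_sample=200)
        b = ip.generate_maf(cfg, mutations_per_sample=200)
        pd.testing.assert_frame_equal(a.records, b.records)
        vafs = a.vafs()
        assert len(vafs) > 9_000
        mean, se = 2.0 / 10.0, np.sqrt(0.2 * 0.8 / 11) / np.sqrt(len(vafs))
        # rounding to depth 100 adds < 0.005 bias at most
        assert abs(vafs.mean() - mean) < 3 * se + 0.005

    def test_degenerate_beta_gives_zero_math(self):
        cfg = ip.SyntheticConfig(
            n_samples=5, vaf_beta_params=(1e6 * 0.3, 1e6 * 0.7), seed=1
        )
        muts = ip.generate_maf(cfg, mutations_per_sample=30)
        from immunophen.genomics import math_scores_per_sample

        scores = math_scores_per_sample(muts)
        assert (scores.abs() < 1e-9).all()

    def test_hotspot_planting(self):
        cfg = ip.SyntheticConfig(n_samples=20, seed=3)
        muts = ip.generate_maf(cfg, mutations_per_sample=5, hotspots=[("7", 55242464, 8)])
        hits = ip.recurrent_site_counts(muts, min_n=5)
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row["Chromosome"], int(row["Start_Position"]), int(row["count"])) == (
            "7", 55242464, 8,
        )


class TestCellLines:
    def test_noiseless_linear_model_exact(self):
        cfg = ip.SyntheticConfig(n_genes=60, markers_per_type=5, seed=7)
        expr, ic50, truth = ip.generate_cellline_training(
            cfg, n_lines=40, drug_effect_genes=5, noise_sd=0.0
        )
        recon = truth.intercept + expr.values.T @ truth.coefficients
        assert np.allclose(ic50, recon, atol=1e-9)

    def test_zero_coefficients_constant_response(self):
        cfg = ip.SyntheticConfig(n_genes=60, markers_per_type=5, seed=7)
        expr, ic50, truth = ip.generate_cellline_training(
            cfg, n_lines=20, drug_effect_genes=1, effect_sd=0.0, noise_sd=0.0
        )
        assert np.allclose(ic50, truth.intercept)

    def test_effect_gene_guard(self):
        cfg = ip.SyntheticConfig(n_genes=60, markers_per_type=5)
        with pytest.raises(ValueError, match="drug_effect_genes"):
            ip.generate_cellline_training(cfg, n_lines=10, drug_effect_genes=61)
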