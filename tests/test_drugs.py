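"""Ridge closed form, cross-validated penalty choice, and response comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import immunophen as ip
from immunophen.drugs import _ridge_solve


def expr_from(arr, genes=None, lines=None):
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    lines = lines or [f"cl{j}" for j in range(arr.shape[1])]
    return ip.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=lines))


class TestRidgeClosedForm:
    def test_hand_evaluated_two_gene_design(self):
        """Standardised 2-gene, 3-line design at lambda = 1 equals the
        hand-evaluated (X'X + I)^-1 X'y."""
        X = np.array([[1.0, 0.0], [-1.0, 1.0], [0.0, -1.0]])
        X = X - X.mean(axis=0)
        y = np.array([1.0, 2.0, 3.0])
        coef, intercept = _ridge_solve(X, y, 1.0)
        expected = np.linalg.solve(X.T @ X + np.eye(2), X.T @ (y - y.mean()))
        assert np.allclose(coef, expected, atol=1e-12)
        assert intercept == pytest.approx(2.0)

    def test_matches_sklearn_ridge(self):
        """Independent cross-check against sklearn's solver at several lambdas."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 8))
        X = X - X.mean(axis=0)
        y = rng.normal(size=50)
        for lam in (0.01, 1.0, 100.0):
            coef, intercept = _ridge_solve(X, y, lam)
            sk = Ridge(alpha=lam, fit_intercept=True).fit(X, y)
            assert np.allclose(coef, sk.coef_, atol=1e-8)
            assert intercept == pytest.approx(sk.intercept_, abs=1e-8)

    def test_infinite_shrinkage_limit(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=1)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=30, noise_sd=0.1)
        model = ip.train_ridge_model(
            expr, ic50, lambda_grid=np.array([1e9 * 30]), folds=5, var_quantile=0.0
        )
        assert np.abs(model.coefficients).max() < 1e-3
        preds = ip.predict_ic50(model, expr)
        assert np.allclose(preds, ic50.mean(), atol=1e-3)

    def test_shrinkage_monotone_in_lambda(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=2)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=60, noise_sd=0.2)
        norms = []
        for lam in (0.01, 1.0, 100.0, 1e4):
            m = ip.train_ridge_model(
                expr, ic50, lambda_grid=np.array([lam]), folds=5, var_quantile=0.0
            )
            norms.append(np.linalg.norm(m.coefficients))
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestTraining:
    def test_noiseless_generative_recovery(self):
        """Small lambda on noiseless linear data recovers the planted
        coefficients (on the raw-expression scale) within 5%."""
        cfg = ip.SyntheticConfig(n_genes=60, markers_per_type=5, seed=3)
        expr, ic50, truth = ip.generate_cellline_training(
            cfg, n_lines=200, drug_effect_genes=10, noise_sd=0.0
        )
        model = ip.train_ridge_model(
            expr, ic50, lambda_grid=np.array([1e-8]), folds=10, var_quantile=0.0
        )
        beta_hat = pd.Series(model.coefficients / model.sds, index=model.genes)
        nz = truth.coefficients[truth.coefficients != 0]
        rel_err = (beta_hat.reindex(nz.index) - nz).abs() / nz.abs()
        assert rel_err.max() < 0.05

    def test_cv_choice_deterministic_given_seed(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=4)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=50, noise_sd=0.2)
        a = ip.train_ridge_model(expr, ic50, folds=5, cv_seed=7)
        b = ip.train_ridge_model(expr, ic50, folds=5, cv_seed=7)
        assert a.lam == b.lam
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_folds_guard(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=5)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=5)
        with pytest.raises(ValueError, match="folds"):
            ip.train_ridge_model(expr, ic50, folds=10)


class TestPrediction:
    def test_training_line_reproduces_fitted_value(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=6)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=30, noise_sd=0.1)
        model = ip.train_ridge_model(expr, ic50, folds=5, var_quantile=0.0)
        preds = ip.predict_ic50(model, expr)
        X = (expr.values.loc[model.genes].to_numpy().T - model.means) / model.sds
        fitted = X @ model.coefficients + model.intercept
        assert np.allclose(preds.to_numpy(), fitted, atol=1e-10)

    def test_heldout_correlation_at_modest_noise(self):
        """Held-out samples from the same generative model: r > 0.8."""
        cfg = ip.SyntheticConfig(n_genes=100, markers_per_type=10, seed=7)
        expr, ic50, truth = ip.generate_cellline_training(
            cfg, n_lines=300, drug_effect_genes=10, noise_sd=0.1
        )
        model = ip.train_ridge_model(expr, ic50, folds=10, var_quantile=0.2, cv_seed=1)
        rng = np.random.default_rng(8)
        Xte = rng.lognormal(2.0, 0.8, size=(cfg.n_genes, 100))
        y_true = truth.intercept + Xte.T @ truth.coefficients.to_numpy()
        te = expr_from(Xte, genes=list(expr.genes), lines=[f"T{i}" for i in range(100)])
        preds = ip.predict_ic50(model, te)
        assert np.corrcoef(preds, y_true)[0, 1] > 0.8

    def test_overlap_guard_and_imputation(self):
        cfg = ip.SyntheticConfig(n_genes=40, markers_per_type=4, seed=9)
        expr, ic50, _ = ip.generate_cellline_training(cfg, n_lines=30)
        model = ip.train_ridge_model(expr, ic50, folds=5, var_quantile=0.0)
        missing_all = expr_from(np.ones((2, 3)), genes=["zz1", "zz2"])
        with pytest.raises(ValueError, match="model genes"):
            ip.predict_ic50(model, missing_all)
        # above-threshold partial overlap predicts with imputation
        keep = model.genes[: int(len(model.genes) * 0.6)]
        partial = ip.ExpressionMatrix(expr.values.loc[keep])
        preds = ip.predict_ic50(model, partial, min_gene_overlap=0.5)
        assert np.isfinite(preds).all()


class TestCompareResponse:
    def make_groups(self, shift=0.0, n=40, seed=0, spread=1.0):
        rng = np.random.default_rng(seed)
        preds = np.concatenate([
            rng.normal(0.0, spread, n),
            rng.normal(0.0, spread, n),
            rng.normal(shift, spread, n),
        ])
        idx = [f"s{i}" for i in range(3 * n)]
        labels = pd.Series(
            ["immune-L"] * n + ["immune-M"] * n + ["immune-H"] * n, index=idx
        )
        return pd.Series(preds, index=idx), labels

    def test_identical_groups_zero_kw(self):
        preds = pd.Series([1.0, 2.0] * 3, index=[f"s{i}" for i in range(6)])
        labels = pd.Series(
            ["immune-L"] * 2 + ["immune-M"] * 2 + ["immune-H"] * 2, index=preds.index
        )
        out = ip.compare_response(preds, labels, test="kruskal-wallis")
        assert out["statistic"] == 0.0

    def test_power_at_two_sd_shift(self):
        """2-sd mean shift in one phenotype, n=100/group: p < 0.001 in
        >= 19 of 20 seeds (both tests)."""
        hits = 0
        for seed in range(20):
            preds, labels = self.make_groups(shift=2.0, n=100, seed=seed)
            out = ip.compare_response(preds, labels, test="kruskal-wallis")
            hits += out["p"] < 1e-3
        assert hits >= 19

    def test_anova_matches_hand_computed_f(self):
        """3x3 toy table: F = between-group MS / within-group MS."""
        data = {"immune-L": [1.0, 2.0, 3.0], "immune-M": [2.0, 3.0, 4.0], "immune-H": [6.0, 7.0, 8.0]}
        values = np.array(sum(data.values(), []))
        grand = values.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
        f_hand = (ssb / 2) / (ssw / 6)
        idx = [f"s{i}" for i in range(9)]
        preds = pd.Series(values, index=idx)
        labels = pd.Series(sum([[k] * 3 for k in data], []), index=idx)
        out = ip.compare_response(preds, labels, test="anova")
        assert out["statistic"] == pytest.approx(f_hand, abs=1e-10)

    def test_auto_gate_selects_kw_for_skewed_data(self):
        rng = np.random.default_rng(10)
        idx = [f"s{i}" for i in range(150)]
        preds = pd.Series(rng.lognormal(0.0, 2.0, size=150) ** 2, index=idx)
        labels = pd.Series(
            ["immune-L"] * 50 + ["immune-M"] * 50 + ["immune-H"] * 50, index=idx
        )
        out = ip.compare_response(preds, labels, test="auto")
        assert out["test"] == "kruskal-wallis"

    def test_empty_group_rejected(self):
        preds = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = pd.Series(["immune-L", "immune-L"], index=["a", "b"])
        with pytest.raises(ValueError, match="groups"):
            ip.compare_response(preds, labels, test="anova")
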