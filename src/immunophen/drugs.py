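"""Ridge-regression prediction of drug response (log IC50) from expression.

A model is trained on cell-line expression with measured log IC50: the
lowest-variance genes are removed, the rest are standardised by their
training mean/sd, the ridge penalty is chosen by 10-fold cross-validation
over a log-spaced grid, and the final coefficients are the closed form
(X'X + lambda I)^-1 X'y with an unpenalised intercept.  Tumor samples are
then scored with the training standardisation (missing model genes imputed
at the training mean, i.e. standardised 0) and predictions are compared
across immune phenotypes with ANOVA or Kruskal-Wallis, optionally gated by
a Shapiro-Wilk normality check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 25)


@dataclass
class RidgeModel:
    """Fitted ridge model with its training standardisation parameters."""

    genes: list[str]
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    lam: float
    cv_rmse: float
    cv_seed: int

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.means) == len(self.sds) == len(self.coefficients)):
            raise ValueError("inconsistent model dimensions")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge on centred data; intercept is the mean of y.

    X is assumed standardised (column mean 0), so the unpenalised intercept
    decouples from the penalised slope estimates.
    """
    n, p = X.shape
    intercept = float(y.mean())
    yc = y - intercept
    coef = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ yc)
    return coef, intercept


def train_ridge_model(
    train_expr: ExpressionMatrix,
    ic50: pd.Series,
    lambda_grid: np.ndarray | None = None,
    folds: int = 10,
    var_quantile: float = 0.2,
    cv_seed: int = 0,
) -> RidgeModel:
    """Train the log-IC50 ridge model on cell-line data.

    Parameters
    ----------
    train_expr
        Gene x cell-line expression.
    ic50
        Per-line log IC50, indexed by cell line.
    lambda_grid
        Candidate penalties; the one minimising mean cross-validated RMSE
        wins.  Defaults to 25 points log-spaced in [1e-3, 1e3].
    folds
        Cross-validation folds (fold assignment seeded by ``cv_seed`` and
        recorded on the model).
    var_quantile
        Genes below this variance quantile are removed before fitting.
    """
    lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if (lambda_grid <= 0).any():
        raise ValueError("lambda grid must be positive")
    lines = train_expr.samples.intersection(ic50.index)
    if len(lines) < len(train_expr.samples):
        logger.warning("dropping %d line(s) without IC50", len(train_expr.samples) - len(lines))
    if folds > len(lines):
        raise ValueError(f"folds={folds} exceeds the number of training lines ({len(lines)})")
    y = ic50.loc[lines].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("IC50 values must be finite")

    values = train_expr.values[lines]
    variances = values.var(axis=1, ddof=0)
    if var_quantile > 0:
        cutoff = variances.quantile(var_quantile)
        keep = variances > cutoff
        if keep.sum() == 0:  # degenerate: keep everything rather than nothing
            keep = variances >= cutoff
        values = values.loc[keep]
    zero_var = values.var(axis=1, ddof=0) == 0
    if zero_var.any():
        logger.warning("dropping %d zero-variance gene(s) after filtering", int(zero_var.sum()))
        values = values.loc[~zero_var]
    genes = values.index.tolist()
    means = values.mean(axis=1).to_numpy()
    sds = values.std(axis=1, ddof=0).to_numpy()
    X = ((values.to_numpy(dtype=float).T - means) / sds)

    kf = KFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    cv_rmse = np.zeros(len(lambda_grid))
    for train_idx, test_idx in kf.split(X):
        Xt, yt = X[train_idx], y[train_idx]
        # re-centre within the fold so the intercept stays unpenalised
        mu = Xt.mean(axis=0)
        for i, lam in enumerate(lambda_grid):
            coef, intercept = _ridge_solve(Xt - mu, yt, lam)
            pred = (X[test_idx] - mu) @ coef + intercept
            cv_rmse[i] += np.sqrt(np.mean((pred - y[test_idx]) ** 2))
    cv_rmse /= folds
    best = int(np.argmin(cv_rmse))
    lam = float(lambda_grid[best])

    coef, intercept = _ridge_solve(X, y, lam)
    logger.info("ridge: lambda=%.4g, CV RMSE=%.4g, %d genes", lam, cv_rmse[best], len(genes))
    return RidgeModel(
        genes=genes,
        means=means,
        sds=sds,
        coefficients=coef,
        intercept=intercept,
        lam=lam,
        cv_rmse=float(cv_rmse[best]),
        cv_seed=cv_seed,
    )


def predict_ic50(
    model: RidgeModel,
    tumor_expr: ExpressionMatrix,
    min_gene_overlap: float = 0.5,
) -> pd.Series:
    """Predict log IC50 for tumor samples with the trained model.

    Model genes absent from the tumor matrix are imputed at the training
    mean (standardised 0).  If fewer than ``min_gene_overlap`` of the model
    genes are present, prediction is refused.
    """
    present = [g for g in model.genes if g in tumor_expr.genes]
    overlap = len(present) / len(model.genes)
    if overlap < min_gene_overlap:
        raise ValueError(
            f"only {overlap:.0%} of model genes present in tumor matrix "
            f"(threshold {min_gene_overlap:.0%})"
        )
    if overlap < 1.0:
        logger.warning("imputing %d missing model gene(s) at training mean", len(model.genes) - len(present))
    Z = np.zeros((tumor_expr.n_samples, len(model.genes)))
    pos = {g: i for i, g in enumerate(model.genes)}
    for g in present:
        i = pos[g]
        Z[:, i] = (tumor_expr.values.loc[g].to_numpy(dtype=float) - model.means[i]) / model.sds[i]
    pred = Z @ model.coefficients + model.intercept
    return pd.Series(pred, index=tumor_expr.samples, name="predicted_log_ic50")


def compare_response(
    predictions: pd.Series,
    labels: pd.Series,
    test: str = "auto",
    shapiro_alpha: float = 0.05,
) -> dict:
    """Compare predicted response across phenotype groups.

    ``test`` is ``"anova"``, ``"kruskal-wallis"`` or ``"auto"``; auto runs
    a Shapiro-Wilk normality check on each group and uses one-way ANOVA
    only when every group passes at ``shapiro_alpha``, otherwise the
    Kruskal-Wallis rank test — the usual parametric/nonparametric gate.
    """
    common = predictions.index.intersection(labels.index)
    predictions, labels = predictions.loc[common], labels.loc[common]
    group_names = list(dict.fromkeys(labels))
    groups = [predictions[labels == lab].to_numpy(dtype=float) for lab in group_names]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")

    chosen = test
    if test == "auto":
        normal = all(
            len(g) >= 3 and np.std(g) > 0 and stats.shapiro(g).pvalue > shapiro_alpha
            for g in groups
        )
        chosen = "anova" if normal else "kruskal-wallis"
    if chosen == "anova":
        stat, p = stats.f_oneway(*groups)
    elif chosen == "kruskal-wallis":
        if all(np.array_equal(g, groups[0]) for g in groups):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    medians = {lab: float(np.median(g)) for lab, g in zip(group_names, groups)}
    return {"test": chosen, "statistic": float(stat), "p": float(p), "medians": medians}
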