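"""Bulk-expression deconvolution against a leukocyte signature matrix.

Plays the role the 22-type leukocyte signature matrix (LM22) plays in bulk
immunogenomic studies: each bulk sample is modelled as a non-negative
mixture of cell-type expression profiles and the mixture weights are
recovered per sample, either by non-negative least squares (default,
deterministic) or by linear nu-support-vector regression over a small nu
grid (the convention of the original deconvolution algorithm).

Both the mixture column and each signature column are z-scored over the
shared genes before fitting, which makes the fit invariant to the bulk
sample's overall scale.  The fitted weights live on the z-scored scale
(weight_c = fraction_c * sd_c / sd_bulk), so each weight is divided by its
signature column's standard deviation before renormalising onto the
simplex — this recovers planted fractions exactly on noiseless mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignatureMatrix:
    """Gene x cell-type reference profiles (non-negative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate genes in signature matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate cell-type names in signature matrix")
        arr = v.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature matrix must be non-negative")
        if (arr.max(axis=0) <= 0).any():
            bad = v.columns[arr.max(axis=0) <= 0].tolist()
            raise ValueError(f"signature column(s) with no positive entry: {bad}")
        self.values = v.astype(float)

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclass
class FractionMatrix:
    """Cell-type x sample fractions on the simplex, plus per-sample fit RMSE."""

    fractions: pd.DataFrame
    residual_rmse: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy(dtype=float)
        if (f < -1e-12).any():
            raise ValueError("negative fractions")
        if not np.allclose(f.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1")


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float]:
    sd = float(x.std())
    if sd == 0:
        return np.zeros_like(x), 0.0
    return (x - x.mean()) / sd, sd


def deconvolve(
    bulk: ExpressionMatrix,
    sig: SignatureMatrix,
    method: str = "nnls",
) -> FractionMatrix:
    """Estimate per-sample cell-type fractions from bulk expression.

    Parameters
    ----------
    bulk
        Bulk expression matrix (linear scale).
    sig
        Signature matrix of reference cell-type profiles.
    method
        ``"nnls"`` (default; deterministic non-negative least squares) or
        ``"nu-svr"`` (linear nu-SVR over nu in {0.25, 0.5, 0.75}, keeping
        the lowest-RMSE fit, negatives truncated to zero).

    A degenerate all-zero weight vector falls back to uniform fractions
    with a warning.
    """
    if method not in ("nnls", "nu-svr"):
        raise ValueError(f"unknown method {method!r}")
    shared = bulk.genes.intersection(sig.values.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared gene(s) between bulk and signature; need >= 2")

    S = sig.values.loc[shared].to_numpy(dtype=float)
    n_types = S.shape[1]
    col_sd = S.std(axis=0)
    if (col_sd == 0).any():
        bad = sig.cell_types[col_sd == 0].tolist()
        raise ValueError(f"signature column(s) constant over shared genes: {bad}")
    Sz = (S - S.mean(axis=0)) / col_sd

    B = bulk.values.loc[shared].to_numpy(dtype=float)
    fractions = np.empty((n_types, bulk.n_samples))
    rmses = np.empty(bulk.n_samples)
    for j in range(bulk.n_samples):
        b, b_sd = _zscore(B[:, j])
        if b_sd == 0:
            logger.warning("sample %s is constant over shared genes; uniform fractions", bulk.samples[j])
            fractions[:, j] = 1.0 / n_types
            rmses[j] = np.nan
            continue
        if method == "nnls":
            w, rnorm = nnls(Sz, b)
            rmse = rnorm / np.sqrt(len(b))
        else:
            best: tuple[float, np.ndarray] | None = None
            for nu in (0.25, 0.5, 0.75):
                model = NuSVR(kernel="linear", nu=nu, C=1.0)
                model.fit(Sz, b)
                coefs = model.coef_.ravel()
                resid = b - Sz @ coefs - model.intercept_
                rmse_nu = float(np.sqrt(np.mean(resid**2)))
                if best is None or rmse_nu < best[0]:
                    best = (rmse_nu, coefs)
            rmse, w = best[0], np.clip(best[1], 0.0, None)
        # map z-scale weights back to original-scale contributions
        w = w / col_sd
        total = w.sum()
        if total <= 0:
            logger.warning(
                "degenerate fit for sample %s (all-zero weights); uniform fractions",
                bulk.samples[j],
            )
            fractions[:, j] = 1.0 / n_types
        else:
            fractions[:, j] = w / total
        rmses[j] = rmse

    return FractionMatrix(
        fractions=pd.DataFrame(fractions, index=sig.cell_types, columns=bulk.samples),
        residual_rmse=pd.Series(rmses, index=bulk.samples, name="residual_rmse"),
    )


def cell_fraction_correlations(fractions: FractionMatrix) -> pd.DataFrame:
    """Pearson correlation between every pair of cell types across samples.

    Symmetric with unit diagonal; cell types with constant fractions yield
    undefined correlations, reported as NaN.
    """
    f = fractions.fractions
    if f.shape[1] < 3:
        raise ValueError("need at least 3 samples for cell-cell correlations")
    corr = f.T.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    constant = f.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "%d cell type(s) constant across samples; correlations undefined",
            int(constant.sum()),
        )
        corr.loc[constant, :] = np.nan
        corr.loc[:, constant] = np.nan
    return corr
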