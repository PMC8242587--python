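"""Survival contrasts: Kaplan-Meier / log-rank between groups and Cox
proportional-hazards summaries (univariable and multivariable).

Built on lifelines.  Cox fits use lifelines' Efron partial likelihood for
tied event times; the synthetic cohorts draw continuous times, where ties
are absent and all tie conventions coincide.  Collinear or separating
covariates are flagged per covariate with a missing hazard ratio instead
of aborting the fit — mirroring how published multivariable tables report
NA for levels confounded with another covariate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .containers import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class SurvivalContrast:
    """Log-rank contrast between >= 2 groups plus per-group KM curves."""

    groups: list[str]
    logrank_statistic: float
    df: int
    p: float
    km_curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    pairwise: pd.DataFrame | None = None  # group_a, group_b, statistic, p


@dataclass
class HazardTable:
    """Rows of (covariate, level, HR, ci_low, ci_high, p); NaN HR = flagged fit."""

    table: pd.DataFrame
    multivariable: bool


def km_logrank(clin: ClinicalTable, groups: pd.Series) -> SurvivalContrast:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    For three or more groups the overall (k-1)-df statistic is reported and
    every pairwise contrast is emitted as well.
    """
    common = clin.samples.intersection(groups.index)
    if len(common) < len(clin.samples):
        logger.warning("dropping %d clinical sample(s) without a group label", len(clin.samples) - len(common))
    time = clin.time.loc[common]
    event = clin.event.loc[common]
    g = groups.loc[common].astype(str)

    labels = [lab for lab in dict.fromkeys(g)]
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")

    res = multivariate_logrank_test(time, g, event)
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=lab)
        tab = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[lab].to_numpy(),
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )

    pairwise = None
    if len(labels) > 2:
        rows = []
        for a, b in itertools.combinations(labels, 2):
            mask = g.isin([a, b])
            r = logrank_test(
                time[mask & (g == a)], time[mask & (g == b)],
                event[mask & (g == a)], event[mask & (g == b)],
            )
            rows.append({"group_a": a, "group_b": b, "statistic": float(r.test_statistic), "p": float(r.p_value)})
        pairwise = pd.DataFrame(rows)

    return SurvivalContrast(
        groups=labels,
        logrank_statistic=float(res.test_statistic),
        df=len(labels) - 1,
        p=float(res.p_value),
        km_curves=curves,
        pairwise=pairwise,
    )


def _design_matrix(
    clin: ClinicalTable, covariates: list[str], reference_levels: dict[str, str] | None
) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals are dummy-coded against
    a stated (default: first-seen) reference level."""
    refs = reference_levels or {}
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov not in clin.data.columns:
            raise ValueError(f"covariate {cov!r} absent from clinical table")
        col = clin.data[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float)
        else:
            levels = list(dict.fromkeys(col.dropna()))
            ref = refs.get(cov, levels[0])
            for level in levels:
                if level == ref:
                    continue
                cols[f"{cov}[{level} vs {ref}]"] = (col == level).astype(float)
    return pd.DataFrame(cols, index=clin.samples)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop columns that are linearly dependent on earlier ones."""
    keep: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy(dtype=float)
        centered = trial - trial.mean(axis=0)
        if np.linalg.matrix_rank(centered) < len(keep) + 1:
            dropped.append(col)
        else:
            keep.append(col)
    return X[keep], dropped


def cox_regression(
    clin: ClinicalTable,
    covariates: list[str],
    multivariable: bool = False,
    reference_levels: dict[str, str] | None = None,
) -> HazardTable:
    """Cox proportional-hazards fit, one covariate at a time or jointly.

    Returns hazard ratios with Wald 95% confidence intervals and p-values.
    Collinear columns and non-converging covariates are flagged with NaN
    rows (``flag`` column) rather than raising.
    """
    X = _design_matrix(clin, covariates, reference_levels)

    def fit_block(cols: pd.DataFrame) -> pd.DataFrame:
        cols, dropped = _drop_collinear(cols)
        rows = []
        for name in dropped:
            logger.warning("covariate column %r is collinear; reported as NA", name)
            rows.append({"covariate": name, "HR": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "flag": "collinear"})
        if cols.shape[1] == 0:
            return pd.DataFrame(rows)
        df = cols.copy()
        df["time"] = clin.time
        df["event"] = clin.event
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            logger.warning("Cox fit failed to converge (%s); block reported as NA", exc)
            for name in cols.columns:
                rows.append({"covariate": name, "HR": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan, "flag": "non-convergence"})
            return pd.DataFrame(rows)
        summary = cph.summary
        for name in cols.columns:
            s = summary.loc[name]
            rows.append({
                "covariate": name,
                "HR": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef lower 95%"])),
                "ci_high": float(np.exp(s["coef upper 95%"])),
                "p": float(s["p"]),
                "flag": "",
            })
        return pd.DataFrame(rows)

    if multivariable:
        table = fit_block(X)
    else:
        blocks = [fit_block(X[[c]]) for c in X.columns]
        table = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()

    bad = table["HR"].notna() & ~(
        (table["ci_low"] <= table["HR"]) & (table["HR"] <= table["ci_high"])
    )
    if bad.any():  # defensive; Wald CI always brackets the point estimate
        raise RuntimeError("hazard ratio outside its confidence interval")
    return HazardTable(table=table, multivariable=multivariable)
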