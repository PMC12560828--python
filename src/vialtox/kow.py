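"""Narcosis screening: linear regression of BMC50 on predicted logKow.

Under a narcotic (baseline-toxicity) mode of action, potency tracks
membrane partitioning, so BMC50 should decrease roughly linearly with
hydrophobicity (logKow).  This module fits that simple model by
ordinary least squares over the chemicals that have an estimated
any-effect BMC50, optionally after removing predictor outliers flagged
by the interquartile-range rule, and summarises fit quality by R2, the
slope p-value, and the average relative error
mean(|observed - predicted| / observed) x 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import iqr_outliers

__all__ = [
    "PotencyRecord",
    "PotencyModel",
    "PotencyResults",
    "fit_potency_model",
    "average_relative_error",
]


@dataclass(frozen=True)
class PotencyRecord:
    """A chemical's predicted logKow and (optional) any-effect BMC50."""

    chemical: str
    logkow: float
    bmc50: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.logkow):
            raise ValueError("logkow must be finite")
        if self.bmc50 is not None and self.bmc50 <= 0:
            raise ValueError("bmc50 must be positive when present")


@dataclass(frozen=True)
class PotencyResults:
    """OLS fit of BMC50 on logKow with its diagnostics."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    residuals: np.ndarray
    fitted: np.ndarray
    chemicals: tuple
    avg_rel_error_pct: float
    outliers_removed: tuple = field(default_factory=tuple)

    def predict(self, logkow):
        return self.intercept + self.slope * np.asarray(logkow, dtype=float)

    def summary(self) -> str:
        lines = [
            "Linear narcosis model: BMC50 ~ logKow",
            "=" * 40,
            f"n modeled            {len(self.chemicals)}",
            f"slope                {self.slope:10.4f}",
            f"intercept            {self.intercept:10.4f}",
            f"R-squared            {self.r2:10.4f}",
            f"slope p-value        {self.p_value:10.4g}",
            f"avg relative error   {self.avg_rel_error_pct:9.1f}%",
        ]
        if self.outliers_removed:
            lines.append("outliers removed     "
                         + ", ".join(self.outliers_removed))
        return "\n".join(lines)


class PotencyModel:
    """BMC50-on-logKow regression over chemicals with an estimated BMC.

    Chemicals lacking a BMC50 are kept for reporting (their high
    logKow with no observed effect is itself informative against
    narcosis) but never enter the fit.
    """

    def __init__(self, records):
        self.records = tuple(records)
        self.modeled = tuple(r for r in self.records if r.bmc50 is not None)
        self.unmodeled = tuple(r for r in self.records if r.bmc50 is None)
        if len(self.modeled) < 3:
            raise ValueError("need >= 3 chemicals with a BMC50 to fit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, chemical_col: str = "chemical",
                       logkow_col: str = "logkow", bmc_col: str = "bmc"):
        recs = [PotencyRecord(r[chemical_col], float(r[logkow_col]),
                              None if pd.isna(r[bmc_col]) else float(r[bmc_col]))
                for _, r in df.iterrows()]
        return cls(recs)

    def predictor_outliers(self):
        """Chemicals whose logKow is an IQR outlier among modeled records."""
        kow = np.array([r.logkow for r in self.modeled])
        flags = iqr_outliers(kow)
        return tuple(r.chemical for r, f in zip(self.modeled, flags) if f)

    def fit(self, exclude_outliers: bool = False) -> PotencyResults:
        """OLS fit; ``exclude_outliers`` drops IQR-flagged predictors.

        Fitting with all modeled chemicals and refitting after outlier
        removal correspond to the screening workflow's model A and
        model B.
        """
        removed = self.predictor_outliers() if exclude_outliers else ()
        recs = [r for r in self.modeled if r.chemical not in removed]
        if len(recs) < 3:
            raise ValueError("too few chemicals left after outlier removal")
        x = np.array([r.logkow for r in recs])
        y = np.array([r.bmc50 for r in recs])
        if np.ptp(x) == 0:
            raise ValueError("constant predictor")
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        resid = np.asarray(ols.resid)
        are = float(np.mean(np.abs(resid) / y) * 100.0)
        return PotencyResults(
            slope=float(ols.params[1]), intercept=float(ols.params[0]),
            r2=float(ols.rsquared), p_value=float(ols.pvalues[1]),
            residuals=resid, fitted=np.asarray(ols.fittedvalues),
            chemicals=tuple(r.chemical for r in recs),
            avg_rel_error_pct=are, outliers_removed=removed)


def fit_potency_model(records, exclude_outliers: bool = False
                      ) -> PotencyResults:
    """Functional wrapper around :class:`PotencyModel`."""
    return PotencyModel(records).fit(exclude_outliers)


def average_relative_error(results: PotencyResults, records=None) -> float:
    """Mean |observed - predicted| / observed over modeled chemicals, in %.

    With ``records`` given, recomputed from scratch against the fitted
    line; otherwise taken from the residual vector (identical values).
    """
    if records is None:
        obs = results.fitted + results.residuals
        return float(np.mean(np.abs(results.residuals) / obs) * 100.0)
    recs = [r for r in records
            if r.bmc50 is not None and r.chemical in results.chemicals]
    obs = np.array([r.bmc50 for r in recs])
    if np.any(obs == 0):
        raise ValueError("observed bmc50 must be nonzero")
    pred = results.predict([r.logkow for r in recs])
    return float(np.mean(np.abs(obs - pred) / obs) * 100.0)
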