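"""Fit-quality diagnostics computed from the residuals of a 4PL fit.

Nine scores: R2, adjusted R2, standard error of the estimate (Sy.x), RMSE,
Shapiro-Wilk residual-normality p-value, explained variance, maximum
absolute residual, root mean absolute error (RMAE, defined here as
sqrt(mean |residual|)) and MAPE.  Plain MAE is reported as well under its
own name since RMAE is occasionally used for either quantity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["QualityReport", "quality_report"]


@dataclass
class QualityReport:
    r2: float | None = None
    adjusted_r2: float | None = None
    sy_x: float | None = None
    rmse: float | None = None
    shapiro_p: float | None = None
    explained_variance: float | None = None
    max_residual: float | None = None
    rmae: float | None = None
    mae: float | None = None
    mape: float | None = None
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "adj_r2": self.adjusted_r2,
            "sy_x": self.sy_x,
            "rmse": self.rmse,
            "shapiro_p": self.shapiro_p,
            "explained_variance": self.explained_variance,
            "max_residual": self.max_residual,
            "rmae": self.rmae,
            "mae": self.mae,
            "mape": self.mape,
        }


def quality_report(fit, observed=None, n_params: int = 4) -> QualityReport:
    """Quality suite for a fit.

    *fit* is either a results object (residuals and observations taken from
    it) or an array of fitted values, in which case *observed* must be
    given.  Shapiro-Wilk needs at least five residuals and is left
    undefined below that; R2-type scores are undefined (with a note) when
    the observations have zero variance.
    """
    if observed is None:
        if getattr(fit, "converged", True) is False:
            return QualityReport(notes=[f"fit not convergent: {getattr(fit, 'reason', '')}"])
        observed = np.asarray(fit.model._y, dtype=float)
        fitted = np.asarray(fit.fittedvalues, dtype=float)
        n_params = getattr(fit, "n_params", n_params)
    else:
        fitted = np.asarray(fit, dtype=float)
        observed = np.asarray(observed, dtype=float)
    resid = observed - fitted
    n = resid.size
    report = QualityReport()

    sse = float(np.dot(resid, resid))
    abs_resid = np.abs(resid)
    report.rmse = math.sqrt(sse / n)
    report.max_residual = float(abs_resid.max())
    report.mae = float(abs_resid.mean())
    report.rmae = math.sqrt(report.mae)
    if n > n_params:
        report.sy_x = math.sqrt(sse / (n - n_params))
    else:
        report.notes.append("sy_x undefined: no residual degrees of freedom")

    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst > 0:
        report.r2 = 1.0 - sse / sst
        if n - n_params - 1 > 0:
            report.adjusted_r2 = 1.0 - (1.0 - report.r2) * (n - 1) / (n - n_params - 1)
        var_obs = float(np.var(observed))
        report.explained_variance = 1.0 - float(np.var(resid)) / var_obs
    else:
        report.notes.append("r2 undefined: observations have zero variance")

    nonzero = observed != 0
    if nonzero.any():
        report.mape = float(100.0 * np.mean(abs_resid[nonzero] / np.abs(observed[nonzero])))
    else:
        report.notes.append("mape undefined: all observations are zero")

    if n >= 5:
        if np.ptp(resid) > 0:
            report.shapiro_p = float(stats.shapiro(resid).pvalue)
        else:
            report.notes.append("shapiro_p undefined: identical residuals")
    else:
        report.notes.append("shapiro_p undefined: fewer than 5 residuals")
    return report
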