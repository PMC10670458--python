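"""Dose-response series containers and replicate summarisation.

A :class:`DoseResponseSeries` holds one (sample, drug) experiment: molar
concentrations plus a replicate response matrix already converted to percent
inhibition.  :func:`summarize` collapses replicates to per-concentration
means (and SEM when at least three replicate columns exist), optionally
removing outlier wells first with an iterative one-sided Grubbs test.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseSeries",
    "SeriesSummary",
    "grubbs_critical",
    "grubbs_mask",
    "summarize",
]


@dataclass
class DoseResponseSeries:
    """One (sample, drug) experiment in canonical units.

    concentrations are molar, strictly positive and sorted ascending;
    ``responses`` is an (n_concentrations, n_replicates) matrix of percent
    inhibition, NaN marking a missing well.
    """

    sample_id: str
    drug_id: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if resp.ndim == 1:
            resp = resp[:, None]
        if conc.ndim != 1 or conc.size == 0:
            raise ValueError("concentrations must be a non-empty 1-D array")
        if np.any(~np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("concentrations must be finite and strictly positive")
        if resp.shape[0] != conc.size:
            raise ValueError(
                f"response matrix has {resp.shape[0]} rows for {conc.size} concentrations"
            )
        order = np.argsort(conc, kind="stable")
        conc = conc[order]
        resp = resp[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be distinct")
        self.concentrations = conc
        self.responses = resp

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[1]

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.drug_id)


def grubbs_critical(n: int, alpha: float) -> float:
    """Critical value of the one-sided Grubbs statistic for sample size *n*."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_mask(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative one-sided-max Grubbs test on one replicate set.

    Tests the largest observation against the rest, removes it if the Grubbs
    statistic exceeds the critical value, and repeats on the survivors — at
    most one removal per pass, stopping once fewer than three finite values
    remain or the maximum is no longer extreme.  Returns a boolean mask of
    flagged cells (NaN cells are never flagged).
    """
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    while True:
        alive = np.isfinite(x) & ~mask
        n = int(alive.sum())
        if n < 3:
            break
        vals = x[alive]
        sd = vals.std(ddof=1)
        if sd == 0.0:
            break
        g = (vals.max() - vals.mean()) / sd
        if g <= grubbs_critical(n, alpha):
            break
        # flag the (first) maximal surviving cell
        idx_alive = np.flatnonzero(alive)
        mask[idx_alive[np.argmax(vals)]] = True
    return mask


@dataclass
class SeriesSummary:
    """Per-concentration means (and SEM) of a series after outlier handling.

    ``sem`` is None when fewer than three replicate columns exist — SEM is
    undefined there, not zero.  ``mean_response`` may contain NaN where a
    concentration lost all its replicates; fitting skips those points.
    """

    series: DoseResponseSeries
    mean_response: np.ndarray
    sem: np.ndarray | None
    outlier_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.series.responses.shape, dtype=bool)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return self.series.log10_concentrations

    @property
    def concentrations(self) -> np.ndarray:
        return self.series.concentrations

    @property
    def n_replicates(self) -> int:
        return self.series.n_replicates


def summarize(
    series: DoseResponseSeries,
    remove_outliers: bool = False,
    alpha: float = 0.05,
) -> SeriesSummary:
    """Collapse replicates to means/SEM, optionally Grubbs-filtering each row.

    Outlier removal is a no-op (with a warning) below three replicate
    columns.  Means are computed over surviving, non-missing wells only.
    """
    resp = series.responses
    n_conc, n_rep = resp.shape
    mask = np.zeros(resp.shape, dtype=bool)
    if remove_outliers:
        if n_rep >= 3:
            for i in range(n_conc):
                mask[i] = grubbs_mask(resp[i], alpha=alpha)
        else:
            logger.warning(
                "outlier removal skipped for %s/%s: needs >= 3 replicate columns, got %d",
                series.sample_id,
                series.drug_id,
                n_rep,
            )
    mean = np.full(n_conc, np.nan)
    sem = np.full(n_conc, np.nan) if n_rep >= 3 else None
    for i in range(n_conc):
        vals = resp[i][np.isfinite(resp[i]) & ~mask[i]]
        if vals.size == 0:
            logger.warning(
                "concentration %.3g M of %s/%s has no surviving replicates; dropped",
                series.concentrations[i],
                series.sample_id,
                series.drug_id,
            )
            continue
        mean[i] = vals.mean()
        if sem is not None and vals.size >= 2:
            sem[i] = vals.std(ddof=1) / math.sqrt(vals.size)
    return SeriesSummary(series=series, mean_response=mean, sem=sem, outlier_mask=mask)
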