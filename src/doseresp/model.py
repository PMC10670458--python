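"""Four-parameter logistic (4PL) dose-response model.

The model is the standard sigmoid on a log10 molar concentration axis,

    f(c) = response_min + (response_max - response_min)
           / (1 + 10 ** (hillslope * (log10_ic50 - log10 c)))

with responses in percent inhibition, so the curve is non-decreasing in
concentration whenever hillslope > 0.  ``log10_ic50`` is the midpoint
parameter — the "traditional" (relative) IC50.

The API follows the Model/Results convention: build a
:class:`FourParamLogistic` from data, call :meth:`~FourParamLogistic.fit`
to obtain a :class:`FourParamLogisticResults` carrying the estimates, their
standard errors, convergence diagnostics and residuals, with ``metrics()``,
``quality()``, ``plot()`` and ``simulate()`` hanging off the results.

Fitting is two-stage: an unconstrained least-squares pass
(:func:`scipy.optimize.curve_fit`) from a heuristic initial guess, then a
bounded refinement with :mod:`lmfit`.  Refinement must not increase the sum
of squared errors; a fit that violates that, or its bounds, is reported as
non-convergent rather than raising.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .series import DoseResponseSeries, SeriesSummary, summarize

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

__all__ = [
    "LogisticParams",
    "FitBounds",
    "evaluate_4pl",
    "initial_guess",
    "FourParamLogistic",
    "FourParamLogisticResults",
]


@dataclass(frozen=True)
class LogisticParams:
    """The four 4PL parameters (percent inhibition asymptotes, slope, log10 M midpoint)."""

    response_min: float
    response_max: float
    hillslope: float
    log10_ic50: float

    def as_tuple(self) -> tuple:
        return (self.response_min, self.response_max, self.hillslope, self.log10_ic50)


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the bounded refinement stage.

    Asymptotes tolerate modest assay overshoot (below 0 / above 100); the
    hill slope is constrained positive because responses are inhibition;
    the midpoint may sit up to ``log10_ic50_pad`` decades outside the
    tested range.
    """

    response_min: tuple = (-10.0, 60.0)
    response_max: tuple = (-10.0, 120.0)
    hillslope: tuple = (1e-3, 20.0)
    log10_ic50_pad: float = 3.0


def _logistic(x, response_min, response_max, hillslope, log10_ic50):
    """4PL over log10 concentration; expit keeps the 10** term overflow-safe."""
    z = LN10 * hillslope * (np.asarray(x, dtype=float) - log10_ic50)
    return response_min + (response_max - response_min) * expit(z)


def _coerce_params(params) -> LogisticParams:
    if isinstance(params, LogisticParams):
        return params
    if hasattr(params, "response_min"):
        return LogisticParams(
            float(params.response_min),
            float(params.response_max),
            float(params.hillslope),
            float(params.log10_ic50),
        )
    rmin, rmax, h, x50 = params
    return LogisticParams(float(rmin), float(rmax), float(h), float(x50))


def evaluate_4pl(params, concentration):
    """Evaluate the 4PL at molar *concentration* (> 0); scalar in, scalar out."""
    p = _coerce_params(params)
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc <= 0) or np.any(~np.isfinite(conc)):
        raise ValueError("concentration must be positive and finite")
    out = _logistic(np.log10(conc), *p.as_tuple())
    return float(out) if out.ndim == 0 else out


def initial_guess(x, y=None) -> LogisticParams:
    """Heuristic starting point for the optimiser.

    Accepts either a :class:`SeriesSummary` or explicit (log10 conc, mean)
    arrays.  Asymptotes start at the observed extremes, the slope at 1, and
    the midpoint at the tested concentration whose mean lies nearest the
    half-way response (ties broken toward the lower concentration).
    Requires at least four distinct concentrations with defined means.
    """
    if isinstance(x, SeriesSummary):
        summary = x
        x = summary.log10_concentrations
        y = summary.mean_response
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.unique(x).size < 4:
        raise ValueError("initial guess needs >= 4 distinct concentrations")
    rmin = float(y.min())
    rmax = float(y.max())
    mid = 0.5 * (rmin + rmax)
    # argmin on ascending x returns the lowest concentration on ties
    idx = int(np.argmin(np.abs(y - mid)))
    return LogisticParams(rmin, rmax, 1.0, float(x[idx]))


class FourParamLogistic:
    """4PL regression model for one dose-response series.

    Parameters
    ----------
    concentrations : array of molar concentrations (> 0)
    response : per-concentration mean percent inhibition (NaN = dropped point)
    sem : optional per-concentration SEM, descriptive only (plots)
    """

    def __init__(self, concentrations, response, sem=None, *, sample_id="", drug_id=""):
        conc = np.asarray(concentrations, dtype=float)
        y = np.asarray(response, dtype=float)
        if conc.shape != y.shape or conc.ndim != 1:
            raise ValueError("concentrations and response must be matching 1-D arrays")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive (molar)")
        order = np.argsort(conc, kind="stable")
        self.concentrations = conc[order]
        self.response = y[order]
        self.sem = None if sem is None else np.asarray(sem, dtype=float)[order]
        self.sample_id = sample_id
        self.drug_id = drug_id
        valid = np.isfinite(self.response)
        self._x = np.log10(self.concentrations[valid])
        self._y = self.response[valid]

    # ---------------------------------------------------------------- constructors
    @classmethod
    def from_summary(cls, summary: SeriesSummary) -> "FourParamLogistic":
        return cls(
            summary.concentrations,
            summary.mean_response,
            sem=summary.sem,
            sample_id=summary.series.sample_id,
            drug_id=summary.series.drug_id,
        )

    @classmethod
    def from_series(
        cls,
        series: DoseResponseSeries,
        remove_outliers: bool = False,
        alpha: float = 0.05,
    ) -> "FourParamLogistic":
        """Summarise replicates (mean over non-outlier wells) and build the model."""
        return cls.from_summary(summarize(series, remove_outliers=remove_outliers, alpha=alpha))

    @classmethod
    def from_dataframe(cls, df, convention=None, schema=None, **kwargs) -> "FourParamLogistic":
        """Build from a long-format frame holding exactly one (sample, drug) pair."""
        from .io import series_from_frame

        all_series = series_from_frame(df, convention=convention, schema=schema)
        if len(all_series) != 1:
            raise ValueError(
                f"from_dataframe expects one (sample, drug) pair, found {len(all_series)}; "
                "use doseresp.io.read_batch for batch input"
            )
        return cls.from_series(all_series[0], **kwargs)

    # ---------------------------------------------------------------- interface
    @property
    def nobs(self) -> int:
        return self._y.size

    def predict(self, params, concentrations=None):
        conc = self.concentrations if concentrations is None else concentrations
        return evaluate_4pl(params, conc)

    def _sse(self, theta) -> float:
        r = self._y - _logistic(self._x, *theta)
        return float(np.dot(r, r))

    def fit(
        self,
        bounds: FitBounds | None = None,
        xtol: float = 1e-12,
        ftol: float = 1e-12,
        max_nfev: int = 10000,
    ) -> "FourParamLogisticResults":
        """Two-stage least-squares fit on the mean responses.

        Never raises on numeric failure: degenerate data (flat response,
        too few points) and optimiser breakdowns yield a results object
        with ``converged=False`` and a ``reason``.
        """
        bounds = bounds or FitBounds()
        x, y = self._x, self._y

        def failed(reason):
            logger.warning("fit failed for %s/%s: %s", self.sample_id, self.drug_id, reason)
            return FourParamLogisticResults(self, None, {}, False, reason, math.nan, math.nan)

        if np.unique(x).size < 4:
            return failed("fewer than 4 distinct concentrations")
        if float(np.ptp(y)) < 1e-9:
            return failed("flat response")

        guess = initial_guess(x, y)
        lo_x50 = x.min() - bounds.log10_ic50_pad
        hi_x50 = x.max() + bounds.log10_ic50_pad
        box = [bounds.response_min, bounds.response_max, bounds.hillslope, (lo_x50, hi_x50)]
        p0 = np.clip(
            np.array(guess.as_tuple()),
            [lo for lo, _ in box],
            [hi for _, hi in box],
        )

        # stage 1: unconstrained least squares
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt1, _ = curve_fit(
                    _logistic, x, y, p0=p0, maxfev=max_nfev, xtol=xtol, ftol=ftol
                )
            if not np.all(np.isfinite(popt1)):
                raise RuntimeError("non-finite stage-1 parameters")
            sse1 = self._sse(popt1)
        except Exception as exc:  # stage 2 can still rescue from the guess
            logger.debug("stage-1 fit fell back to initial guess: %s", exc)
            popt1 = p0
            sse1 = self._sse(p0)

        # stage 2: bounded refinement seeded by stage 1
        seed = np.clip(popt1, [lo for lo, _ in box], [hi for _, hi in box])
        lm = lmfit.Model(_logistic, independent_vars=["x"])
        pars = lm.make_params(
            response_min=dict(value=seed[0], min=box[0][0], max=box[0][1]),
            response_max=dict(value=seed[1], min=box[1][0], max=box[1][1]),
            hillslope=dict(value=seed[2], min=box[2][0], max=box[2][1]),
            log10_ic50=dict(value=seed[3], min=box[3][0], max=box[3][1]),
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res2 = lm.fit(
                    y,
                    pars,
                    x=x,
                    method="least_squares",
                    max_nfev=max_nfev,
                    fit_kws={"xtol": xtol, "ftol": ftol, "gtol": 1e-14},
                )
        except Exception as exc:
            return failed(f"bounded refinement failed: {exc}")

        theta2 = np.array([res2.params[k].value for k in
                           ("response_min", "response_max", "hillslope", "log10_ic50")])
        if not np.all(np.isfinite(theta2)):
            return failed("non-finite refined parameters")
        sse2 = self._sse(theta2)
        if sse2 > sse1 * (1 + 1e-9) + 1e-9:
            return failed("bounded refinement increased SSE")
        if theta2[1] < theta2[0]:
            return failed("response_max below response_min")

        params = LogisticParams(*theta2)
        bse = {
            k: (res2.params[k].stderr if res2.params[k].stderr is not None else math.nan)
            for k in ("response_min", "response_max", "hillslope", "log10_ic50")
        }
        return FourParamLogisticResults(self, params, bse, True, "", sse2, sse1)


class FourParamLogisticResults:
    """Fit results: estimates, standard errors, diagnostics and downstream metrics."""

    n_params = 4

    def __init__(self, model, params, bse, converged, reason, sse, sse_stage1):
        self.model = model
        self._params = params
        self.bse = dict(bse)
        self.converged = bool(converged)
        self.reason = reason
        self.sse = sse
        self.sse_stage1 = sse_stage1
        if params is not None:
            self.fittedvalues = _logistic(model._x, *params.as_tuple())
            self.resid = model._y - self.fittedvalues
        else:
            self.fittedvalues = np.full(model._x.shape, np.nan)
            self.resid = np.full(model._x.shape, np.nan)

    # parameter access -----------------------------------------------------
    @property
    def params(self) -> LogisticParams | None:
        return self._params

    def _p(self, name):
        return getattr(self._params, name) if self._params is not None else math.nan

    @property
    def response_min(self):
        return self._p("response_min")

    @property
    def response_max(self):
        return self._p("response_max")

    @property
    def hillslope(self):
        return self._p("hillslope")

    @property
    def log10_ic50(self):
        return self._p("log10_ic50")

    @property
    def ic50(self):
        """Traditional (relative) IC50 in molar: the fitted midpoint."""
        return 10.0 ** self.log10_ic50

    @property
    def nobs(self):
        return self.model.nobs

    @property
    def n_points(self):
        return self.model.nobs

    @property
    def df_resid(self):
        return self.model.nobs - self.n_params

    def predict(self, concentrations=None):
        if self._params is None:
            raise ValueError(f"fit did not converge: {self.reason}")
        return self.model.predict(self._params, concentrations)

    # downstream -----------------------------------------------------------
    def metrics(self, config=None):
        """Compute the metric bundle (IC50s, AUC, DSS1-3, xepto50 score)."""
        from .metrics import MetricConfig, compute_metrics

        if config is None:
            config = MetricConfig.for_model(self.model)
        return compute_metrics(self, config)

    def quality(self):
        """Residual-based fit-quality report."""
        from .quality import quality_report

        return quality_report(self)

    def plot(self, ax=None, **kwargs):
        from .plotting import plot_fit

        return plot_fit(self, ax=ax, **kwargs)

    def simulate(self, noise_sd=2.0, n_replicates=3, seed=0):
        """Draw a replicate response matrix from the fitted curve plus noise."""
        from .synthetic import SyntheticSpec, generate

        if self._params is None:
            raise ValueError(f"fit did not converge: {self.reason}")
        spec = SyntheticSpec(
            response_min=self.response_min,
            response_max=self.response_max,
            hillslope=self.hillslope,
            log10_ic50=self.log10_ic50,
            concentrations=self.model.concentrations,
            n_replicates=n_replicates,
            noise_sd=noise_sd,
            seed=seed,
            sample_id=self.model.sample_id or "sim",
            drug_id=self.model.drug_id or "sim",
        )
        return generate(spec).series

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        name = f"{self.model.sample_id}/{self.model.drug_id}".strip("/") or "<series>"
        lines = [
            "Four-parameter logistic fit",
            "===========================",
            f"series:      {name}",
            f"n points:    {self.nobs}",
            f"converged:   {self.converged}" + (f"  ({self.reason})" if self.reason else ""),
            f"SSE:         {self.sse:.6g}" if np.isfinite(self.sse) else "SSE:         nan",
            "",
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
            "-" * 42,
        ]
        for k in ("response_min", "response_max", "hillslope", "log10_ic50"):
            est = self._p(k)
            se = self.bse.get(k, math.nan)
            lines.append(f"{k:<14}{est:>14.6g}{se:>14.4g}")
        if self._params is not None:
            lines += ["", f"{'IC50 (M)':<14}{self.ic50:>14.6g}"]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FourParamLogisticResults converged={self.converged} "
            f"params={self._params}>"
        )
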