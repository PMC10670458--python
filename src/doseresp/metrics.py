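"""Drug-sensitivity metrics computed from a fitted 4PL curve and its data.

The bundle covers:

* traditional (relative) IC50 — the fitted midpoint parameter, also
  reported as -log10 IC50;
* interpolated (absolute) IC50 — where the fitted curve crosses 50 %
  inhibition, solved in closed form; undefined when the curve never
  reaches 50 %;
* AUC — trapezoidal area of the mean responses above a baseline (default
  10 % inhibition) over the tested log10-concentration range, matching
  the data-trapezoid convention of spreadsheet/Prism AUC;
* DSS1-3 — normalised areas of the *fitted* curve above an activity
  threshold over the tested range, with increasing normalisation,
  following the published drug-sensitivity-score definitions;
* xepto50 — a position-invariant shape score: the normalised area between
  the fitted curve and the 50 % baseline over a fixed log-concentration
  window starting at the interpolated IC50.

All fitted-curve areas use the closed-form logistic antiderivative

    \\int f dx = rmin * x + (rmax - rmin) * ln(1 + 10**(h (x - x50))) / (h ln 10)

evaluated in overflow-safe form, so the scores are deterministic and carry
no quadrature error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import LN10, FourParamLogistic, _coerce_params

__all__ = [
    "MetricConfig",
    "MetricBundle",
    "logistic_area",
    "crossing_log10",
    "interpolated_ic50",
    "auc",
    "dss",
    "xepto50_score",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricConfig:
    """Knobs for the metric bundle.

    auc_baseline : percent inhibition subtracted before the AUC trapezoid
        (default 10).
    xepto_window : width C of the xepto50 integration window in log10
        concentration units (default 2.0, i.e. a hundred-fold span).
    dss_threshold : minimum activity t (percent inhibition) for the DSS
        area (default 10).
    tested_range : (log10 min, log10 max) of the tested concentrations;
        required for AUC and DSS.
    """

    auc_baseline: float = 10.0
    xepto_baseline: float = 50.0  # fixed by the score's definition
    xepto_window: float = 2.0
    dss_threshold: float = 10.0
    tested_range: tuple | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc_baseline < 100.0):
            raise ValueError("auc_baseline must lie in [0, 100)")
        if self.xepto_window <= 0:
            raise ValueError("xepto_window must be positive")
        if self.tested_range is not None and not (self.tested_range[0] < self.tested_range[1]):
            raise ValueError("tested_range must be non-degenerate (log10 min < log10 max)")

    @classmethod
    def for_model(cls, model: FourParamLogistic, **kwargs) -> "MetricConfig":
        x = np.log10(model.concentrations)
        return cls(tested_range=(float(x.min()), float(x.max())), **kwargs)


_UNDEFINED = None


@dataclass
class MetricBundle:
    """The metric bundle for one fitted series; None marks undefined values."""

    ic50_traditional: float | None = None
    neg_log10_ic50: float | None = None
    ic50_interpolated: float | None = None
    auc: float | None = None
    dss1: float | None = None
    dss2: float | None = None
    dss3: float | None = None
    xepto50: float | None = None
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "ic50_M": self.ic50_traditional,
            "neg_log10_ic50": self.neg_log10_ic50,
            "ic50_interp_M": self.ic50_interpolated,
            "auc": self.auc,
            "dss1": self.dss1,
            "dss2": self.dss2,
            "dss3": self.dss3,
            "xepto50": self.xepto50,
        }


# --------------------------------------------------------------------------- areas
def _softplus10(u: float) -> float:
    """ln(1 + 10**u), overflow-safe for large |u|."""
    if u > 0:
        return u * LN10 + math.log1p(10.0 ** (-u))
    return math.log1p(10.0**u)


def _area_shifted(rmin: float, rmax: float, h: float, a: float, b: float) -> float:
    """Integral of the 4PL over [a, b] in midpoint-relative coordinates u = x - x50.

    Working relative to the midpoint makes every downstream score that uses
    only shape parameters exactly independent of the curve's position.
    """
    return rmin * (b - a) + (rmax - rmin) * (_softplus10(h * b) - _softplus10(h * a)) / (h * LN10)


def logistic_area(params, a: float, b: float) -> float:
    """Closed-form integral of the fitted curve over log10 concentration in [a, b]."""
    p = _coerce_params(params)
    return _area_shifted(
        p.response_min, p.response_max, p.hillslope, a - p.log10_ic50, b - p.log10_ic50
    )


def _crossing_shifted(rmin: float, rmax: float, h: float, level: float) -> float | None:
    """u = x - x50 where the curve equals *level*; None when level is outside (rmin, rmax)."""
    if not (rmin < level < rmax):
        return None
    return -(1.0 / h) * math.log10((rmax - level) / (level - rmin))


def crossing_log10(params, level: float) -> float | None:
    p = _coerce_params(params)
    u = _crossing_shifted(p.response_min, p.response_max, p.hillslope, level)
    return None if u is None else p.log10_ic50 + u


# --------------------------------------------------------------------------- IC50s
def interpolated_ic50(fit) -> float | None:
    """Absolute IC50 (molar): where the fitted curve crosses 50 % inhibition.

    Closed form: log10 c = log10_ic50 - (1/h) * log10((rmax - 50)/(50 - rmin)).
    Undefined (None) when 50 lies outside the open asymptote interval or the
    fit did not converge.
    """
    if getattr(fit, "converged", True) is False:
        return None
    x = crossing_log10(fit, 50.0)
    return None if x is None else 10.0**x


# --------------------------------------------------------------------------- AUC
def _clipped_segment_area(x0, x1, y0, y1, baseline) -> float:
    """Exact area of max(linear segment - baseline, 0), splitting at the crossing."""
    d0, d1 = y0 - baseline, y1 - baseline
    if d0 <= 0 and d1 <= 0:
        return 0.0
    if d0 >= 0 and d1 >= 0:
        return 0.5 * (d0 + d1) * (x1 - x0)
    xc = x0 + (x1 - x0) * d0 / (d0 - d1)
    if d0 > 0:
        return 0.5 * d0 * (xc - x0)
    return 0.5 * d1 * (x1 - xc)


def auc(summary_or_xy, config: MetricConfig | None = None) -> float:
    """Trapezoidal AUC of the mean responses above the baseline.

    Integrates max(piecewise-linear interpolant - baseline, 0) exactly over
    log10 concentration (segments crossing the baseline are split at the
    crossing point).  Operates on the raw means, not the fitted curve.
    """
    config = config or MetricConfig()
    if hasattr(summary_or_xy, "mean_response"):
        x = np.asarray(summary_or_xy.log10_concentrations, dtype=float)
        y = np.asarray(summary_or_xy.mean_response, dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in summary_or_xy)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size < 2:
        raise ValueError("AUC needs at least two concentrations")
    b = config.auc_baseline
    return float(
        sum(
            _clipped_segment_area(x[i], x[i + 1], y[i], y[i + 1], b)
            for i in range(x.size - 1)
        )
    )


# --------------------------------------------------------------------------- DSS
def dss_area(fit, config: MetricConfig) -> tuple:
    """(A, x1): closed-form area of the fitted curve above the DSS threshold.

    x1 is the log10 concentration where activity first exceeds the
    threshold t (clamped to the tested range); A integrates (fitted - t)
    from x1 to the top of the tested range.
    """
    if config.tested_range is None:
        raise ValueError("DSS needs MetricConfig.tested_range")
    p = _coerce_params(fit)
    x_min, x_max = config.tested_range
    t = config.dss_threshold
    if p.response_max <= t:
        return 0.0, x_max
    if p.response_min >= t:
        x1 = x_min
    else:
        x1 = p.log10_ic50 + _crossing_shifted(p.response_min, p.response_max, p.hillslope, t)
        x1 = min(max(x1, x_min), x_max)
    area = logistic_area(p, x1, x_max) - t * (x_max - x1)
    return max(area, 0.0), x1


def dss(fit, config: MetricConfig | None = None, variant: int = 1) -> float | None:
    """Drug sensitivity score, variants 1-3.

    With A the area of the fitted curve above threshold t between its first
    crossing x1 and the top of the tested range:

        DSS1 = 100 * A / ((100 - t) * (x_max - x_min))
        DSS2 = DSS1 / log10(response_max)
        DSS3 = DSS2 * (x_max - x1) / (x_max - x_min)

    following the published DSS definitions.  Returns None for a
    non-convergent fit; 0 when the curve never rises above the threshold.
    """
    if getattr(fit, "converged", True) is False:
        return None
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    config = config or MetricConfig()
    p = _coerce_params(fit)
    x_min, x_max = config.tested_range
    t = config.dss_threshold
    area, x1 = dss_area(p, config)
    if area == 0.0:
        return 0.0
    d1 = 100.0 * area / ((100.0 - t) * (x_max - x_min))
    if variant == 1:
        return d1
    if p.response_max <= 1.0:
        return 0.0  # log10 normalisation undefined for sub-unity maxima
    d2 = d1 / math.log10(p.response_max)
    if variant == 2:
        return d2
    return d2 * (x_max - x1) / (x_max - x_min)


# --------------------------------------------------------------------------- xepto50
def xepto50_numerator(fit, config: MetricConfig | None = None) -> float:
    """Area between min(fitted curve, 100) and the 50 % baseline over the window.

    Computed in midpoint-relative coordinates so the value depends only on
    the curve's shape (asymptotes and slope), never on its position along
    the concentration axis.  The curve is capped at 100 % inhibition so the
    normalised score stays within [0, 1] even for overshooting asymptotes.
    """
    config = config or MetricConfig()
    p = _coerce_params(fit)
    rmin, rmax, h = p.response_min, p.response_max, p.hillslope
    C = config.xepto_window
    base = config.xepto_baseline
    if rmax <= base:
        return 0.0
    u0 = _crossing_shifted(rmin, rmax, h, base)
    if u0 is None:  # rmin >= 50: curve above the baseline everywhere; anchor at midpoint
        u0 = 0.0
    a, b = u0, u0 + C
    u_hi = _crossing_shifted(rmin, rmax, h, 100.0) if rmax > 100.0 else None
    if u_hi is None or u_hi >= b:
        num = _area_shifted(rmin, rmax, h, a, b) - base * C
    else:
        m = max(a, u_hi)
        num = (
            _area_shifted(rmin, rmax, h, a, m)
            - base * (m - a)
            + (100.0 - base) * (b - m)
        )
    return max(num, 0.0)


def xepto50_score(fit, config: MetricConfig | None = None) -> float | None:
    """Position-invariant shape score in [0, 1].

    The area between the fitted curve and the 50 % baseline over a window
    of ``xepto_window`` log10 units starting at the interpolated IC50,
    normalised by the window's total area (100 - 50) * window.  Returns 0
    when the curve never reaches 50 % inhibition, None for a
    non-convergent fit.
    """
    if getattr(fit, "converged", True) is False:
        return None
    config = config or MetricConfig()
    p = _coerce_params(fit)
    if p.response_max <= config.xepto_baseline:
        return 0.0
    num = xepto50_numerator(p, config)
    total = (100.0 - config.xepto_baseline) * config.xepto_window
    return min(num / total, 1.0)


# --------------------------------------------------------------------------- bundle
def compute_metrics(results, config: MetricConfig | None = None) -> MetricBundle:
    """Full metric bundle for a fit-results object (its model supplies the means)."""
    bundle = MetricBundle()
    if not getattr(results, "converged", False):
        bundle.notes.append(f"fit not convergent: {getattr(results, 'reason', '')}")
        return bundle
    model = results.model
    if config is None:
        config = MetricConfig.for_model(model)
    elif config.tested_range is None:
        config = MetricConfig(
            auc_baseline=config.auc_baseline,
            xepto_baseline=config.xepto_baseline,
            xepto_window=config.xepto_window,
            dss_threshold=config.dss_threshold,
            tested_range=(float(model._x.min()), float(model._x.max())),
        )
    p = results.params
    bundle.ic50_traditional = 10.0**p.log10_ic50
    bundle.neg_log10_ic50 = -p.log10_ic50
    bundle.ic50_interpolated = interpolated_ic50(p)
    if bundle.ic50_interpolated is None:
        bundle.notes.append("curve does not cross 50% inhibition")
    bundle.auc = auc((model._x, model._y), config)
    bundle.dss1 = dss(p, config, 1)
    bundle.dss2 = dss(p, config, 2)
    bundle.dss3 = dss(p, config, 3)
    bundle.xepto50 = xepto50_score(p, config)
    return bundle
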