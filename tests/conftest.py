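import numpy as np
import pytest
from scipy.integrate import quad

from doseresp import DEFAULT_CONCENTRATIONS, LogisticParams, evaluate_4pl


@pytest.fixture
def symmetric_params():
    """A full-range symmetric curve with midpoint at 100 nM."""
    return LogisticParams(0.0, 100.0, 1.0, -7.0)


@pytest.fixture
def tested_range():
    """log10 of the default 5 pM .. 10 uM design."""
    x = np.log10(DEFAULT_CONCENTRATIONS)
    return (float(x.min()), float(x.max()))


def quad_area(params, a, b, baseline=0.0, clip_high=None, tol=1e-12):
    """Independent adaptive-quadrature oracle for areas of the 4PL above a baseline.

    When the curve is clipped from above, the clip crossing is a kink and is
    handed to quad as a breakpoint so the requested tolerance is actually met.
    """
    from doseresp.metrics import crossing_log10

    def integrand(x):
        y = evaluate_4pl(params, 10.0**x)
        if clip_high is not None:
            y = min(y, clip_high)
        return max(y - baseline, 0.0)

    pts = None
    if clip_high is not None:
        xc = crossing_log10(params, clip_high)
        if xc is not None and a < xc < b:
            pts = [xc]
    val, _ = quad(integrand, a, b, epsabs=tol, epsrel=tol, limit=500, points=pts)
    return val


def piecewise_auc_oracle(x, y, baseline, tol=1e-13):
    """Quadrature oracle for the clipped piecewise-linear AUC.

    Integrates max(interp(x) - baseline, 0) segment by segment, handing
    quad the in-segment baseline crossing as a breakpoint so the kink is
    fully resolved.
    """
    total = 0.0
    for i in range(len(x) - 1):
        d0, d1 = y[i] - baseline, y[i + 1] - baseline
        pts = None
        if d0 * d1 < 0:
            pts = [x[i] + (x[i + 1] - x[i]) * d0 / (d0 - d1)]
        total += quad(
            lambda t: max(np.interp(t, x, y) - baseline, 0.0),
            x[i],
            x[i + 1],
            epsabs=tol,
            epsrel=tol,
            limit=200,
            points=pts,
        )[0]
    return total


def random_convergent_params(rng, n):
    """Well-behaved random parameter quadruples for oracle comparisons."""
    out = []
    for _ in range(n):
        rmin = rng.uniform(-5.0, 20.0)
        rmax = rng.uniform(rmin + 40.0, 115.0)
        h = rng.uniform(0.3, 5.0)
        x50 = rng.uniform(-10.0, -6.0)
        out.append(LogisticParams(rmin, rmax, h, x50))
    return out
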