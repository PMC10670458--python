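import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from doseresp import (
    DEFAULT_CONCENTRATIONS,
    LogisticParams,
    MetricConfig,
    auc,
    dss,
    evaluate_4pl,
    interpolated_ic50,
    xepto50_score,
)
from doseresp.metrics import dss_area, xepto50_numerator

from conftest import piecewise_auc_oracle, quad_area, random_convergent_params


def config_for(tested_range, **kw):
    return MetricConfig(tested_range=tested_range, **kw)


class TestInterpolatedIC50:
    def test_symmetric_curve_crosses_at_midpoint(self, symmetric_params):
        assert interpolated_ic50(symmetric_params) == pytest.approx(1e-7, rel=1e-12)

    def test_asymmetric_curve_closed_form_matches_bisection(self):
        p = LogisticParams(0.0, 80.0, 1.0, -7.0)
        closed = interpolated_ic50(p)
        assert closed == pytest.approx(10 ** (-7 - np.log10(30 / 50)), rel=1e-12)
        # independent root-finding oracle on the raw curve
        root = brentq(lambda x: evaluate_4pl(p, 10.0**x) - 50.0, -12, -3, xtol=1e-13)
        assert closed == pytest.approx(10.0**root, rel=1e-9)

    def test_undefined_when_curve_never_reaches_50(self):
        assert interpolated_ic50(LogisticParams(0.0, 40.0, 1.0, -7.0)) is None

    def test_undefined_for_non_convergent_fit(self, symmetric_params):
        class Fake:
            converged = False

        assert interpolated_ic50(Fake()) is None


class TestAUC:
    def test_flat_full_inhibition_rectangle(self):
        x = np.linspace(-11.0, -5.0, 10)  # exactly 6 log units
        y = np.full(10, 100.0)
        assert auc((x, y), MetricConfig()) == pytest.approx(540.0, abs=1e-12)

    def test_response_at_baseline_gives_zero(self):
        x = np.linspace(-11.0, -5.0, 10)
        assert auc((x, np.full(10, 10.0)), MetricConfig()) == 0.0

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            auc((np.array([-7.0]), np.array([50.0])), MetricConfig())

    def test_matches_quadrature_on_piecewise_linear_interpolant(self, symmetric_params):
        x = np.log10(DEFAULT_CONCENTRATIONS)
        y = evaluate_4pl(symmetric_params, DEFAULT_CONCENTRATIONS)
        got = auc((x, y), MetricConfig())
        assert got == pytest.approx(piecewise_auc_oracle(x, y, 10.0), abs=1e-9)


class TestDSS:
    def test_curve_below_threshold_scores_zero(self, tested_range):
        p = LogisticParams(0.0, 8.0, 1.0, -7.0)
        cfg = config_for(tested_range)
        assert dss(p, cfg, 1) == 0.0
        assert dss(p, cfg, 2) == 0.0
        assert dss(p, cfg, 3) == 0.0

    def test_step_curve_covers_half_the_range(self, tested_range):
        """A near-step curve at the range midpoint leaves (100-t) x half-range
        above threshold: DSS1 -> 50 in the limit (quadrature-verified)."""
        x_min, x_max = tested_range
        mid = 0.5 * (x_min + x_max)
        p = LogisticParams(0.0, 100.0, 50.0, mid)
        cfg = config_for(tested_range)
        d1 = dss(p, cfg, 1)
        assert d1 == pytest.approx(50.0, abs=0.5)
        area, x1 = dss_area(p, cfg)
        oracle = quad_area(p, x1, x_max, baseline=10.0)
        assert area == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("variant", [1, 2, 3])
    def test_all_variants_match_quadrature_oracle(self, tested_range, variant):
        rng = np.random.default_rng(42)
        cfg = config_for(tested_range)
        x_min, x_max = tested_range
        for p in random_convergent_params(rng, 25):
            got = dss(p, cfg, variant)
            area, x1 = dss_area(p, cfg)
            oracle_area = quad_area(p, x1, x_max, baseline=10.0)
            d1 = 100.0 * oracle_area / ((100.0 - 10.0) * (x_max - x_min))
            expect = {
                1: d1,
                2: d1 / np.log10(p.response_max),
                3: d1 / np.log10(p.response_max) * (x_max - x1) / (x_max - x_min),
            }[variant]
            assert got == pytest.approx(expect, abs=1e-6)

    def test_undefined_for_non_convergent_fit(self, tested_range):
        class Fake:
            converged = False

        assert dss(Fake(), config_for(tested_range), 1) is None


class TestXepto50:
    def test_worked_symmetric_value(self, symmetric_params):
        """Closed-form integral gives (100*(2 + log10(1.01) - log10 2) - 100)/100."""
        got = xepto50_score(symmetric_params, MetricConfig(xepto_window=2.0))
        expect = (100.0 * (2.0 + np.log10(1.01) - np.log10(2.0)) - 100.0) / 100.0
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.70329, abs=1e-4)

    def test_step_curve_fills_the_window(self):
        """As the slope grows the window fills; the deficit is the half of the
        sigmoid transition inside the window, 100*log10(2)/h area units."""
        cfg = MetricConfig()
        for h in (100.0, 1000.0):
            got = xepto50_score(LogisticParams(0.0, 100.0, h, -7.0), cfg)
            deficit = 100.0 * np.log10(2.0) / h / 100.0
            assert got == pytest.approx(1.0 - deficit, abs=1e-9)
        assert xepto50_score(LogisticParams(0.0, 100.0, 1000.0, -7.0), cfg) > 1 - 1e-3

    def test_score_zero_when_curve_never_reaches_50(self):
        assert xepto50_score(LogisticParams(0.0, 40.0, 1.0, -7.0), MetricConfig()) == 0.0

    def test_position_invariance_exact(self):
        """Shifting the midpoint anywhere leaves the score bit-identical."""
        cfg = MetricConfig()
        base = xepto50_score(LogisticParams(0.0, 100.0, 1.0, -7.0), cfg)
        for x50 in [-12.0, -8.0, -6.0, -3.0, 0.0, 4.0]:
            shifted = xepto50_score(LogisticParams(0.0, 100.0, 1.0, x50), cfg)
            assert abs(shifted - base) < 1e-12

    def test_strictly_increasing_in_response_max(self):
        cfg = MetricConfig()
        scores = [
            xepto50_score(LogisticParams(0.0, rmax, 1.0, -7.0), cfg)
            for rmax in np.linspace(55.0, 100.0, 10)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_strictly_increasing_in_hillslope(self):
        cfg = MetricConfig()
        scores = [
            xepto50_score(LogisticParams(0.0, 100.0, h, -7.0), cfg)
            for h in np.linspace(0.3, 5.0, 10)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_numerator_matches_quadrature_oracle(self):
        rng = np.random.default_rng(9)
        cfg = MetricConfig()
        for p in random_convergent_params(rng, 25):
            if p.response_max <= 50.0:
                continue
            num = xepto50_numerator(p, cfg)
            x0 = np.log10(interpolated_ic50(p))
            oracle = quad_area(p, x0, x0 + cfg.xepto_window, baseline=50.0, clip_high=100.0)
            assert num == pytest.approx(oracle, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(
        rmin=st.floats(-10.0, 49.0),
        span=st.floats(1.0, 130.0),
        h=st.floats(0.05, 20.0),
        x50=st.floats(-12.0, 0.0),
    )
    def test_score_always_within_unit_interval(self, rmin, span, h, x50):
        p = LogisticParams(rmin, min(rmin + span, 120.0), h, x50)
        s = xepto50_score(p, MetricConfig())
        assert 0.0 <= s <= 1.0

    def test_lateral_shift_moves_both_ic50s_exactly(self):
        """Potency separation: a one-decade shift moves both IC50s one decade."""
        p1 = LogisticParams(0.0, 80.0, 1.3, -8.0)
        p2 = LogisticParams(0.0, 80.0, 1.3, -7.0)
        assert interpolated_ic50(p2) / interpolated_ic50(p1) == pytest.approx(10.0, rel=1e-9)
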