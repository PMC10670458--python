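import numpy as np
import pytest

from doseresp import (
    DEFAULT_CONCENTRATIONS,
    FourParamLogistic,
    LogisticParams,
    SyntheticSpec,
    evaluate_4pl,
    generate,
    initial_guess,
)


def noiseless_model(params, conc=DEFAULT_CONCENTRATIONS):
    y = evaluate_4pl(params, conc)
    return FourParamLogistic(conc, y)


class TestEvaluate:
    def test_midpoint_is_exactly_half_way(self, symmetric_params):
        assert evaluate_4pl(symmetric_params, 1e-7) == 50.0

    def test_one_decade_above_midpoint(self, symmetric_params):
        # hand evaluation: 100 / (1 + 10**(-1))
        assert evaluate_4pl(symmetric_params, 1e-6) == pytest.approx(100 / 1.1, rel=1e-12)

    def test_degenerate_flat_curve(self):
        p = LogisticParams(20.0, 20.0, 3.0, -7.0)
        for c in [1e-12, 1e-7, 1e-3]:
            assert evaluate_4pl(p, c) == pytest.approx(20.0, abs=1e-12)

    def test_non_positive_concentration_rejected(self, symmetric_params):
        with pytest.raises(ValueError):
            evaluate_4pl(symmetric_params, 0.0)
        with pytest.raises(ValueError):
            evaluate_4pl(symmetric_params, -1e-7)

    def test_monotone_non_decreasing_in_concentration(self):
        rng = np.random.default_rng(7)
        conc = np.geomspace(1e-12, 1e-4, 200)
        for _ in range(20):
            p = LogisticParams(
                rng.uniform(-10, 40),
                rng.uniform(50, 120),
                rng.uniform(0.1, 20.0),
                rng.uniform(-10, -6),
            )
            y = evaluate_4pl(p, conc)
            assert np.all(np.diff(y) >= -1e-12)


class TestInitialGuess:
    def test_guess_matches_definition_on_noiseless_means(self, symmetric_params):
        x = np.log10(DEFAULT_CONCENTRATIONS)
        y = evaluate_4pl(symmetric_params, DEFAULT_CONCENTRATIONS)
        g = initial_guess(x, y)
        assert g.response_min == y.min()
        assert g.response_max == y.max()
        assert g.hillslope == 1.0
        assert g.log10_ic50 == x[np.argmin(np.abs(y - 0.5 * (y.min() + y.max())))]

    def test_tie_breaks_to_lower_concentration(self):
        x = np.array([-9.0, -8.0, -7.0, -6.0])
        y = np.array([0.0, 40.0, 60.0, 100.0])  # 40 and 60 equidistant from 50
        assert initial_guess(x, y).log10_ic50 == -8.0

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(ValueError):
            initial_guess(np.array([-9.0, -8.0, -7.0]), np.array([0.0, 50.0, 100.0]))


class TestFit:
    def test_noiseless_data_recovers_truth(self, symmetric_params):
        res = noiseless_model(symmetric_params).fit()
        assert res.converged
        truth = np.array(symmetric_params.as_tuple())
        est = np.array(res.params.as_tuple())
        assert np.max(np.abs(est - truth)) < 1e-6

    def test_noiseless_fit_reproduces_every_mean(self, symmetric_params):
        model = noiseless_model(symmetric_params)
        res = model.fit()
        assert np.max(np.abs(res.fittedvalues - model.response)) < 1e-6

    def test_flat_response_flagged_not_raised(self):
        model = FourParamLogistic(DEFAULT_CONCENTRATIONS, np.zeros(10))
        res = model.fit()
        assert not res.converged
        assert "flat" in res.reason

    def test_too_few_points_flagged(self):
        model = FourParamLogistic([1e-9, 1e-8, 1e-7], [0.0, 50.0, 100.0])
        res = model.fit()
        assert not res.converged

    def test_refinement_never_worsens_sse(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            gen = generate(SyntheticSpec(noise_sd=4.0, seed=seed, log10_ic50=-8.0))
            res = FourParamLogistic.from_series(gen.series).fit()
            assert res.converged
            assert res.sse <= res.sse_stage1 * (1 + 1e-9) + 1e-9

    def test_scale_equivariance_of_ic50(self, symmetric_params):
        """Relabelling all concentrations x10 (same responses) shifts
        log10_ic50 by exactly +1 and nothing else."""
        y = evaluate_4pl(symmetric_params, DEFAULT_CONCENTRATIONS)
        res1 = FourParamLogistic(DEFAULT_CONCENTRATIONS, y).fit()
        res2 = FourParamLogistic(DEFAULT_CONCENTRATIONS * 10, y).fit()
        assert res2.log10_ic50 - res1.log10_ic50 == pytest.approx(1.0, abs=1e-8)
        for attr in ("response_min", "response_max", "hillslope"):
            assert getattr(res2, attr) == pytest.approx(getattr(res1, attr), abs=1e-8)

    def test_monte_carlo_ic50_recovery(self):
        """Noisy replicates (sigma = 2%) still locate the midpoint closely."""
        errs = []
        for seed in range(30):
            gen = generate(SyntheticSpec(log10_ic50=-7.0, noise_sd=2.0, seed=seed))
            res = FourParamLogistic.from_series(gen.series).fit()
            assert res.converged
            errs.append(abs(res.log10_ic50 - (-7.0)))
        assert np.mean(errs) < 0.1

    def test_stderr_reported_for_noisy_fits(self):
        gen = generate(SyntheticSpec(noise_sd=2.0, seed=3))
        res = FourParamLogistic.from_series(gen.series).fit()
        assert res.bse["log10_ic50"] > 0

    def test_summary_mentions_parameters(self):
        res = noiseless_model(LogisticParams(0, 100, 1, -7)).fit()
        text = res.summary()
        for token in ("response_min", "hillslope", "log10_ic50", "IC50"):
            assert token in text


class TestResultsSimulate:
    def test_simulate_round_trip_recovers_fit(self):
        res = noiseless_model(LogisticParams(5, 95, 1.2, -7.5)).fit()
        series = res.simulate(noise_sd=0.0, seed=1)
        res2 = FourParamLogistic.from_series(series).fit()
        assert res2.log10_ic50 == pytest.approx(res.log10_ic50, abs=1e-6)
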