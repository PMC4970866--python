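import numpy as np
import pandas as pd
import pytest

from nigramode import data_model, regression, synthetic
from nigramode.regression import (
    encode_predictors,
    extended_fit,
    fit_rate_regression,
    population_fraction,
    sliding_window_fit,
    value_predictor,
    window_offsets,
)

from conftest import make_trials


class TestEncodePredictors:
    def test_choice_and_type_codings(self):
        trials = make_trials(
            ["IS", "IS", "SG"], ["left", "right", "none"],
            left_odor_pct=[50.0, 50.0, 80.0],
        )
        d = encode_predictors(trials, hemisphere="left")
        # second trial: prev = ipsi (left), curr = contra (right), IS
        assert (d.loc[1, ["x_prev", "x_curr", "x_type"]].tolist() == [-1.0, 1.0, -1.0])
        assert d.loc[0, "x_prev"] == 0.0  # first trial has no previous choice
        assert d.loc[2, "x_curr"] == 0.0  # no choice
        assert d.loc[2, "x_type"] == 1.0  # SG

    def test_hemisphere_flips_ipsi_contra(self):
        trials = make_trials(["SG"], ["left"])
        assert encode_predictors(trials, "left").loc[0, "x_curr"] == -1.0
        assert encode_predictors(trials, "right").loc[0, "x_curr"] == 1.0

    def test_rt_minmax_endpoints(self):
        trials = make_trials(["SG"] * 3, ["left"] * 3, rt_s=[0.3, 0.5, 0.4])
        d = encode_predictors(trials)
        assert d["x_rt"].tolist() == [0.0, 1.0, pytest.approx(0.5)]

    def test_missing_rt_gets_median_and_flag(self):
        trials = make_trials(["SG"] * 4, ["left", "left", "left", "none"],
                             rt_s=[0.3, 0.5, 0.4, 0.4])
        d = encode_predictors(trials)
        assert d.loc[3, "rt_imputed"]
        assert d.loc[3, "x_rt"] == pytest.approx(0.5)  # median of {0, 1, 0.5}


class TestFitRateRegression:
    def _design(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x_prev": rng.choice([-1.0, 0.0, 1.0], n),
                "x_curr": rng.choice([-1.0, 1.0], n),
                "x_type": rng.choice([-1.0, 1.0], n),
                "x_rt": rng.uniform(0, 1, n),
            }
        )

    def test_exact_interpolation_without_noise(self):
        d = self._design(100)
        rates = 10 + 2 * d["x_curr"].to_numpy()
        fit = fit_rate_regression(rates, d)
        assert fit.beta("const") == pytest.approx(10.0, abs=1e-10)
        assert fit.beta("x_curr") == pytest.approx(2.0, abs=1e-10)
        for name in ("x_prev", "x_type", "x_rt"):
            assert fit.beta(name) == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = self._design(60, seed=rng.integers(1 << 30))
            rates = rng.normal(10, 2, 60)
            fit = fit_rate_regression(rates, d)
            X = np.column_stack([np.ones(60), d.to_numpy()])
            beta = np.linalg.solve(X.T @ X, X.T @ rates)
            np.testing.assert_allclose(
                [fit.beta(n) for n in fit.names], beta, atol=1e-8
            )

    def test_intercept_is_mean_rate_with_centered_predictors(self):
        # the intercept equals the mean rate when every predictor averages zero
        rng = np.random.default_rng(2)
        n = 200
        d = self._design(n, seed=7)
        d = d - d.mean(axis=0)
        rates = rng.normal(15, 3, n)
        fit = fit_rate_regression(rates, d)
        assert fit.beta("const") == pytest.approx(rates.mean(), abs=1e-8)

    def test_zero_variance_predictor_raises_naming_column(self):
        d = self._design(50)
        d["x_type"] = 1.0  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="x_type"):
            fit_rate_regression(np.random.default_rng(0).normal(10, 1, 50), d)

    def test_too_few_trials_raises(self):
        d = self._design(12)
        with pytest.raises(ValueError, match="trials"):
            fit_rate_regression(np.ones(12), d)

    def test_ci_contains_point_estimate(self):
        d = self._design(80)
        rates = np.random.default_rng(3).normal(12, 2, 80)
        fit = fit_rate_regression(rates, d)
        for name in fit.names:
            lo, hi = fit.ci(name)
            assert lo <= fit.beta(name) <= hi


class TestSlidingWindow:
    def test_window_count_arithmetic(self):
        assert len(window_offsets((-0.5, 0.5), 0.1, 0.01)) == 91

    def test_constant_neuron_null_significance_rate(self, session_trials, included_trials):
        neuron = synthetic.simulate_spikes(
            session_trials, synthetic.NeuronParams(baseline_rate=15.0), seed=21
        )
        fits = sliding_window_fit(neuron, included_trials, "odor_exit")
        assert len(fits) == 91
        frac = np.mean(
            [[f.p(n) < 0.05 for n in ("x_prev", "x_curr", "x_type", "x_rt")] for f in fits]
        )
        assert frac < 0.15  # overlapping windows correlate, but stay near alpha

    def test_static_fit_equals_single_window_covering_delay(self):
        # fixed-duration delay epochs: one window == the whole delay epoch
        trials = make_trials(
            ["SG"] * 30 + ["IS"] * 30,
            ["left", "right"] * 30,
            rt_s=list(np.linspace(0.3, 0.6, 60)),
        )
        neuron = synthetic.simulate_spikes(
            trials, synthetic.NeuronParams(baseline_rate=20.0, b_curr=3.0), seed=5
        )
        delay_len = 0.55  # valve -> exit in make_trials
        static = fit_rate_regression(
            data_model.epoch_rates(neuron, trials, "delay"),
            encode_predictors(trials),
        )
        (windowed,) = sliding_window_fit(
            neuron, trials, "valve_open",
            window=delay_len, step=1.0, span=(0.0, delay_len),
        )
        pd.testing.assert_frame_equal(static.table, windowed.table)

    def test_delay_limited_modulation_profile(self, session_trials, included_trials):
        # average the profile over a few neurons: single-window estimates have
        # SE ~1 sp/s and overlapping windows share spikes
        params = synthetic.NeuronParams(baseline_rate=20.0, b_type=4.0)
        profiles = []
        for seed in (22, 23, 24):
            neuron = synthetic.simulate_spikes(session_trials, params, seed=seed)
            fits = sliding_window_fit(neuron, included_trials, "odor_exit")
            profiles.append([f.beta("x_type") for f in fits])
        centers = np.array([f.window[1] for f in fits])
        b_type = np.mean(profiles, axis=0)  # truth: +4 during the delay epoch
        in_delay = (centers > -0.35) & (centers < -0.1)
        after_move = centers > 0.2
        assert b_type[in_delay].mean() > 2.5
        assert abs(b_type[after_move].mean()) < 1.0
        assert b_type[in_delay].mean() > b_type[after_move].mean() + 2.0

    def test_population_fraction_grid_mismatch_raises(self, session_trials, included_trials):
        neuron = synthetic.simulate_spikes(
            session_trials, synthetic.NeuronParams(baseline_rate=10.0), seed=23
        )
        a = sliding_window_fit(neuron, included_trials, "odor_exit", span=(-0.2, 0.2))
        b = sliding_window_fit(neuron, included_trials, "odor_exit", span=(-0.3, 0.2))
        with pytest.raises(ValueError, match="grid"):
            population_fraction([a, b])

    def test_single_neuron_fraction_is_binary(self, session_trials, included_trials):
        neuron = synthetic.simulate_spikes(
            session_trials, synthetic.NeuronParams(baseline_rate=10.0), seed=24
        )
        fits = sliding_window_fit(neuron, included_trials, "odor_exit", span=(-0.2, 0.0))
        frac = population_fraction([fits])
        assert set(np.unique(frac[["x_prev", "x_curr", "x_type", "x_rt"]])) <= {0.0, 1.0}


class TestExtendedFit:
    def test_constant_value_is_collinear(self, included_trials, session_design):
        rates = np.random.default_rng(4).normal(10, 1, len(included_trials))
        with pytest.raises(ValueError, match="x_value"):
            extended_fit(rates, session_design, np.full(len(included_trials), 0.7))

    def test_value_driven_rates_load_on_value_term(self, included_trials, session_design):
        rng = np.random.default_rng(5)
        values = value_predictor(included_trials)
        rates = 10 + 6 * values + rng.normal(0, 1, len(included_trials))
        fit = extended_fit(rates, session_design, values)
        assert fit.p("x_value") < 0.01
        assert fit.beta("x_value") > 2

    def test_value_free_generator_keeps_base_coefficients(self, session_trials, included_trials, session_design):
        params = synthetic.NeuronParams(baseline_rate=20.0, b_curr=4.0, b_type=2.0)
        neuron = synthetic.simulate_spikes(session_trials, params, seed=25)
        rates = data_model.epoch_rates(neuron, included_trials, "delay")
        base = fit_rate_regression(rates, session_design)
        ext = extended_fit(rates, session_design, value_predictor(included_trials))
        for name in ("x_prev", "x_curr", "x_type", "x_rt"):
            lo, hi = ext.ci(name)
            assert lo - 0.5 <= base.beta(name) <= hi + 0.5

    def test_value_predictor_ranges(self, included_trials):
        values = value_predictor(included_trials)
        assert np.nanmin(values) >= 0 and np.nanmax(values) <= 1
        is_mask = (included_trials["block_type"] == "IS").to_numpy()
        assert not np.isnan(values[is_mask]).any()
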