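import numpy as np
import pytest

from nigramode import data_model, modulation, synthetic
from nigramode.modulation import (
    TrialTypeResult,
    correct_mask,
    cross_classification,
    difficulty_dependence,
    direction_difference_by_type,
    population_counts,
    population_direction_difference,
    trial_type_dependence,
)
from nigramode.selectivity import PreferenceResult, direction_preference

from conftest import make_trials


def _pref(preference=0.5, p=0.001):
    return PreferenceResult(roc_area=0.5 + preference / 2, preference=preference,
                            p_value=p, n_perm=500)


class TestPopulationCounts:
    def _results(self, n_is, n_sg, direction="preferred"):
        out = []
        for _ in range(n_is):
            out.append(TrialTypeResult("x", direction, 5.0, 9.0, 0.01))
        for _ in range(n_sg):
            out.append(TrialTypeResult("x", direction, 9.0, 5.0, 0.01))
        return out

    def test_reproduces_printed_probability_84_17(self):
        res = population_counts(self._results(84, 17))["preferred"]
        assert res["n_higher_IS"] == 84 and res["n_higher_SG"] == 17
        assert res["p"] == pytest.approx(2.6e-11, abs=0.05e-11)

    def test_reproduces_printed_probability_76_33(self):
        res = population_counts(self._results(33, 76))["preferred"]
        assert res["n_higher_SG"] == 76
        assert res["p"] == pytest.approx(3.8e-5, abs=0.05e-5)

    def test_even_split_gives_chi2_zero(self):
        res = population_counts(self._results(50, 50))["preferred"]
        assert res["chi2"] == 0 and res["p"] == pytest.approx(1.0)

    def test_zero_significant_flagged_undefined(self):
        ns = [TrialTypeResult("x", "preferred", 5.0, 5.1, 0.7)]
        res = population_counts(ns)["preferred"]
        assert res["undefined"] and np.isnan(res["p"])


class TestCorrectMask:
    def test_balanced_sg_choices_count_as_correct(self):
        trials = make_trials(
            ["SG"] * 3, ["left", "right", "none"],
            correct=[False, False, False],
            left_odor_pct=[50.0, 50.0, 50.0],
        )
        assert correct_mask(trials).tolist() == [True, True, False]

    def test_unbalanced_sg_keeps_recorded_correctness(self):
        trials = make_trials(["SG"] * 2, ["left", "right"], correct=[True, False])
        assert correct_mask(trials).tolist() == [True, False]


class TestTrialTypeDependence:
    def _neuron_session(self, b_curr_type, seed=0):
        trials = synthetic.simulate_behavior(seed=seed)
        inc = data_model.filter_trials(trials)
        params = synthetic.NeuronParams(
            baseline_rate=20.0, b_curr=4.0, b_curr_type=b_curr_type
        )
        neuron = synthetic.simulate_spikes(trials, params, seed=seed + 100)
        return neuron, inc

    def test_interaction_neuron_classified_higher_is_in_preferred(self):
        neuron, inc = self._neuron_session(b_curr_type=-2.0)
        pref = direction_preference(neuron, inc, seed=0)
        res = trial_type_dependence(neuron, inc, pref, "preferred")
        assert res.klass == "higher_IS"
        res_anti = trial_type_dependence(neuron, inc, pref, "antipreferred")
        assert res_anti.klass == "higher_SG"

    def test_null_neuron_rarely_significant(self):
        n_sig = 0
        for seed in range(20):
            neuron, inc = self._neuron_session(b_curr_type=0.0, seed=seed)
            pref = _pref(0.5)
            res = trial_type_dependence(neuron, inc, pref, "preferred")
            n_sig += res.klass != "ns"
        assert n_sig <= 4

    def test_insufficient_trials_flagged_ns(self):
        trials = make_trials(["SG"] * 4 + ["IS"], ["right"] * 5)
        neuron = data_model.SpikeTrain("n", "left", np.linspace(0, 30, 100))
        res = trial_type_dependence(neuron, trials, _pref(0.5))
        assert res.insufficient and res.klass == "ns"

    def test_zero_variance_equal_means_is_ns(self):
        trials = make_trials(["SG"] * 4 + ["IS"] * 4, ["right"] * 8)
        # perfectly regular spiking: identical rate in every delay epoch
        spikes = np.concatenate(
            [np.arange(s, e, 0.01) for s, e in zip(trials["t_valve_open"],
                                                   trials["t_odor_port_exit"])]
        )
        neuron = data_model.SpikeTrain("n", "left", np.sort(spikes))
        res = trial_type_dependence(neuron, trials, _pref(0.5))
        assert res.klass == "ns"


class TestDirectionDifference:
    def test_interaction_increases_is_difference(self):
        trials = synthetic.simulate_behavior(seed=2)
        inc = data_model.filter_trials(trials)
        params = synthetic.NeuronParams(baseline_rate=20.0, b_curr=4.0, b_curr_type=-2.0)
        neuron = synthetic.simulate_spikes(trials, params, seed=3)
        pref = direction_preference(neuron, inc, seed=0)
        d_sg, d_is = direction_difference_by_type(neuron, inc, pref)
        assert d_is > d_sg

    def test_swapping_type_labels_swaps_differences(self):
        trials = synthetic.simulate_behavior(seed=2)
        # correct trials only, so the trial sets are identical before/after swap
        inc = data_model.filter_trials(trials)
        inc = inc[inc["correct"]].copy()
        params = synthetic.NeuronParams(baseline_rate=20.0, b_curr=4.0, b_curr_type=-2.0)
        neuron = synthetic.simulate_spikes(trials, params, seed=3)
        pref = direction_preference(neuron, inc, seed=0)
        d_sg, d_is = direction_difference_by_type(neuron, inc, pref)
        swapped = inc.assign(
            block_type=inc["block_type"].map({"SG": "IS", "IS": "SG"}),
            left_odor_pct=50.0,
        )
        s_sg, s_is = direction_difference_by_type(neuron, swapped, pref)
        assert s_sg == pytest.approx(d_is) and s_is == pytest.approx(d_sg)

    def test_population_paired_test_splits_by_sign(self):
        deltas = [(2.0, 4.0)] * 10 + [(3.0, 5.5)] * 8
        signs = [1] * 10 + [-1] * 8
        res = population_direction_difference(deltas, signs)
        assert res["contraversive"]["n"] == 10
        assert res["ipsiversive"]["mean_delta_IS"] == pytest.approx(5.5)
        assert res["contraversive"]["p"] < 0.05  # constant positive paired diff


class TestDifficultyDependence:
    def _sg_session(self, mixture_gain, seed=0, n_per_mix=50):
        rng = np.random.default_rng(seed)
        mixes = [95.0, 80.0, 60.0, 40.0, 20.0, 5.0] * n_per_mix
        trials = make_trials(["SG"] * len(mixes), ["right"] * len(mixes),
                             left_odor_pct=mixes)
        spikes = []
        for _, tr in trials.iterrows():
            lam = 10 + mixture_gain * tr["left_odor_pct"] / 100
            dur = tr["t_odor_port_exit"] - tr["t_valve_open"]
            n = rng.poisson(lam * dur)
            spikes.append(rng.uniform(tr["t_valve_open"], tr["t_odor_port_exit"], n))
        neuron = data_model.SpikeTrain(
            "n", "left", np.sort(np.concatenate(spikes))
        )
        return neuron, trials

    def test_mixture_coupled_rate_detected(self):
        neuron, trials = self._sg_session(mixture_gain=8.0)
        res = difficulty_dependence(neuron, trials, "contraversive", Fc=10.0)
        assert res.significant

    def test_null_rate_rarely_significant(self):
        ps = []
        for seed in range(20):
            neuron, trials = self._sg_session(mixture_gain=0.0, seed=seed)
            ps.append(difficulty_dependence(neuron, trials, "contraversive", Fc=10.0).anova_p)
        assert sum(p < 0.05 for p in ps) <= 4

    def test_single_group_raises(self):
        trials = make_trials(["SG"] * 10, ["right"] * 10, left_odor_pct=[80.0] * 10)
        neuron = data_model.SpikeTrain("n", "left", np.linspace(0, 40, 200))
        with pytest.raises(ValueError):
            difficulty_dependence(neuron, trials, "contraversive", Fc=5.0)

    def test_easy_difficult_normalized_means(self):
        neuron, trials = self._sg_session(mixture_gain=0.0, seed=1)
        res = difficulty_dependence(neuron, trials, "contraversive", Fc=10.0)
        assert res.mean_norm_easy == pytest.approx(1.0, rel=0.1)
        assert res.mean_norm_difficult == pytest.approx(1.0, rel=0.1)


class TestCrossClassification:
    def test_counts_and_independence(self):
        rng = np.random.default_rng(0)
        a = rng.random(200) < 0.2
        b = rng.random(200) < 0.5
        res = cross_classification(list(a), list(b))
        assert res["n_both"] + res["n_difficulty_only"] == a.sum()
        assert res["p"] > 0.001  # independent labels: no strong association
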