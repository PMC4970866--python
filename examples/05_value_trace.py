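"""Reward-history value traces and rate-value correlations.

Each direction's value follows V <- V + alpha*(R - V) on trials where it was
chosen.  Within IS blocks, a neuron whose rate carries choice-history
signals correlates with the value of the chosen side: positively for its
preferred direction, negatively for the antipreferred one.
"""

import numpy as np

from nigramode import data_model, selectivity, synthetic, value_model

trials = synthetic.simulate_behavior(seed=7)
included = data_model.filter_trials(trials)

trace = value_model.value_trace(included, alpha=0.1)
is2 = included[included["block_index"] == 4]
side = is2["rewarded_side"].iloc[0]
v = trace.side_value(side)[included["block_index"].to_numpy() == 4]
print(f"2nd IS block rewards {side}: V starts {v[0]:.2f}, ends {v[-1]:.2f}")
print("(the trace re-learns the side after the unsignaled switch)")

params = synthetic.NeuronParams(baseline_rate=20.0, b_curr=4.0, b_prev=2.0)
neuron = synthetic.simulate_spikes(trials, params, seed=11)
rates = data_model.epoch_rates(neuron, included, "delay")
sign = data_model.choice_sign(included)
vals = trace.chosen_value(included)
is_mask = (included["block_type"] == "IS").to_numpy()
pref = selectivity.direction_preference(neuron, included, seed=0)
ps = 1 if pref.preference > 0 else -1
for label, s in (("preferred", ps), ("antipreferred", -ps)):
    m = is_mask & (sign == s) & ~np.isnan(rates)
    r, p = value_model.rate_value_correlation(rates[m], vals[m])
    print(f"rate-value correlation, {label} direction: r = {r:+.2f}, p = {p:.3f}")
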