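"""Simulate one behavioral session and summarize its structure.

The agent plays five alternating blocks (stimulus-guided first).  SG choices
come from a logistic psychometric function of the odor mixture; IS choices
from a softmax over reward-history values, so the rewarded side must be
rediscovered after every unsignaled block switch.
"""

from nigramode import synthetic
from nigramode.behavior import block_performance

trials = synthetic.simulate_behavior(seed=1)

print(f"trials: {len(trials)}")
print("block sequence:", " ".join(trials.groupby("block_index")["block_type"].first()))
print("correct per block:", trials.groupby("block_index")["correct"].sum().tolist())

for perf in block_performance(trials):
    print(
        f"IS block {perf.block_index}: {perf.percent_correct:.1f}% correct, "
        f"{perf.n_error_events} error events over {perf.n_choice_trials} choices"
    )
print("(an error event is a maximal run of consecutive incorrect choices;")
print(" the runs right after each switch show the agent re-learning the side)")
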