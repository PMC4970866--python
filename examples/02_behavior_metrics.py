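"""Behavioral metrics: psychometric curve and reaction-time contrast.

Fits p(right) = 1/(1 + exp(-a - b*x)) to single-trial SG choices (x = left-
odor proportion) and compares reaction times between internally-specified
trials and easy stimulus-guided trials, per movement direction.
"""

from nigramode import behavior, data_model, synthetic

sessions = [synthetic.simulate_behavior(seed=s) for s in range(6)]
sg = sessions[0][
    (sessions[0]["block_type"] == "SG") & (sessions[0]["chosen_side"] != "none")
]

fit = behavior.fit_psychometric(sg)
print(f"psychometric fit: a = {fit.a:.2f}, b = {fit.b:.2f} (generator truth 4.4, -8.8)")
print("negative b: the more left odor in the mixture, the fewer right choices")

rt = behavior.reaction_time_contrast(sessions)
for side, res in rt.items():
    print(
        f"{side}ward: mean RT easy-SG {res['mean_rt_sg_easy']*1000:.0f} ms vs "
        f"IS {res['mean_rt_is']*1000:.0f} ms, paired t p = {res['paired_p']:.2e}"
    )
print("IS trials are faster: the movement can be prepared before the stimulus")

agg = behavior.aggregate_left_fraction(sessions)
print(f"smoothed left-choice fraction: {len(agg)} (block, position) points "
      f"present in >=60% of sessions")
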