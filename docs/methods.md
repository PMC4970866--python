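# Methods

This note documents the models implemented in `nigramode`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions the analyses rely on.

## Task and data model

A session is a table of trials (one row each) plus per-neuron sorted spike
times, all in seconds from session start. Sessions contain five blocks that
alternate stimulus-guided (SG), internally-specified (IS), starting and
ending with SG; a block advances after 50 correct choices. SG trials draw
one of seven binary odor mixtures (95/80/60/50/40/20/5 % left odor); the
dominant component indicates the rewarded side, and on the balanced mixture
each port independently holds reward with probability 0.5. IS trials always
present the balanced mixture and reward one side for the whole block; the
side switches between consecutive IS blocks without any cue.

Trial epochs are half-open intervals `[start, end)` between events —
pre-stimulus (odor port entry → valve open), delay (valve open → odor port
exit), movement (odor port exit → reward port entry) and control (entry →
reward port exit, i.e. the whole trial). Half-open intervals guarantee a
spike on a shared boundary is counted exactly once. The control window
stands in for a baseline because the task has no task-free epoch.

Exclusions: trials with movement time strictly greater than 1.5 s are
removed from all analyses; neurons with fewer than 100 trials of either
block type, or a mean control-window rate below 2.5 sp/s in SG trials, IS
trials, or across the session, are excluded (the first failing rule is
reported). "Session-wide rate" is read as the mean control-window rate over
trials, since the control window tiles the trials.

## Synthetic sessions

The generator exists so that every analysis stage can be validated by
parameter recovery; its defaults are the study conditions.

**Agent.** SG choices follow `p(right) = 1/(1+exp(−a−bx))` with
`(a, b) = (4.4, −8.8)` and `x` the left-odor proportion — ~98% accuracy on
the easiest mixtures, chance at the balanced one. IS choices are a softmax
(inverse temperature 5) over per-direction value traces updated by the same
delta rule the analysis uses (α = 0.1), with a 2% lapse rate. Because
values are updated on every trial, the agent must rediscover the rewarded
side after each unsignaled switch, producing post-switch error runs and
~85–90% correct IS blocks. A session is ~300–330 trials.

**Timing.** Odor valve opens 0.2 s after port entry — long enough that the
pre-stimulus epoch can carry measurable preparatory activity, which is
itself an analysis target; a 200 ms olfactometer delay is realistic. The go
cue follows the valve after a truncated-normal delay (mean 488 ms, SD
104 ms, > 0). Reaction times (go → reward port entry) are lognormal with
means 550 ms (SG) and 450 ms (IS) per side, so IS trials are faster than
easy SG trials by construction — the signature of a movement prepared
before the stimulus. Odor-port exit trails the go cue by an exponential
latency (mean 50 ms); the reward port is occupied for 1 s. With probability
0.05 the agent exits the odor port prematurely (before the go cue), which
withholds reward even when the chosen side was correct; half of those
trials end with no choice at all.

**Spikes.** Spike trains are piecewise-homogeneous Poisson. Within each
epoch of each trial the rate is
`max(baseline + b_prev·x_prev + b_curr·x_curr + b_type·x_type + b_rt·x_rt
+ b_ct·x_curr·x_type, floor)` using exactly the predictor codings the
regression module produces for that session, restricted to a configurable
set of modulated epochs (default: delay only); inter-trial gaps run at
baseline. Because generation and analysis share the linear rate model, OLS
on the generated rates is unbiased for the `b` coefficients (verified
empirically: mean estimates match truth to within Monte-Carlo error). The
interaction term `b_ct` is what the population analyses are sensitive to: a
contraversive-preferring neuron with `b_ct < 0` shows a larger direction
signal in IS than SG trials, higher preferred-direction rates in IS, higher
antipreferred rates in SG, and — through the aligned previous-choice term —
positive rate–value correlations in its preferred direction and negative in
the antipreferred.

**What the generator does not emulate.** No within-session learning or
satiation drifts, no inter-neuron correlations, no bursting or
refractoriness (rates are conditionally Poisson), no difficulty coupling of
firing rates unless explicitly configured, and no session-to-session
variation in psychometric parameters. Passing recovery tests therefore
shows that the estimators are correct for linear-Poisson neurons in a
stationary task, not that real recordings satisfy those assumptions.

## Analyses

**Direction preference.** The ROC area is the Mann–Whitney probability
that a contraversive-trial rate exceeds an ipsiversive-trial rate, ties
counted ½ (computed from pooled ranks, so tie handling is exact);
preference is 2·(area − ½), positive = contraversive. Hemisphere fixes the
mapping (left hemisphere: ipsiversive = leftward). Significance comes from
re-assigning rates to the two groups at original sizes, 500 times. The
test is two-sided on |preference| — both preference signs are scientific
findings — with an add-one correction, `p = (1 + #{|perm| ≥ |obs|})/501`,
so p is never exactly zero and the realized type-I rate at α = 0.05 is
≈ 0.049 (measured 0.035–0.065 over 1,000 null neurons). Under label
permutation the pooled ranks are fixed, so each shuffle only re-draws which
ranks fall in one group; this makes the permutation loop rank-free and
fast without changing the statistic.

**Normalized response.** NR = F_t/F_c over trials in the preferred
direction (all choice trials for nonselective neurons); NR > 1 increasing,
NR < 1 decreasing, exactly 1 "no change". Exact equality is measure-zero
for real data; an optional paired-test criterion could be exposed instead,
but the literal ratio rule is the default because it is the stated
definition.

**Trial-type modulation.** Per-neuron comparisons use the classic
equal-variance unpaired *t*-test (Welch available by flag); population
splits use the χ² goodness-of-fit against an even split with one degree of
freedom and no continuity correction — this reproduces the closed-form
p-values for known count splits (84/17 → 2.6×10⁻¹¹; 76/33 → 3.8×10⁻⁵) to
the printed precision. On balanced SG trials every choice counts as correct
for these analyses (there is no wrong answer when both ports may be armed).
No multiple-testing correction is applied anywhere; classifications use raw
p < 0.05 and reports state this.

**Value.** `V ← V + α(R − V)` per direction, updated only on trials where
that direction was chosen, with R = 0 for unrewarded trials including
correct-but-premature ones. V₀ = 0.5 at session start (configurable). On a
constant-reward run the trace follows `V_k = 1 − (1 − V₀)(1 − α)^k`
exactly, which the tests assert. The trace at trial *t* is the value
*going into* the trial — the quantity concurrent firing could reflect.
Rate–value correlations pool both IS blocks (per-block correlation is a
caller-side restriction). Because the trace runs over SG blocks too, it
enters IS blocks near the session's experienced reward rate rather than
exactly 0.5.

**Regression.** OLS with homoskedastic t-based inference (the standard
linear-model fit); predictors coded −1/0/+1 for previous/current choice
(0 = no choice), −1 IS / +1 SG for trial type, and reaction time min–max
normalized within the session's included trials. Trials without a defined
reaction time receive the session-median normalized value and are flagged.
Sliding-window fits use spike count / 0.1 s in 100 ms windows stepped
10 ms over ±0.5 s around the alignment event (91 windows; span
configurable — the plotted range is a presentation choice); no smoothing
is applied to window rates. Rank-deficient designs raise an error naming
the collinear columns. The extended model adds a value regressor — the
reward-history value of the block's rewarded side in IS trials, the
block's realized accuracy at that trial's mixture ratio in SG trials — and
its interaction with trial type.

Calibration: with Poisson spiking the OLS error is heteroskedastic
(variance ∝ rate/duration), so the 95% CIs are only asymptotically exact.
Measured over 2,000 replicates of a 300-trial session with
choice-complete trials, per-coefficient coverage is 0.945–0.951 with
SE/SD ratios 0.98–1.00, i.e. nominal. Trials with truncated delay epochs
(premature exits) inflate the pooled residual variance and push coverage
conservative (~0.96–0.97); the coverage simulation therefore uses
choice-complete sessions to isolate the estimator's calibration.

**PSTH.** Event-aligned rates are binned at 2 ms, Gaussian-smoothed
(σ = 15 ms default) per trial and averaged with SEM bands; as σ → 0 the
curve reduces to the binned histogram.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: single ~300-trial sessions, populations of 20–50 neurons,
1,000 null neurons for test calibration, 1,000 replicates for CI coverage,
and 10,000 trials for timing calibration. These sizes put Monte-Carlo
noise well inside each assertion's tolerance while keeping the whole suite
around a minute.

## Known limitations

- The linear rate model with a floor is not a point-process model; latency
  structure, adaptation and bursting are out of scope.
- The "no change" (NR = 1) class is effectively empty under the literal
  ratio rule on continuous data.
- Percent correct uses choice trials as the denominator; sessions with many
  no-choice trials will look better than their completion rate.
- The IS-agent's exploration parameters are calibrated to qualitative
  block-performance patterns, not fitted to any animal's data.
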