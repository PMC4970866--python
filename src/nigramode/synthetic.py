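"""Synthetic sessions with known ground truth for parameter recovery.

The behavioral generator plays the two-alternative odor-choice task the way
a trained mouse does: five alternating blocks (stimulus-guided first), each
advancing after 50 correct choices.  In SG blocks one of seven binary odor
mixtures is drawn and the agent answers from a logistic psychometric
function of the left-odor proportion; in IS blocks the balanced mixture is
always presented and the agent chooses by a softmax over per-direction
reward-history values updated with the same delta rule the analysis uses,
so it must rediscover the rewarded side after each unsignaled switch —
producing the characteristic post-switch error runs.  Event timestamps
follow the task's trial clock: odor valve ~50 ms after port entry, a go
cue after a truncated-normal delay (488 ± 104 ms), and lognormal reaction
times that are shorter in IS than in easy SG trials.

Spike trains are piecewise-homogeneous Poisson: within each epoch of each
trial the rate is a linear function of the same coded predictors the
regression analysis estimates (previous choice, current choice, trial type,
reaction time, optionally a current-choice × trial-type interaction),
floored at a small positive rate; between trials the neuron fires at
baseline.  Because generation and analysis share the linear rate model,
every analysis stage can be checked by recovering the parameters it was
generated from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import regression
from .data_model import (
    IS,
    SG,
    SpikeTrain,
    TrialRecord,
    filter_trials,
    trials_to_frame,
)
from .value_model import update_value

__all__ = ["GeneratorConfig", "NeuronParams", "simulate_behavior", "simulate_spikes", "simulate_session"]


@dataclass
class GeneratorConfig:
    """Defaults emulate one recording session of the task.

    ``psychometric_a/b`` parameterize the SG agent's p(right) =
    1 / (1 + exp(-a - b*x)) with x the left-odor proportion on [0, 1];
    the defaults give ~98% accuracy on the easiest mixtures and chance at
    the balanced one.  The IS agent is a softmax (inverse temperature
    ``agent_beta_softmax``) over the delta-rule value traces with learning
    rate ``agent_alpha``; ``lapse`` is the probability of an entirely
    random choice on any trial.  Go-cue delay is truncated normal
    (``delay_mean_s`` = 0.488, ``delay_sd_s`` = 0.104, > 0).  ``rt_means``
    are lognormal reaction-time means keyed by (block type, side), IS
    faster than SG by construction.
    """

    n_blocks: int = 5
    correct_per_block: int = 50
    sg_mixtures: tuple[int, ...] = (95, 80, 60, 50, 40, 20, 5)
    psychometric_a: float = 4.4
    psychometric_b: float = -8.8
    agent_alpha: float = 0.1
    agent_beta_softmax: float = 5.0
    lapse: float = 0.02
    premature_prob: float = 0.05
    no_choice_given_premature: float = 0.5
    is_first_rewarded_side: str = "left"
    delay_mean_s: float = 0.488
    delay_sd_s: float = 0.104
    rt_means: dict = field(
        default_factory=lambda: {
            (SG, "left"): 0.55,
            (SG, "right"): 0.55,
            (IS, "left"): 0.45,
            (IS, "right"): 0.45,
        }
    )
    rt_log_sd: float = 0.15
    valve_latency_s: float = 0.2
    exit_latency_mean_s: float = 0.05
    reward_hold_s: float = 1.0
    iti_min_s: float = 1.0
    iti_mean_s: float = 2.0
    max_trials_per_block: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks % 2 == 0:
            raise ValueError("n_blocks must be odd (sessions start and end with SG)")
        for name in ("lapse", "premature_prob", "no_choice_given_premature"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.agent_alpha <= 1:
            raise ValueError("agent_alpha must be in (0, 1]")


@dataclass
class NeuronParams:
    """Ground-truth rate model of one simulated neuron.

    Realized rate in a modulated epoch is
    ``max(baseline + b_prev*x_prev + b_curr*x_curr + b_type*x_type +
    b_rt*x_rt + b_curr_type*x_curr*x_type, rate_floor)`` with the same
    predictor codings the regression module uses; un-modulated epochs and
    inter-trial gaps run at baseline.  ``b_curr_type`` < 0 makes the
    direction signal stronger in IS than SG trials (the interaction the
    population analyses look for).
    """

    baseline_rate: float = 20.0
    b_prev: float = 0.0
    b_curr: float = 0.0
    b_type: float = 0.0
    b_rt: float = 0.0
    b_curr_type: float = 0.0
    modulated_epochs: tuple[str, ...] = ("delay",)
    epoch_baselines: dict = field(default_factory=dict)
    rate_floor: float = 0.1

    def rate(self, epoch: str, x_prev: float, x_curr: float, x_type: float, x_rt: float) -> float:
        base = self.epoch_baselines.get(epoch, self.baseline_rate)
        if epoch in self.modulated_epochs:
            base = base + (
                self.b_prev * x_prev
                + self.b_curr * x_curr
                + self.b_type * x_type
                + self.b_rt * x_rt
                + self.b_curr_type * x_curr * x_type
            )
        return max(base, self.rate_floor)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def _psychometric_p_right(cfg: GeneratorConfig, left_prop: float) -> float:
    return 1.0 / (1.0 + np.exp(-cfg.psychometric_a - cfg.psychometric_b * left_prop))


def simulate_behavior(cfg: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate one session; returns the canonical trial table.

    Blocks alternate SG, IS, ... starting with SG; each advances after
    ``correct_per_block`` correct choices (capped at
    ``max_trials_per_block`` with a warning, recorded in
    ``df.attrs['capped_blocks']``).  The IS rewarded side switches between
    consecutive IS blocks.  Identical ``seed`` gives a bit-identical table.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    V = {"left": 0.5, "right": 0.5}
    is_side = cfg.is_first_rewarded_side
    trials: list[TrialRecord] = []
    capped: list[int] = []
    t = rng.uniform(1.0, 3.0)  # session start offset
    trial_index = 0
    for block in range(1, cfg.n_blocks + 1):
        block_type = SG if block % 2 == 1 else IS
        if block_type == IS and block > 2:
            is_side = "right" if is_side == "left" else "left"
        n_correct = n_in_block = 0
        while n_correct < cfg.correct_per_block:
            if n_in_block >= cfg.max_trials_per_block:
                capped.append(block)
                warnings.warn(
                    f"block {block} capped at {cfg.max_trials_per_block} trials "
                    f"before reaching {cfg.correct_per_block} correct",
                    stacklevel=2,
                )
                break
            # --- stimulus and rewarded side
            if block_type == SG:
                left_pct = float(rng.choice(cfg.sg_mixtures))
                rewarded_side = (
                    "either" if left_pct == 50 else ("left" if left_pct > 50 else "right")
                )
            else:
                left_pct = 50.0
                rewarded_side = is_side
            # --- choice policy
            if rng.random() < cfg.lapse:
                p_right = 0.5
            elif block_type == SG:
                p_right = _psychometric_p_right(cfg, left_pct / 100.0)
            else:
                p_right = 1.0 / (
                    1.0 + np.exp(-cfg.agent_beta_softmax * (V["right"] - V["left"]))
                )
            premature = rng.random() < cfg.premature_prob
            no_choice = premature and rng.random() < cfg.no_choice_given_premature
            chosen = "none" if no_choice else ("right" if rng.random() < p_right else "left")
            # --- outcome
            if chosen == "none":
                correct = rewarded = False
            elif rewarded_side == "either":
                correct = rng.random() < 0.5  # chosen port armed independently
                rewarded = correct and not premature
            else:
                correct = chosen == rewarded_side
                rewarded = correct and not premature
            # --- value update on every chosen trial (SG and IS alike)
            if chosen != "none":
                V[chosen] = update_value(V[chosen], 1.0 if rewarded else 0.0, cfg.agent_alpha)
            # --- event timing
            t_entry = t
            t_valve = t_entry + cfg.valve_latency_s
            delay = _truncated_normal(rng, cfg.delay_mean_s, cfg.delay_sd_s)
            if premature:
                t_go = np.nan
                t_exit = t_valve + delay * rng.uniform(0.1, 0.9)
            else:
                t_go = t_valve + delay
                t_exit = np.nan  # set below from the reaction time
            if chosen == "none":
                t_rew_in = t_rew_out = np.nan
                if np.isnan(t_exit):
                    t_exit = t_valve + delay * rng.uniform(0.1, 0.9)
                t = t_exit + cfg.iti_min_s + rng.exponential(cfg.iti_mean_s)
            else:
                mean_rt = cfg.rt_means[(block_type, chosen)]
                rt = rng.lognormal(np.log(mean_rt) - cfg.rt_log_sd**2 / 2, cfg.rt_log_sd)
                exit_latency = min(rng.exponential(cfg.exit_latency_mean_s), 0.6 * rt)
                if premature:
                    t_rew_in = t_exit + max(rt - cfg.exit_latency_mean_s, 0.05)
                else:
                    t_exit = t_go + exit_latency
                    t_rew_in = t_go + rt
                t_rew_out = t_rew_in + cfg.reward_hold_s
                t = t_rew_out + cfg.iti_min_s + rng.exponential(cfg.iti_mean_s)
            trials.append(
                TrialRecord(
                    trial_index=trial_index,
                    block_index=block,
                    block_type=block_type,
                    left_odor_pct=left_pct,
                    rewarded_side=rewarded_side,
                    chosen_side=chosen,
                    correct=correct,
                    rewarded=rewarded,
                    premature_exit=premature,
                    t_odor_port_entry=t_entry,
                    t_valve_open=t_valve,
                    t_go=t_go,
                    t_odor_port_exit=t_exit,
                    t_reward_port_entry=t_rew_in,
                    t_reward_port_exit=t_rew_out,
                )
            )
            trial_index += 1
            n_in_block += 1
            n_correct += int(correct)
    df = trials_to_frame(trials)
    df.attrs["capped_blocks"] = capped
    return df


_GEN_EPOCHS = (
    ("pre_stim", "t_odor_port_entry", "t_valve_open"),
    ("delay", "t_valve_open", "t_odor_port_exit"),
    ("movement", "t_odor_port_exit", "t_reward_port_entry"),
    ("reward", "t_reward_port_entry", "t_reward_port_exit"),
)


def simulate_spikes(
    trials: pd.DataFrame,
    params: NeuronParams,
    seed: int = 0,
    neuron_id: str = "n0",
    hemisphere: str = "left",
) -> SpikeTrain:
    """Draw one neuron's spike train over the session.

    Each epoch of each trial is homogeneous Poisson at the realized rate
    from ``params`` and that trial's coded predictors; inter-epoch gaps run
    at baseline.  Predictors are coded exactly as the regression module
    codes them on the trial-filtered session, so regression on the
    generated rates is unbiased for the ``b`` coefficients; trials the
    analyses would exclude are generated at baseline.
    """
    rng = np.random.default_rng(seed)
    included = filter_trials(trials)
    design = regression.encode_predictors(included, hemisphere)
    x = pd.DataFrame(
        0.0, index=trials.index, columns=["x_prev", "x_curr", "x_type", "x_rt"]
    )
    x.loc[included.index] = design[["x_prev", "x_curr", "x_type", "x_rt"]]
    modulated = np.zeros(len(trials), dtype=bool)
    modulated[trials.index.get_indexer(included.index)] = True

    segments: list[tuple[float, float, float]] = []  # (start, end, rate)
    cursor = 0.0
    base = params.rate_floor if params.baseline_rate <= 0 else params.baseline_rate
    xp = x.to_numpy()
    for i, (_, tr) in enumerate(trials.iterrows()):
        for name, c0, c1 in _GEN_EPOCHS:
            s, e = tr[c0], tr[c1]
            if np.isnan(s) or np.isnan(e) or e <= s:
                continue
            if s > cursor:
                segments.append((cursor, s, base))
            rate = (
                params.rate(name, *xp[i])
                if modulated[i]
                else max(params.epoch_baselines.get(name, params.baseline_rate), params.rate_floor)
            )
            segments.append((s, e, rate))
            cursor = e
    spikes = []
    for s, e, rate in segments:
        n = rng.poisson(rate * (e - s))
        if n:
            spikes.append(rng.uniform(s, e, size=n))
    times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    return SpikeTrain(neuron_id=neuron_id, hemisphere=hemisphere, spike_times=times)


def simulate_session(
    cfg: GeneratorConfig | None = None,
    neuron_params: list[NeuronParams] | None = None,
    seed: int = 0,
    hemisphere: str = "left",
) -> tuple[pd.DataFrame, list[SpikeTrain], list[NeuronParams]]:
    """Simulate behavior plus a population of neurons with known ground truth."""
    cfg = replace(cfg or GeneratorConfig(), seed=seed)
    trials = simulate_behavior(cfg)
    neuron_params = neuron_params if neuron_params is not None else [NeuronParams()]
    rng = np.random.default_rng(seed + 1)
    neurons = [
        simulate_spikes(
            trials, p, seed=int(rng.integers(2**31)), neuron_id=f"n{i:03d}", hemisphere=hemisphere
        )
        for i, p in enumerate(neuron_params)
    ]
    return trials, neurons, neuron_params
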