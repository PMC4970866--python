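import numpy as np
import pandas as pd
import pytest

from nigramode import data_model, regression, synthetic


@pytest.fixture(scope="session")
def session_trials() -> pd.DataFrame:
    """One default-generator session, shared across tests."""
    return synthetic.simulate_behavior(seed=1)


@pytest.fixture(scope="session")
def included_trials(session_trials) -> pd.DataFrame:
    return data_model.filter_trials(session_trials)


@pytest.fixture(scope="session")
def session_design(included_trials) -> pd.DataFrame:
    return regression.encode_predictors(included_trials)


@pytest.fixture(scope="session")
def contra_neuron(session_trials) -> data_model.SpikeTrain:
    """Left-hemisphere neuron with a strong contraversive direction signal."""
    params = synthetic.NeuronParams(baseline_rate=20.0, b_curr=4.0)
    return synthetic.simulate_spikes(session_trials, params, seed=7)


def make_trials(
    block_types: list[str],
    chosen: list[str],
    correct: list[bool] | None = None,
    rewarded: list[bool] | None = None,
    left_odor_pct: list[float] | None = None,
    delay_s: float = 0.5,
    rt_s: list[float] | float = 0.4,
    trial_spacing_s: float = 3.0,
) -> pd.DataFrame:
    """Hand-build a minimal valid trial table for targeted unit tests."""
    n = len(chosen)
    if correct is None:
        correct = [c != "none" for c in chosen]
    if rewarded is None:
        rewarded = list(correct)
    if left_odor_pct is None:
        left_odor_pct = [50.0 if bt == "IS" else 80.0 for bt in block_types]
    rts = np.broadcast_to(np.asarray(rt_s, float), (n,))
    recs = []
    for i in range(n):
        entry = trial_spacing_s * (i + 1)
        valve = entry + 0.05
        go = valve + delay_s
        has_choice = chosen[i] != "none"
        exit_ = go + 0.05
        recs.append(
            data_model.TrialRecord(
                trial_index=i,
                block_index=1 if block_types[i] == "SG" else 2,
                block_type=block_types[i],
                left_odor_pct=left_odor_pct[i],
                rewarded_side=chosen[i] if (has_choice and correct[i]) else "left",
                chosen_side=chosen[i],
                correct=bool(correct[i] and has_choice),
                rewarded=bool(rewarded[i] and correct[i] and has_choice),
                premature_exit=False,
                t_odor_port_entry=entry,
                t_valve_open=valve,
                t_go=go,
                t_odor_port_exit=exit_,
                t_reward_port_entry=go + rts[i] if has_choice else np.nan,
                t_reward_port_exit=go + rts[i] + 1.0 if has_choice else np.nan,
            )
        )
    return data_model.trials_to_frame(recs)
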