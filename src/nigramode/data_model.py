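"""Core domain types, epoch definitions, firing-rate extraction and session I/O.

A behavioral session is represented as a :class:`pandas.DataFrame` with one
row per trial (the :data:`TRIAL_COLUMNS` schema) together with a list of
:class:`SpikeTrain` objects, one per simultaneously recorded neuron.  All
times are seconds from session start; absent timestamps (e.g. the reward-port
events of a trial in which no choice was made) are NaN.

Trial epochs are half-open intervals ``[start, end)`` bounded by behavioral
events:

==========  =============================================
pre_stim    odor port entry -> odor valve open
delay       odor valve open -> odor port exit
movement    odor port exit -> reward port entry
control     odor port entry -> reward port exit (whole trial)
==========  =============================================

The delay epoch is the window in which the direction of the upcoming
movement is being selected; the control window stands in for a baseline
because the task has no task-free epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "EPOCHS",
    "SG",
    "IS",
    "TrialRecord",
    "SpikeTrain",
    "NeuronFilterResult",
    "trials_to_frame",
    "validate_trials",
    "with_derived_times",
    "epoch_bounds",
    "epoch_rate",
    "epoch_rates",
    "choice_sign",
    "filter_trials",
    "filter_neurons",
    "read_session",
    "write_session",
    "MOVEMENT_TIME_MAX_S",
    "MIN_TRIALS_PER_TYPE",
    "MIN_RATE_SP_S",
]

SG = "SG"
IS = "IS"

#: Mixture levels, as percent of the left-indicating odor in the binary mixture.
SG_MIXTURE_LEVELS = (95, 80, 60, 50, 40, 20, 5)
EASY_MIXTURES = frozenset({95, 80, 20, 5})
DIFFICULT_MIXTURES = frozenset({60, 50, 40})

TRIAL_COLUMNS = [
    "trial_index",
    "block_index",
    "block_type",
    "left_odor_pct",
    "rewarded_side",
    "chosen_side",
    "correct",
    "rewarded",
    "premature_exit",
    "t_odor_port_entry",
    "t_valve_open",
    "t_go",
    "t_odor_port_exit",
    "t_reward_port_entry",
    "t_reward_port_exit",
]

_TIMESTAMP_COLUMNS = TRIAL_COLUMNS[9:]

#: Epoch name -> (start event column, end event column); intervals [start, end).
EPOCHS = {
    "pre_stim": ("t_odor_port_entry", "t_valve_open"),
    "delay": ("t_valve_open", "t_odor_port_exit"),
    "movement": ("t_odor_port_exit", "t_reward_port_entry"),
    "control": ("t_odor_port_entry", "t_reward_port_exit"),
}

#: Trials with movement time (odor port exit -> reward port entry) above this
#: are excluded from all analyses.
MOVEMENT_TIME_MAX_S = 1.5
#: A neuron needs at least this many trials of each block type to be analysed.
MIN_TRIALS_PER_TYPE = 100
#: ... and at least this mean control-window rate (sp/s) in SG trials, in IS
#: trials, and across the session.
MIN_RATE_SP_S = 2.5


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``left_odor_pct`` is the percentage of the left-indicating odor in the
    binary mixture (50 on every internally-specified trial).  ``rewarded_side``
    is ``"either"`` on balanced stimulus-guided trials, where each port
    independently holds reward with probability 0.5.
    """

    trial_index: int
    block_index: int
    block_type: str
    left_odor_pct: float
    rewarded_side: str
    chosen_side: str
    correct: bool
    rewarded: bool
    premature_exit: bool
    t_odor_port_entry: float
    t_valve_open: float
    t_go: float = np.nan
    t_odor_port_exit: float = np.nan
    t_reward_port_entry: float = np.nan
    t_reward_port_exit: float = np.nan


@dataclass
class SpikeTrain:
    """Sorted spike times (s from session start) of one well-isolated neuron.

    ``hemisphere`` fixes the ipsi/contra mapping: for a left-hemisphere
    neuron an ipsiversive movement is a leftward choice.
    """

    neuron_id: str
    hemisphere: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"spike_times of {self.neuron_id} are not sorted")

    @property
    def ipsiversive_side(self) -> str:
        return self.hemisphere

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class NeuronFilterResult:
    neuron_id: str
    include: bool
    reason: str | None = None


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Stack TrialRecords into the canonical trials table."""
    df = pd.DataFrame([vars(t) for t in trials], columns=TRIAL_COLUMNS)
    return df.astype({"correct": bool, "rewarded": bool, "premature_exit": bool})


def validate_trials(trials: pd.DataFrame) -> None:
    """Check the trial-table schema and its internal invariants.

    Raises ``ValueError`` naming the offending column or trial.  Checked
    invariants: present timestamps strictly increase in event order; IS
    trials carry the balanced mixture; no-choice trials are incorrect and
    unrewarded; reward implies a correct choice.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s): {', '.join(missing)}")
    ts = trials[_TIMESTAMP_COLUMNS].to_numpy(dtype=float)
    for row, idx in zip(ts, trials["trial_index"]):
        present = row[~np.isnan(row)]
        if np.any(np.diff(present) <= 0):
            raise ValueError(f"trial {idx}: timestamps not strictly increasing")
    is_trials = trials["block_type"] == IS
    if not np.all(trials.loc[is_trials, "left_odor_pct"] == 50):
        raise ValueError("IS trial with unbalanced mixture")
    no_choice = trials["chosen_side"] == "none"
    if trials.loc[no_choice, ["correct", "rewarded"]].any().any():
        raise ValueError("no-choice trial marked correct or rewarded")
    if (trials["rewarded"] & ~trials["correct"]).any():
        raise ValueError("rewarded trial marked incorrect")
    if (trials["rewarded"] & trials["premature_exit"]).any():
        raise ValueError("premature trial marked rewarded")


def with_derived_times(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with reaction_time, movement_time and delay_duration.

    Reaction time runs from the go cue to reward-port entry; movement time
    from odor-port exit to reward-port entry.  Undefined (missing event)
    values are NaN.
    """
    out = trials.copy()
    out["reaction_time"] = out["t_reward_port_entry"] - out["t_go"]
    out["movement_time"] = out["t_reward_port_entry"] - out["t_odor_port_exit"]
    out["delay_duration"] = out["t_odor_port_exit"] - out["t_valve_open"]
    return out


def epoch_bounds(trials: pd.DataFrame, epoch: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (start, end) arrays for a named epoch; NaN where undefined."""
    try:
        start_col, end_col = EPOCHS[epoch]
    except KeyError:
        raise KeyError(f"unknown epoch {epoch!r}; expected one of {sorted(EPOCHS)}") from None
    return (
        trials[start_col].to_numpy(dtype=float),
        trials[end_col].to_numpy(dtype=float),
    )


def epoch_rate(spikes: SpikeTrain | np.ndarray, start: float, end: float) -> float:
    """Firing rate (sp/s) in the half-open window ``[start, end)``.

    Raises ``ValueError`` for an undefined or empty window (NaN endpoint or
    ``end <= start``), e.g. the movement epoch of a no-choice trial.
    """
    times = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    if np.isnan(start) or np.isnan(end):
        raise ValueError("epoch endpoint undefined for this trial")
    if end <= start:
        raise ValueError(f"degenerate epoch [{start}, {end})")
    lo, hi = np.searchsorted(times, [start, end], side="left")
    return float(hi - lo) / (end - start)


def epoch_rates(spikes: SpikeTrain, trials: pd.DataFrame, epoch: str = "delay") -> np.ndarray:
    """Per-trial firing rate in the named epoch; NaN where the epoch is undefined."""
    start, end = epoch_bounds(trials, epoch)
    ok = ~np.isnan(start) & ~np.isnan(end) & (end > start)
    counts = np.zeros(len(trials))
    lo = np.searchsorted(spikes.spike_times, np.where(ok, start, 0.0), side="left")
    hi = np.searchsorted(spikes.spike_times, np.where(ok, end, 0.0), side="left")
    counts = (hi - lo).astype(float)
    rates = np.full(len(trials), np.nan)
    rates[ok] = counts[ok] / (end[ok] - start[ok])
    return rates


def choice_sign(trials: pd.DataFrame, hemisphere: str = "left") -> np.ndarray:
    """Code choices as -1 (ipsiversive), +1 (contraversive), 0 (no choice).

    For a left-hemisphere neuron an ipsiversive choice is leftward, so +1
    means a rightward (contraversive) movement.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError(f"bad hemisphere {hemisphere!r}")
    chosen = trials["chosen_side"].to_numpy()
    sign = np.zeros(len(trials))
    sign[chosen == hemisphere] = -1.0
    sign[(chosen != hemisphere) & (chosen != "none")] = 1.0
    return sign


def filter_trials(trials: pd.DataFrame, require_choice: bool = False) -> pd.DataFrame:
    """Apply the session-wide trial exclusions.

    Trials whose movement time exceeds 1.5 s (strictly) are removed from
    all analyses.  With ``require_choice`` the no-choice trials are removed
    too, for movement-conditioned analyses.  Original row indices are
    preserved so excluded trials leave gaps rather than renumbering.
    """
    mt = trials["t_reward_port_entry"] - trials["t_odor_port_exit"]
    keep = ~(mt > MOVEMENT_TIME_MAX_S)
    if require_choice:
        keep &= trials["chosen_side"] != "none"
    return trials.loc[keep]


def filter_neurons(
    neuron: SpikeTrain, trials: pd.DataFrame
) -> NeuronFilterResult:
    """Decide whether a neuron enters the analyses, with the first failing rule.

    A neuron is excluded when it has fewer than 100 trials of either block
    type, or when its mean control-window rate is below 2.5 sp/s in SG
    trials, in IS trials, or across the whole session.  ``trials`` should
    already be trial-filtered.
    """
    if len(trials) == 0:
        raise ValueError("empty session: no trials to evaluate neuron against")
    is_sg = (trials["block_type"] == SG).to_numpy()
    n_sg, n_is = int(is_sg.sum()), int((~is_sg).sum())
    if n_sg < MIN_TRIALS_PER_TYPE or n_is < MIN_TRIALS_PER_TYPE:
        return NeuronFilterResult(neuron.neuron_id, False, "trial count")
    rates = epoch_rates(neuron, trials, "control")
    with np.errstate(invalid="ignore"):
        mean_sg = np.nanmean(rates[is_sg])
        mean_is = np.nanmean(rates[~is_sg])
        mean_all = np.nanmean(rates)
    if min(mean_sg, mean_is, mean_all) < MIN_RATE_SP_S:
        return NeuronFilterResult(neuron.neuron_id, False, "firing rate")
    return NeuronFilterResult(neuron.neuron_id, True)


# ---------------------------------------------------------------------------
# Session I/O: trials.csv + spikes_<neuron_id>.csv + neurons.json

def write_session(
    path: str | Path, trials: pd.DataFrame, neurons: Sequence[SpikeTrain] = ()
) -> None:
    """Write a session directory: trials.csv, per-neuron spike CSVs, neurons.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials[TRIAL_COLUMNS].to_csv(path / "trials.csv", index=False, float_format="%.6f")
    sidecar = []
    for n in neurons:
        pd.DataFrame({"spike_time_s": n.spike_times}).to_csv(
            path / f"spikes_{n.neuron_id}.csv", index=False, float_format="%.6f"
        )
        sidecar.append({"neuron_id": n.neuron_id, "hemisphere": n.hemisphere})
    (path / "neurons.json").write_text(json.dumps(sidecar, indent=1))


def read_session(path: str | Path) -> tuple[pd.DataFrame, list[SpikeTrain]]:
    """Read a session directory written by :func:`write_session`.

    Returns the validated trial table and the spike trains.  A malformed
    table raises ``ValueError`` naming the column or trial at fault.
    """
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path / 'trials.csv'}: missing column(s) {', '.join(missing)}")
    trials = trials.astype({"correct": bool, "rewarded": bool, "premature_exit": bool})
    validate_trials(trials)
    neurons = []
    sidecar_path = path / "neurons.json"
    if sidecar_path.exists():
        for entry in json.loads(sidecar_path.read_text()):
            spike_path = path / f"spikes_{entry['neuron_id']}.csv"
            spikes = pd.read_csv(spike_path)["spike_time_s"].to_numpy() if spike_path.stat().st_size else np.empty(0)
            if spikes.ndim == 0:
                spikes = np.empty(0)
            neurons.append(
                SpikeTrain(entry["neuron_id"], entry["hemisphere"], spikes)
            )
    return trials, neurons
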