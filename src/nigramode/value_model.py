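"""Reward-history value traces (Q-learning without a future-value term).

Each movement direction carries a value ``V`` in [0, 1], updated only on
trials in which that direction was chosen::

    V <- V + alpha * (R - V)

with ``R = 1`` for a rewarded trial and ``R = 0`` otherwise — including
trials in which the correct port was chosen but the odor port was exited
before the go signal, so no reward was delivered.  The trace for the
unchosen direction is carried forward unchanged.  With a constant reward
stream the trace follows the closed form
``V_k = R - (R - V_0) * (1 - alpha)**k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ValueTrace", "update_value", "value_trace", "rate_value_correlation"]

DEFAULT_ALPHA = 0.1


@dataclass
class ValueTrace:
    """Per-trial, per-direction value estimates.

    ``V[side][t]`` is the value of ``side`` *going into* trial ``t`` (i.e.
    before that trial's outcome is applied), which is the quantity a neuron
    recorded during trial ``t`` could reflect.
    """

    alpha: float
    V: dict[str, np.ndarray]
    R: np.ndarray  # reward indicator of the chosen direction, NaN for no choice

    def chosen_value(self, trials: pd.DataFrame) -> np.ndarray:
        """Value of the direction chosen on each trial (NaN for no choice)."""
        out = np.full(len(trials), np.nan)
        chosen = trials["chosen_side"].to_numpy()
        for side in ("left", "right"):
            out[chosen == side] = self.V[side][chosen == side]
        return out

    def side_value(self, side: str) -> np.ndarray:
        return self.V[side]


def update_value(V: float, R: float, alpha: float = DEFAULT_ALPHA) -> float:
    """One delta-rule step ``V + alpha * (R - V)``."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return V + alpha * (R - V)


def value_trace(
    trials: pd.DataFrame, alpha: float = DEFAULT_ALPHA, V0: float = 0.5
) -> ValueTrace:
    """Run the per-direction value update over a whole session (SG and IS trials).

    ``trials`` must be in chronological order with ``chosen_side`` and
    ``rewarded`` columns.  Because the trace runs over the entire session it
    typically sits near — but not exactly at — ``V0`` when an IS block
    begins, then climbs toward 1 for the rewarded side as the animal
    repeatedly returns to it.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = len(trials)
    V = {"left": np.empty(n), "right": np.empty(n)}
    R = np.full(n, np.nan)
    v = {"left": float(V0), "right": float(V0)}
    chosen = trials["chosen_side"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    for t in range(n):
        V["left"][t] = v["left"]
        V["right"][t] = v["right"]
        side = chosen[t]
        if side in v:
            r = 1.0 if rewarded[t] else 0.0
            R[t] = r
            v[side] = update_value(v[side], r, alpha)
    return ValueTrace(alpha=alpha, V=V, R=R)


def rate_value_correlation(
    rates: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between per-trial firing rates and value estimates.

    Both arrays must be restricted to the trials of interest (e.g. the
    IS-block trials of one movement direction) before calling.  Raises
    ``ValueError`` on fewer than 3 trials or zero variance in either input.
    """
    rates = np.asarray(rates, float)
    values = np.asarray(values, float)
    ok = ~np.isnan(rates) & ~np.isnan(values)
    rates, values = rates[ok], values[ok]
    if len(rates) < 3:
        raise ValueError(f"need at least 3 trials, got {len(rates)}")
    if np.ptp(rates) == 0 or np.ptp(values) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(rates, values)
    return float(r), float(p)
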