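"""Linear regression of firing rate on task factors, static and sliding-window.

The base model regresses the delay-epoch firing rate of one neuron on four
coded predictors::

    FR = b0 + b_prev * x_prev + b_curr * x_curr + b_type * x_type + b_rt * x_rt

with x_prev and x_curr in {-1, 0, +1} (ipsiversive / no choice /
contraversive choice on the previous and current trial), x_type in
{-1 (internally specified), +1 (stimulus guided)} and x_rt the reaction time
min–max normalized to [0, 1] within the session's included trials.  b0 is
then the mean rate across trials and each coefficient is the rate change
(sp/s) per coded unit.  Fits are ordinary least squares with homoskedastic
t-based p-values and 95% confidence intervals.

The sliding-window variant refits the same model on spike counts in
overlapping 100 ms bins stepped by 10 ms, aligned to odor valve open, odor
port exit or reward port entry, tracing how each factor's influence evolves
through the trial.  An extended model adds a value regressor (reward-history
value in IS trials, per-mixture block accuracy in SG trials) and its
interaction with trial type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import value_model
from .data_model import IS, SG, SpikeTrain, choice_sign

__all__ = [
    "BASE_PREDICTORS",
    "ALIGN_EVENTS",
    "RegressionFit",
    "encode_predictors",
    "fit_rate_regression",
    "sliding_window_fit",
    "population_fraction",
    "value_predictor",
    "extended_fit",
]

BASE_PREDICTORS = ["x_prev", "x_curr", "x_type", "x_rt"]

#: Short alignment-event names accepted by :func:`sliding_window_fit`.
ALIGN_EVENTS = {
    "valve_open": "t_valve_open",
    "odor_exit": "t_odor_port_exit",
    "reward_entry": "t_reward_port_entry",
}


@dataclass
class RegressionFit:
    """Per-coefficient estimates of one OLS fit.

    ``table`` is indexed by coefficient name (``const`` plus predictor
    columns) with columns beta, se, ci_lo, ci_hi, p.  For sliding-window
    fits ``window`` holds (alignment event, window-center offset in s).
    """

    table: pd.DataFrame
    n_trials: int
    window: tuple[str, float] | None = None

    def beta(self, name: str) -> float:
        return float(self.table.loc[name, "beta"])

    def p(self, name: str) -> float:
        return float(self.table.loc[name, "p"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_lo"]), float(row["ci_hi"])

    @property
    def names(self) -> list[str]:
        return list(self.table.index)


def encode_predictors(trials: pd.DataFrame, hemisphere: str = "left") -> pd.DataFrame:
    """Build the coded design table for an (already trial-filtered) session.

    One row per trial: x_prev, x_curr, x_type, x_rt, plus an ``rt_imputed``
    flag.  The previous-trial code of the first row is 0 (no previous
    choice).  Trials without a defined reaction time (no choice, or
    premature exit before the go cue) get the session-median normalized
    reaction time and are flagged.
    """
    curr = choice_sign(trials, hemisphere)
    prev = np.concatenate([[0.0], curr[:-1]])
    x_type = np.where(trials["block_type"].to_numpy() == SG, 1.0, -1.0)
    rt = (trials["t_reward_port_entry"] - trials["t_go"]).to_numpy(dtype=float)
    ok = ~np.isnan(rt)
    x_rt = np.full(len(trials), np.nan)
    if ok.any():
        lo, hi = rt[ok].min(), rt[ok].max()
        span = hi - lo
        x_rt[ok] = (rt[ok] - lo) / span if span > 0 else 0.0
        x_rt[~ok] = np.median(x_rt[ok])
    return pd.DataFrame(
        {
            "x_prev": prev,
            "x_curr": curr,
            "x_type": x_type,
            "x_rt": x_rt,
            "rt_imputed": ~ok,
        },
        index=trials.index,
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose QR diagonal collapses
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [n for n, d in zip(names, diag) if d < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {', '.join(bad) or 'unidentified'}"
        )


def fit_rate_regression(
    rates: np.ndarray,
    design: pd.DataFrame,
    predictors: list[str] | None = None,
) -> RegressionFit:
    """OLS fit of per-trial rates on the coded predictors.

    Rows with a NaN rate (undefined epoch) are dropped.  Requires at least
    10 more trials than parameters.  Raises ``ValueError`` for a
    rank-deficient design, naming the collinear columns.
    """
    predictors = list(predictors or BASE_PREDICTORS)
    rates = np.asarray(rates, dtype=float)
    ok = ~np.isnan(rates)
    y = rates[ok]
    Xdf = design.loc[ok, predictors] if isinstance(design, pd.DataFrame) else pd.DataFrame(
        np.asarray(design)[ok], columns=predictors
    )
    n, k = len(y), len(predictors) + 1
    if n < k + 10:
        raise ValueError(f"need at least {k + 10} trials for {k} parameters, got {n}")
    X = sm.add_constant(Xdf.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + predictors
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
            "p": res.pvalues,
        },
        index=names,
    )
    return RegressionFit(table=table, n_trials=n)


def _event_column(align_event: str) -> str:
    if align_event in ALIGN_EVENTS:
        return ALIGN_EVENTS[align_event]
    if align_event.startswith("t_"):
        return align_event
    raise KeyError(
        f"unknown alignment event {align_event!r}; expected one of {sorted(ALIGN_EVENTS)}"
    )


def window_offsets(
    span: tuple[float, float] = (-0.5, 0.5), window: float = 0.100, step: float = 0.010
) -> np.ndarray:
    """Left edges of the sliding windows covering ``span``."""
    n = int(round((span[1] - span[0] - window) / step)) + 1
    return span[0] + step * np.arange(n)


def sliding_window_fit(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    align_event: str,
    window: float = 0.100,
    step: float = 0.010,
    span: tuple[float, float] = (-0.5, 0.5),
    design: pd.DataFrame | None = None,
    predictors: list[str] | None = None,
) -> list[RegressionFit]:
    """Refit the rate regression in overlapping windows around one event.

    Firing rate in each window is spike count / window length in
    ``[event + offset, event + offset + window)``.  Trials lacking the
    alignment event are dropped window-by-window.  Returns one
    :class:`RegressionFit` per window, tagged with the window-center offset.
    """
    col = _event_column(align_event)
    if design is None:
        design = encode_predictors(trials, neuron.hemisphere)
    events = trials[col].to_numpy(dtype=float)
    has_event = ~np.isnan(events)
    offsets = window_offsets(span, window, step)
    fits = []
    ev = events[has_event]
    sub_design = design.loc[has_event]
    for off in offsets:
        lo = np.searchsorted(neuron.spike_times, ev + off, side="left")
        hi = np.searchsorted(neuron.spike_times, ev + off + window, side="left")
        rates = (hi - lo) / window
        fit = fit_rate_regression(rates, sub_design, predictors)
        fit.window = (align_event, float(off + window / 2))
        fits.append(fit)
    return fits


def population_fraction(
    fits_by_neuron: list[list[RegressionFit]], alpha: float = 0.05
) -> pd.DataFrame:
    """Fraction of neurons with a significant coefficient, per window.

    All neurons must share the same window grid (same alignment, offsets).
    Returns a table indexed by window-center offset with one column per
    coefficient plus ``n_neurons``.
    """
    grids = {tuple(f.window for f in fits) for fits in fits_by_neuron}
    if len(grids) != 1:
        raise ValueError("neurons have mismatched window grids")
    windows = [f.window for f in fits_by_neuron[0]]
    names = fits_by_neuron[0][0].names
    frac = {
        name: [
            float(np.mean([fits[w].p(name) < alpha for fits in fits_by_neuron]))
            for w in range(len(windows))
        ]
        for name in names
    }
    out = pd.DataFrame(frac, index=pd.Index([w[1] for w in windows], name="window_center_s"))
    out["n_neurons"] = len(fits_by_neuron)
    return out


def value_predictor(trials: pd.DataFrame, alpha: float = value_model.DEFAULT_ALPHA) -> np.ndarray:
    """Per-trial value regressor for the extended model.

    IS trials use the reward-history value trace of the block's rewarded
    side; SG trials use the block's average accuracy at that trial's mixture
    ratio (the empirically experienced probability of reward given the
    stimulus).  Balanced SG trials, where either port may hold reward, use
    the realized fraction rewarded instead of accuracy.
    """
    values = np.full(len(trials), np.nan)
    pos = {idx: i for i, idx in enumerate(trials.index)}
    trace = value_model.value_trace(trials, alpha=alpha)
    is_mask = (trials["block_type"] == IS).to_numpy()
    rewarded_side = trials["rewarded_side"].to_numpy()
    for side in ("left", "right"):
        m = is_mask & (rewarded_side == side)
        values[m] = trace.V[side][m]
    for (block, mix), grp in trials[trials["block_type"] == SG].groupby(
        ["block_index", "left_odor_pct"]
    ):
        rows = [pos[i] for i in grp.index]
        if mix == 50:
            values[rows] = grp["rewarded"].mean()
        else:
            chosen = grp["chosen_side"] != "none"
            values[rows] = grp.loc[chosen, "correct"].mean() if chosen.any() else 0.5
    return values


def extended_fit(
    rates: np.ndarray,
    design: pd.DataFrame,
    values: np.ndarray,
) -> RegressionFit:
    """Six-predictor OLS adding value and the value × trial-type interaction."""
    ext = design.copy()
    ext["x_value"] = values
    ext["x_value_type"] = values * ext["x_type"]
    return fit_rate_regression(rates, ext, BASE_PREDICTORS + ["x_value", "x_value_type"])
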