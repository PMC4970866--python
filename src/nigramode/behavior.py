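"""Behavioral performance: psychometric fits, IS-block metrics, reaction times.

Covers the session-level behavioral characterization of the task: the
logistic psychometric curve of stimulus-guided choices, percent correct and
error events (maximal runs of consecutive incorrect choices) in
internally-specified blocks, the reaction-time advantage of IS over easy SG
trials, and the boxcar-smoothed left-choice fraction across the block
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    DIFFICULT_MIXTURES,
    EASY_MIXTURES,
    IS,
    SG,
    filter_trials,
    with_derived_times,
)

__all__ = [
    "PsychometricFit",
    "BlockPerformance",
    "fit_psychometric",
    "count_error_events",
    "block_performance",
    "reaction_time_contrast",
    "smoothed_left_fraction",
    "aggregate_left_fraction",
]


@dataclass
class PsychometricFit:
    """Logistic choice curve p(right) = 1 / (1 + exp(-a - b*x)).

    ``x`` is the proportion (0-1) of the left-indicating odor, so a
    stimulus-following animal has b < 0: more left odor, fewer right
    choices.
    """

    a: float
    b: float
    converged: bool

    def p_right(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.a - self.b * np.asarray(x, float)))


@dataclass
class BlockPerformance:
    block_index: int
    percent_correct: float
    n_error_events: int
    n_choice_trials: int


def fit_psychometric(sg_trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit of right-choices on left-odor proportion.

    Uses the Bernoulli likelihood of each single-trial choice (not binned
    proportions).  Requires choices at >= 2 distinct mixture levels.
    Perfect separation is flagged ``converged=False`` with the parameters
    left at the optimizer's bound.
    """
    chosen = sg_trials["chosen_side"].to_numpy()
    ok = chosen != "none"
    x = sg_trials["left_odor_pct"].to_numpy(dtype=float)[ok] / 100.0
    y = (chosen[ok] == "right").astype(float)
    if len(np.unique(x)) < 2:
        raise ValueError("psychometric fit needs >= 2 distinct mixture levels")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            a, b = res.params
            converged = bool(res.mle_retvals.get("converged", False)) and np.all(
                np.abs(res.params) < 50
            )
        except Exception:  # perfect separation raises in some statsmodels versions
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6)
            a, b = res.params
            converged = False
    return PsychometricFit(a=float(a), b=float(b), converged=converged)


def count_error_events(correct_flags) -> int:
    """Number of maximal runs of consecutive incorrect choices."""
    flags = np.asarray(list(correct_flags), dtype=bool)
    wrong = ~flags
    if len(wrong) == 0:
        return 0
    starts = wrong & np.concatenate([[True], ~wrong[:-1]])
    return int(starts.sum())


def block_performance(trials: pd.DataFrame) -> list[BlockPerformance]:
    """Percent correct and error events per IS block.

    Percent correct uses choice trials as the denominator (no-choice trials
    have no correctness); error events count runs of incorrect choices in
    trial order.  Empty blocks are skipped with a warning.
    """
    out = []
    for block, grp in trials[trials["block_type"] == IS].groupby("block_index"):
        chose = grp[grp["chosen_side"] != "none"]
        if len(chose) == 0:
            warnings.warn(f"IS block {block} has no choice trials; skipped", stacklevel=2)
            continue
        out.append(
            BlockPerformance(
                block_index=int(block),
                percent_correct=100.0 * chose["correct"].mean(),
                n_error_events=count_error_events(chose["correct"]),
                n_choice_trials=len(chose),
            )
        )
    return out


def reaction_time_contrast(
    sessions: list[pd.DataFrame], alpha: float = 0.05
) -> dict[str, dict]:
    """IS vs easy-SG reaction times, per movement direction.

    Easy SG trials are the four most discriminable mixtures (95/80/20/5 %
    left odor), so any RT difference is not confounded by difficulty.  For
    each direction: a paired t-test across sessions of the per-session mean
    RTs, and a rank-sum test per session, with counts of sessions
    significantly faster either way.  Sessions lacking either trial type in
    a direction are dropped from that direction's pairing.
    """
    out: dict[str, dict] = {}
    for side in ("left", "right"):
        sg_means, is_means, per_session = [], [], []
        for trials in sessions:
            t = with_derived_times(filter_trials(trials, require_choice=True))
            t = t[(t["chosen_side"] == side) & t["reaction_time"].notna()]
            sg_rt = t.loc[
                (t["block_type"] == SG) & t["left_odor_pct"].isin(EASY_MIXTURES),
                "reaction_time",
            ].to_numpy()
            is_rt = t.loc[t["block_type"] == IS, "reaction_time"].to_numpy()
            if len(sg_rt) == 0 or len(is_rt) == 0:
                continue
            sg_means.append(sg_rt.mean())
            is_means.append(is_rt.mean())
            stat, p = stats.ranksums(is_rt, sg_rt)
            per_session.append({"stat": float(stat), "p": float(p),
                                "is_faster": bool(is_rt.mean() < sg_rt.mean())})
        sg_means, is_means = np.asarray(sg_means), np.asarray(is_means)
        if len(sg_means) >= 2:
            tstat, tp = stats.ttest_rel(is_means, sg_means)
        else:
            tstat, tp = np.nan, np.nan
        sig = [s for s in per_session if s["p"] < alpha]
        out[side] = {
            "n_sessions": len(sg_means),
            "mean_rt_sg_easy": float(sg_means.mean()) if len(sg_means) else np.nan,
            "mean_rt_is": float(is_means.mean()) if len(is_means) else np.nan,
            "paired_t": float(tstat),
            "paired_p": float(tp),
            "n_sessions_is_faster_sig": sum(s["is_faster"] for s in sig),
            "n_sessions_sg_faster_sig": sum(not s["is_faster"] for s in sig),
            "per_session": per_session,
        }
    return out


def smoothed_left_fraction(choices_left: np.ndarray, width: int = 7) -> np.ndarray:
    """Centered boxcar average of a 0/1 left-choice series, truncated at edges."""
    v = np.asarray(choices_left, dtype=float)
    half = width // 2
    return np.array(
        [v[max(0, i - half): i + half + 1].mean() for i in range(len(v))]
    )


def aggregate_left_fraction(
    sessions: list[pd.DataFrame],
    width: int = 7,
    min_session_frac: float = 0.6,
    sg_difficult_only: bool = True,
) -> pd.DataFrame:
    """Mean smoothed left-choice fraction by within-block trial position.

    Each session's choice trials are smoothed per block, then averaged
    across sessions at each (block, position); positions present in fewer
    than ``min_session_frac`` of sessions are dropped so late-block
    positions reached by only a few sessions do not distort the average.
    SG blocks are restricted to the difficult mixtures (60/50/40) by
    default, where choices are informative about block context rather than
    the stimulus.
    """
    records: dict[tuple[int, int], list[float]] = {}
    for trials in sessions:
        for block, grp in trials.groupby("block_index"):
            grp = grp[grp["chosen_side"] != "none"]
            if sg_difficult_only and (grp["block_type"] == SG).any():
                grp = grp[grp["left_odor_pct"].isin(DIFFICULT_MIXTURES)]
            if len(grp) == 0:
                continue
            series = smoothed_left_fraction(grp["chosen_side"].eq("left").to_numpy(), width)
            for pos, val in enumerate(series):
                records.setdefault((int(block), pos), []).append(float(val))
    n_sessions = len(sessions)
    rows = [
        {
            "block_index": blk,
            "position": pos,
            "mean_left_fraction": float(np.mean(vals)),
            "n_sessions": len(vals),
        }
        for (blk, pos), vals in sorted(records.items())
        if len(vals) / n_sessions >= min_session_frac
    ]
    return pd.DataFrame(rows, columns=["block_index", "position", "mean_left_fraction", "n_sessions"])
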