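"""Trial-type (SG vs IS) dependence of delay-epoch activity, and controls.

Three complementary views of whether a neuron's movement-selection activity
differs between stimulus-guided and internally-specified trials:

* the ipsi-contra rate difference computed separately within SG and IS
  trials (a larger difference in IS means a stronger direction signal when
  the movement is internally specified);
* per-neuron unpaired t-tests of SG vs IS rates within the preferred (or
  antipreferred) direction, with population chi-square counts of which way
  significant neurons go;
* a difficulty control: one-way ANOVA of delay rates across the SG mixture
  ratios, to ask whether apparent trial-type effects are really effects of
  discrimination difficulty (or associated variables such as value or
  uncertainty).

Correctness convention: on balanced (50/50) SG trials every choice counts
as correct — there is no correct answer to get wrong.  No multiple-testing
correction is applied anywhere; all classifications use raw p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DIFFICULT_MIXTURES,
    EASY_MIXTURES,
    IS,
    SG,
    SpikeTrain,
    choice_sign,
    epoch_rates,
)
from .selectivity import PreferenceResult

__all__ = [
    "TrialTypeResult",
    "DifficultyResult",
    "correct_mask",
    "direction_difference_by_type",
    "population_direction_difference",
    "trial_type_dependence",
    "population_counts",
    "difficulty_dependence",
    "cross_classification",
]

ALPHA = 0.05


@dataclass
class TrialTypeResult:
    neuron_id: str
    direction: str  # preferred | antipreferred
    mean_rate_SG: float
    mean_rate_IS: float
    p_value: float
    insufficient: bool = False

    @property
    def klass(self) -> str:
        if self.insufficient or not self.p_value < ALPHA:
            return "ns"
        return "higher_IS" if self.mean_rate_IS > self.mean_rate_SG else "higher_SG"


@dataclass
class DifficultyResult:
    neuron_id: str
    direction: str  # ipsiversive | contraversive
    anova_p: float
    mean_norm_easy: float
    mean_norm_difficult: float

    @property
    def significant(self) -> bool:
        return self.anova_p < ALPHA


def correct_mask(trials: pd.DataFrame) -> np.ndarray:
    """Correct-choice mask with the balanced-SG convention.

    All choices on 50/50 SG trials count as correct regardless of the coin
    flip that armed the ports.
    """
    fifty_sg = (
        (trials["block_type"] == SG)
        & (trials["left_odor_pct"] == 50)
        & (trials["chosen_side"] != "none")
    )
    return (trials["correct"] | fifty_sg).to_numpy()


def _preferred_sign(preference: PreferenceResult) -> int:
    return 1 if preference.preference > 0 else -1


def direction_difference_by_type(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    preference: PreferenceResult,
) -> tuple[float, float]:
    """(delta_SG, delta_IS): preferred minus antipreferred delay rate per trial type.

    Correct trials only.  Raises ``ValueError`` when any of the four
    direction-by-type cells is empty, in which case the neuron is dropped
    from this analysis.
    """
    rates = epoch_rates(neuron, trials, "delay")
    sign = choice_sign(trials, neuron.hemisphere)
    ok = correct_mask(trials) & ~np.isnan(rates)
    pref = _preferred_sign(preference)
    deltas = []
    for block_type in (SG, IS):
        m = ok & (trials["block_type"] == block_type).to_numpy()
        pref_rates = rates[m & (sign == pref)]
        anti_rates = rates[m & (sign == -pref)]
        if len(pref_rates) == 0 or len(anti_rates) == 0:
            raise ValueError(
                f"{neuron.neuron_id}: no {block_type} trials in one direction"
            )
        deltas.append(float(pref_rates.mean() - anti_rates.mean()))
    return deltas[0], deltas[1]


def population_direction_difference(
    deltas: list[tuple[float, float]], preference_signs: list[int]
) -> dict[str, dict]:
    """Paired t-test of delta_IS vs delta_SG across neurons, by preference sign."""
    arr = np.asarray(deltas, float)
    signs = np.asarray(preference_signs)
    out = {}
    for label, s in (("ipsiversive", -1), ("contraversive", 1)):
        d_sg, d_is = arr[signs == s, 0], arr[signs == s, 1]
        if len(d_sg) >= 2:
            t, p = stats.ttest_rel(d_is, d_sg)
        else:
            t, p = np.nan, np.nan
        out[label] = {
            "n": int(len(d_sg)),
            "mean_delta_SG": float(d_sg.mean()) if len(d_sg) else np.nan,
            "mean_delta_IS": float(d_is.mean()) if len(d_is) else np.nan,
            "t": float(t),
            "p": float(p),
        }
    return out


def trial_type_dependence(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    preference: PreferenceResult,
    direction: str = "preferred",
    equal_var: bool = True,
) -> TrialTypeResult:
    """Unpaired t-test of delay rates, SG vs IS, within one movement direction.

    Correct trials only; ``direction`` picks the neuron's preferred or
    antipreferred side from its preference sign.  The classic
    equal-variance t-test is the default; pass ``equal_var=False`` for
    Welch.  Fewer than 2 trials in either group yields a flagged
    non-significant result rather than an error.
    """
    if direction not in ("preferred", "antipreferred"):
        raise ValueError(f"bad direction {direction!r}")
    rates = epoch_rates(neuron, trials, "delay")
    sign = choice_sign(trials, neuron.hemisphere)
    want = _preferred_sign(preference) * (1 if direction == "preferred" else -1)
    ok = correct_mask(trials) & ~np.isnan(rates) & (sign == want)
    sg_rates = rates[ok & (trials["block_type"] == SG).to_numpy()]
    is_rates = rates[ok & (trials["block_type"] == IS).to_numpy()]
    if len(sg_rates) < 2 or len(is_rates) < 2:
        return TrialTypeResult(
            neuron.neuron_id, direction, np.nan, np.nan, np.nan, insufficient=True
        )
    if np.ptp(sg_rates) == 0 and np.ptp(is_rates) == 0:
        p = 1.0  # zero-variance equal samples: no evidence either way
    else:
        _, p = stats.ttest_ind(sg_rates, is_rates, equal_var=equal_var)
    return TrialTypeResult(
        neuron_id=neuron.neuron_id,
        direction=direction,
        mean_rate_SG=float(sg_rates.mean()),
        mean_rate_IS=float(is_rates.mean()),
        p_value=float(p),
    )


def population_counts(results: list[TrialTypeResult]) -> dict[str, dict]:
    """Chi-square test of the higher-IS vs higher-SG split among significant neurons.

    Goodness-of-fit against an even split, one degree of freedom, no
    continuity correction.  Computed per direction; zero significant
    neurons yields NaN statistics with a flag.
    """
    out = {}
    for direction in ("preferred", "antipreferred"):
        rs = [r for r in results if r.direction == direction]
        n_is = sum(r.klass == "higher_IS" for r in rs)
        n_sg = sum(r.klass == "higher_SG" for r in rs)
        n_sig = n_is + n_sg
        if n_sig == 0:
            out[direction] = {
                "n_tested": len(rs), "n_significant": 0, "n_higher_IS": 0,
                "n_higher_SG": 0, "chi2": np.nan, "p": np.nan, "undefined": True,
            }
            continue
        chi2 = (n_is - n_sg) ** 2 / n_sig
        out[direction] = {
            "n_tested": len(rs),
            "n_significant": n_sig,
            "n_higher_IS": n_is,
            "n_higher_SG": n_sg,
            "chi2": float(chi2),
            "p": float(stats.chi2.sf(chi2, df=1)),
            "undefined": False,
        }
    return out


def difficulty_dependence(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    direction: str,
    Fc: float,
) -> DifficultyResult:
    """One-way ANOVA of delay rates across SG mixture ratios, one direction.

    ``direction`` is ``"ipsiversive"`` or ``"contraversive"``; ``Fc`` is the
    neuron's control-window rate used to express the easy/difficult means
    as normalized change from baseline (mean delay rate / Fc).  Requires
    >= 2 mixture groups with >= 2 trials each.
    """
    if direction not in ("ipsiversive", "contraversive"):
        raise ValueError(f"bad direction {direction!r}")
    want = -1 if direction == "ipsiversive" else 1
    rates = epoch_rates(neuron, trials, "delay")
    sign = choice_sign(trials, neuron.hemisphere)
    ok = (
        (trials["block_type"] == SG).to_numpy()
        & (sign == want)
        & ~np.isnan(rates)
    )
    sub = trials.loc[ok]
    groups = [
        rates[ok][sub["left_odor_pct"].to_numpy() == mix]
        for mix in np.unique(sub["left_odor_pct"])
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError(f"{neuron.neuron_id}: fewer than 2 mixture groups with trials")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp([g.mean() for g in groups]) == 0:
        p = 1.0
    else:
        _, p = stats.f_oneway(*groups)
    easy = rates[ok][sub["left_odor_pct"].isin(EASY_MIXTURES).to_numpy()]
    diff = rates[ok][sub["left_odor_pct"].isin(DIFFICULT_MIXTURES).to_numpy()]
    return DifficultyResult(
        neuron_id=neuron.neuron_id,
        direction=direction,
        anova_p=float(p),
        mean_norm_easy=float(easy.mean() / Fc) if len(easy) else np.nan,
        mean_norm_difficult=float(diff.mean() / Fc) if len(diff) else np.nan,
    )


def cross_classification(
    difficulty_sig: list[bool], trial_type_sig: list[bool]
) -> dict[str, float]:
    """Chi-square test of proportions: difficulty dependence x trial-type dependence.

    Asks whether difficulty-dependent neurons are over-represented among
    trial-type-dependent ones (2x2 contingency, no continuity correction).
    """
    a = np.asarray(difficulty_sig, bool)
    b = np.asarray(trial_type_sig, bool)
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "n_both": int(table[0, 0]),
        "n_difficulty_only": int(table[0, 1]),
        "n_trial_type_only": int(table[1, 0]),
        "n_neither": int(table[1, 1]),
        "chi2": float(chi2),
        "p": float(p),
    }
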