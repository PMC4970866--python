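"""Direction selectivity from an ideal-observer (ROC) analysis.

For one neuron and one epoch, the ROC area measures how well an ideal
observer could tell from a single-trial firing rate whether the upcoming
movement is ipsiversive or contraversive.  Preference is defined as
``2 * (ROC_area - 0.5)``, ranging from -1 (strongest possible ipsiversive
preference) through 0 (none) to +1 (strongest contraversive preference).
Significance comes from a permutation test that shuffles the
ipsi/contra labels over trials (500 shuffles by default) and asks how often
the shuffled |preference| reaches the observed one; two-sided because
neurons of both preference signs are of interest.

The normalized response NR = Ft / Fc — delay-epoch ('test') rate over
control-window rate, averaged over preferred-direction trials — classifies
each neuron as increasing (NR > 1) or decreasing (NR < 1) during movement
selection relative to its whole-trial rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SpikeTrain, choice_sign, epoch_rates

__all__ = [
    "PreferenceResult",
    "NormalizedResponse",
    "roc_area",
    "preference_test",
    "direction_preference",
    "normalized_response",
    "preference_table",
    "epoch_preference_correlation",
]

ALPHA = 0.05
DEFAULT_N_PERM = 500


@dataclass
class PreferenceResult:
    roc_area: float
    preference: float  # 2*(roc_area - 0.5); + = contraversive, - = ipsiversive
    p_value: float
    n_perm: int
    epoch: str = "delay"

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    @property
    def category(self) -> str:
        if not self.significant:
            return "nonselective"
        return "contraversive" if self.preference > 0 else "ipsiversive"


@dataclass
class NormalizedResponse:
    Ft: float  # mean delay-epoch ('test') rate
    Fc: float  # mean control-window rate
    NR: float

    @property
    def sign_class(self) -> str:
        if self.NR > 1:
            return "increase"
        if self.NR < 1:
            return "decrease"
        return "none"


def roc_area(ipsi_rates: np.ndarray, contra_rates: np.ndarray) -> float:
    """P(contra-trial rate > ipsi-trial rate), ties counted 0.5.

    This is the Mann–Whitney U statistic scaled by the number of pairs,
    equivalently the area under the ROC curve of an ideal observer
    classifying single-trial rates; computed from pooled ranks so ties are
    handled exactly.
    """
    ipsi = np.asarray(ipsi_rates, float)
    contra = np.asarray(contra_rates, float)
    if len(ipsi) == 0 or len(contra) == 0:
        raise ValueError("roc_area needs non-empty samples for both directions")
    ranks = stats.rankdata(np.concatenate([contra, ipsi]))
    n_c, n_i = len(contra), len(ipsi)
    u = ranks[:n_c].sum() - n_c * (n_c + 1) / 2
    return float(u / (n_c * n_i))


def preference_test(
    ipsi_rates: np.ndarray,
    contra_rates: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = 0,
    epoch: str = "delay",
) -> PreferenceResult:
    """Preference 2*(ROC-0.5) with a label-shuffling permutation p-value.

    Each shuffle reassigns the pooled rates to two groups of the original
    sizes; the two-sided p-value is the add-one-corrected fraction of
    shuffles whose |preference| reaches the observed one, so p can never be
    exactly 0.  Requires >= 2 trials per direction.
    """
    ipsi = np.asarray(ipsi_rates, float)
    contra = np.asarray(contra_rates, float)
    if len(ipsi) < 2 or len(contra) < 2:
        raise ValueError("need >= 2 trials in each direction")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    auc = roc_area(ipsi, contra)
    pref = 2 * (auc - 0.5)
    # Under label permutation the pooled ranks are fixed; each shuffle just
    # re-draws which ranks land in the contra group.
    ranks = stats.rankdata(np.concatenate([contra, ipsi]))
    n_c, n_i = len(contra), len(ipsi)
    perm_ranks = rng.permuted(
        np.broadcast_to(ranks, (n_perm, len(ranks))).copy(), axis=1
    )
    perm_u = perm_ranks[:, :n_c].sum(axis=1) - n_c * (n_c + 1) / 2
    perm_pref = 2 * (perm_u / (n_c * n_i) - 0.5)
    p = (1 + np.sum(np.abs(perm_pref) >= abs(pref) - 1e-12)) / (1 + n_perm)
    return PreferenceResult(
        roc_area=auc, preference=pref, p_value=float(p), n_perm=n_perm, epoch=epoch
    )


def direction_preference(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    epoch: str = "delay",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator | None = 0,
) -> PreferenceResult:
    """ROC/permutation direction preference of one neuron in one epoch.

    ``trials`` should already be trial-filtered; choices map to
    ipsi/contra through the neuron's hemisphere.  No-choice trials are
    ignored.
    """
    rates = epoch_rates(neuron, trials, epoch)
    sign = choice_sign(trials, neuron.hemisphere)
    ok = ~np.isnan(rates)
    return preference_test(
        rates[ok & (sign == -1)], rates[ok & (sign == 1)], n_perm=n_perm, seed=seed, epoch=epoch
    )


def normalized_response(
    neuron: SpikeTrain,
    trials: pd.DataFrame,
    preference: PreferenceResult | None = None,
) -> NormalizedResponse:
    """NR = Ft/Fc over trials in the neuron's preferred direction.

    For a neuron with no significant direction preference (or when no
    preference result is supplied), all choice trials are used.  Raises if
    Fc is zero — such a neuron fails the 2.5 sp/s inclusion rule anyway.
    """
    sign = choice_sign(trials, neuron.hemisphere)
    mask = sign != 0
    if preference is not None and preference.significant:
        mask = sign == (1 if preference.preference > 0 else -1)
    sub = trials.loc[mask]
    Ft = float(np.nanmean(epoch_rates(neuron, sub, "delay")))
    Fc = float(np.nanmean(epoch_rates(neuron, sub, "control")))
    if Fc == 0:
        raise ValueError("control-window rate is zero; neuron should have been excluded")
    return NormalizedResponse(Ft=Ft, Fc=Fc, NR=Ft / Fc)


def preference_table(
    results: list[tuple[PreferenceResult, NormalizedResponse]]
) -> pd.DataFrame:
    """Contingency table of preference category x sign of activity change.

    Rows contraversive / ipsiversive / nonselective, columns increase /
    decrease, plus Total margins and percent-of-grand-total companions.
    Neurons with no activity change (NR exactly 1) are excluded from the
    table, mirroring how such neurons are tabulated separately.
    """
    rows = ["contraversive", "ipsiversive", "nonselective"]
    cols = ["increase", "decrease"]
    counts = pd.DataFrame(0, index=rows + ["Total"], columns=cols + ["Total"])
    for pref, nr in results:
        if nr.sign_class == "none":
            continue
        counts.loc[pref.category, nr.sign_class] += 1
    counts.loc["Total", cols] = counts.loc[rows, cols].sum(axis=0)
    counts["Total"] = counts[cols].sum(axis=1)
    grand = counts.loc["Total", "Total"]
    pct = 100 * counts / grand if grand else counts * np.nan
    return pd.concat({"n": counts, "pct": pct}, axis=1)


def epoch_preference_correlation(
    per_neuron: list[dict[str, float]] | pd.DataFrame,
) -> tuple[float, float]:
    """Correlate trial-type preference differences across two epochs.

    Input: per neuron, the direction preferences computed separately on SG
    and IS trials in the delay and pre-stimulus epochs (keys
    ``pref_sg_delay``, ``pref_is_delay``, ``pref_sg_pre_stim``,
    ``pref_is_pre_stim``).  Returns the Pearson r (with t-distribution p)
    between (IS - SG) preference in the delay epoch and the same difference
    in the pre-stimulus epoch — a positive r says neurons whose direction
    signal is IS-enhanced before the stimulus keep that enhancement while
    the movement is being selected.
    """
    df = pd.DataFrame(per_neuron)
    if len(df) < 3:
        raise ValueError("need at least 3 neurons")
    d_delay = df["pref_is_delay"] - df["pref_sg_delay"]
    d_pre = df["pref_is_pre_stim"] - df["pref_sg_pre_stim"]
    r, p = stats.pearsonr(d_delay, d_pre)
    return float(r), float(p)
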