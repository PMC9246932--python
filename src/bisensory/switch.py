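"""Modality switch effects (MSEs) and race-model tests on switch/repeat trials.

The MSE is the area between the repeat- and switch-trial CDFs of a condition
(positive when switching slows responses); a mean-RT variant reports the
switch-minus-repeat difference in milliseconds. AV switch trials may be kept
separate by preceding modality (A->AV vs V->AV) and normalised by the pooled
V/A->AV effect for comparison across groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdf import ConditionedCDFSet, QuantileCDF, check_shared_times, condition_subsets, _prev_columns
from .race import auc, race_outcome


@dataclass
class MSEResult:
    condition: str      # "V->A", "A->V", "V/A->AV", "A->AV", "V->AV"
    mse_auc: float
    normalised: float | None = None
    degenerate: bool = False


def mse(f_repeat: QuantileCDF, f_switch: QuantileCDF) -> float:
    """AUC of (F_repeat - F_switch) over the unit quantile interval."""
    check_shared_times(f_repeat, f_switch)
    return auc(f_repeat.probs - f_switch.probs)


def mse_by_condition(cdfset: ConditionedCDFSet,
                     normalise: bool = False) -> list[MSEResult]:
    """MSEs for V->A, A->V, pooled V/A->AV, and separated A->AV / V->AV.

    The separated AV effects are optionally normalised by the pooled AV MSE
    (undefined and flagged when that reference is zero). Degenerate strata
    propagate their flag.
    """
    out = []

    def get(d, key):
        q = d.get(key)
        return q, (q is None or q.degenerate)

    pooled_val = None
    pairs = [("V->A", *get(cdfset.repeat, "A"), *get(cdfset.switch, "A")),
             ("A->V", *get(cdfset.repeat, "V"), *get(cdfset.switch, "V")),
             ("V/A->AV", *get(cdfset.repeat, "AV"), *get(cdfset.switch, "AV")),
             ("A->AV", *get(cdfset.repeat, "AV"), *get(cdfset.av_switch_from, "A")),
             ("V->AV", *get(cdfset.repeat, "AV"), *get(cdfset.av_switch_from, "V"))]
    for label, rep, rep_bad, sw, sw_bad in pairs:
        if rep is None or sw is None:
            out.append(MSEResult(label, np.nan, degenerate=True))
            continue
        val = mse(rep, sw)
        res = MSEResult(label, val, degenerate=rep_bad or sw_bad)
        if label == "V/A->AV":
            pooled_val = val
        out.append(res)

    if normalise:
        for res in out:
            if res.condition in ("A->AV", "V->AV"):
                if pooled_val is None or pooled_val == 0 or np.isnan(pooled_val):
                    warnings.warn("pooled AV MSE is zero/undefined; normalised "
                                  "values flagged", stacklevel=2)
                    res.degenerate = True
                else:
                    res.normalised = res.mse_auc / pooled_val
    return out


def mse_mean_rt(trials: pd.DataFrame,
                isi_window_ms: tuple[float, float] | None = None,
                conditions: tuple[str, ...] = ("A", "V")) -> float:
    """Mean-RT switch cost in ms: mean(switch RTs) - mean(repeat RTs).

    Computed over unisensory conditions by default (AV->A / AV->V trials are
    neither switches nor repeats and are excluded). ``isi_window_ms``
    restricts trials by their preceding ISI.
    """
    t = _prev_columns(trials)
    t = t[t["rt_ms"].notna() & t["condition"].isin(conditions)
          & t["prev_condition"].isin(["A", "V"])]
    if isi_window_ms is not None:
        lo, hi = isi_window_ms
        t = t[(t["isi_ms"] >= lo) & (t["isi_ms"] <= hi)]
    rep = t[t["prev_condition"] == t["condition"]]["rt_ms"]
    sw = t[t["prev_condition"] != t["condition"]]["rt_ms"]
    if len(rep) == 0 or len(sw) == 0:
        raise ValueError("empty switch or repeat subset")
    return float(sw.mean() - rep.mean())


def race_by_switch(trials: pd.DataFrame,
                   limits: tuple[float, float] | None = None,
                   min_trials: int = 10) -> tuple[float, float] | None:
    """Multisensory gain computed separately within switch and repeat trials.

    Each partition gets its own full race pipeline (conditioned race where
    strata permit, else the unconditioned fallback built into
    ``conditioned_race``). Both partitions share the subject's pooled
    evaluation grid so the two gains are comparable. Returns
    (gain_switch, gain_repeat), or None (with a warning) when a partition is
    below the minimum trial count.
    """
    t = _prev_columns(trials)
    t = t[t["rt_ms"].notna()]
    classifiable = t["prev_condition"].isin(["A", "V", "AV"])
    is_repeat = classifiable & (t["prev_condition"] == t["condition"])
    # AV->A / AV->V are neither switch nor repeat
    is_switch = classifiable & ~is_repeat & ~(
        (t["prev_condition"] == "AV") & (t["condition"] != "AV"))

    if limits is None:
        from .cdf import pooled_percentile_limits
        limits = pooled_percentile_limits(
            {c: t.loc[t["condition"] == c, "rt_ms"].to_numpy()
             for c in ("A", "V", "AV")})

    gains = []
    for mask, label in ((is_switch, "switch"), (is_repeat, "repeat")):
        part = t[mask]
        counts = part["condition"].value_counts()
        if any(counts.get(c, 0) < min_trials for c in ("A", "V", "AV")):
            warnings.warn(f"{label} partition below {min_trials} trials per "
                          "condition; subject omitted", stacklevel=2)
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cdfset = condition_subsets(part, limits=limits)
        gains.append(race_outcome(cdfset).gain)
    return gains[0], gains[1]


def mse_table(per_subject: dict[str, list[MSEResult]]) -> pd.DataFrame:
    rows = []
    for sid, results in per_subject.items():
        for r in results:
            rows.append({"subject_id": sid, "condition": r.condition,
                         "mse_auc": r.mse_auc, "normalised": r.normalised,
                         "degenerate": r.degenerate})
    return pd.DataFrame(rows)
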