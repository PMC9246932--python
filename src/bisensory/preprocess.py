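"""Detection-accuracy scoring, participant exclusion, and RT cleaning.

Accuracy is the F1 score (harmonic mean of precision and recall), which
penalises both misses and excessive button pressing. Participants are
excluded on seven criteria (age range, performance IQ, accuracy 3 SD below
the cohort mean, false-alarm excess, modality-imbalanced hits, out-of-range
ISIs, too few RTs per condition). Trial-level cleaning removes double
presses, the first three trials of each block (training), out-of-range ISIs,
RTs outside the 100-2000 ms response window, and finally per-condition RTs
outside the middle 95 percent of their condition's distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONDITIONS

RT_WINDOW_MS = (100.0, 2000.0)
ISI_RANGE_MS = (1000.0, 3000.0)
TRAINING_TRIALS = 3
PCT_TRIM = (2.5, 97.5)
MIN_RTS_PER_CONDITION = 20
AGE_RANGE = (6.0, 40.0)
MIN_PIQ = 80.0
MAX_FA_PROPORTION = 0.65


@dataclass
class AccuracySummary:
    f1: float
    precision: float
    recall: float
    fa_rate: float
    miss_rate: float


@dataclass
class ExclusionReport:
    subject_id: str
    excluded: bool
    reasons: list[str] = field(default_factory=list)


def score_accuracy(trials: pd.DataFrame, fa_count: int = 0) -> AccuracySummary:
    """F1 accuracy from a subject's stimulus trials plus a false-alarm count.

    Hits are stimulus trials with at least one response; rates are reported
    as proportions of the total trial count.
    """
    n = len(trials)
    if n == 0:
        raise ValueError("no stimulus trials")
    responded = trials["n_presses"] >= 1 if "n_presses" in trials \
        else trials["rt_ms"].notna()
    hits = int(responded.sum())
    misses = n - hits
    recall = hits / (hits + misses)
    precision = hits / (hits + fa_count) if hits + fa_count > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return AccuracySummary(f1=f1, precision=precision, recall=recall,
                           fa_rate=fa_count / n, miss_rate=misses / n)


def summarise_subject(subject_row: pd.Series, trials: pd.DataFrame,
                      cleaned: pd.DataFrame | None = None) -> dict:
    """Per-subject facts the exclusion criteria consume."""
    acc = score_accuracy(trials, int(subject_row.get("fa_count", 0)))
    responded = trials["n_presses"] >= 1
    hits_by_cond = {c: int((responded & (trials["condition"] == c)).sum())
                    for c in CONDITIONS}
    rt_source = cleaned if cleaned is not None else trials[trials["rt_ms"].notna()]
    n_rts = {c: int((rt_source["condition"] == c).sum()) for c in CONDITIONS}
    return {
        "subject_id": subject_row["subject_id"],
        "age_years": float(subject_row["age_years"]),
        "piq": float(subject_row["piq"]) if pd.notna(subject_row.get("piq")) else np.nan,
        "accuracy": acc,
        "hits_A": hits_by_cond["A"], "hits_V": hits_by_cond["V"],
        "isi_min": float(trials["isi_ms"].min()),
        "isi_max": float(trials["isi_ms"].max()),
        "n_rts": n_rts,
    }


def apply_exclusions(summaries: list[dict],
                     accuracy_mean: float | None = None,
                     accuracy_sd: float | None = None,
                     isi_tolerance_ms: float = 1.0) -> list[ExclusionReport]:
    """Flag the seven participant-level exclusion criteria.

    The accuracy threshold (3 SD below the cohort mean) is evaluated on the
    candidate pool given here, before any RT-based exclusion, unless explicit
    cohort statistics are supplied.
    """
    f1s = np.array([s["accuracy"].f1 for s in summaries])
    mu = float(np.mean(f1s)) if accuracy_mean is None else accuracy_mean
    sd = float(np.std(f1s, ddof=1)) if accuracy_sd is None else accuracy_sd
    thresh = mu - 3 * sd

    reports = []
    for s in summaries:
        reasons = []
        if not AGE_RANGE[0] <= s["age_years"] <= AGE_RANGE[1]:
            reasons.append("age-range")
        if np.isnan(s["piq"]) or s["piq"] < MIN_PIQ:
            reasons.append("piq")
        if s["accuracy"].f1 < thresh:
            reasons.append("accuracy-3sd")
        if s["accuracy"].fa_rate > MAX_FA_PROPORTION:
            reasons.append("fa-excess")
        ha, hv = s["hits_A"], s["hits_V"]
        if min(ha, hv) < 0.5 * max(ha, hv):
            reasons.append("modality-imbalance")
        if (s["isi_min"] < ISI_RANGE_MS[0] - isi_tolerance_ms
                or s["isi_max"] > ISI_RANGE_MS[1] + isi_tolerance_ms):
            reasons.append("isi-range")
        if min(s["n_rts"].values()) < MIN_RTS_PER_CONDITION:
            reasons.append("min-rts")
        reports.append(ExclusionReport(s["subject_id"], bool(reasons), reasons))
    return reports


@dataclass
class CleaningReport:
    n_input: int
    n_output: int
    fast_outlier_fraction: float
    slow_outlier_fraction: float
    percentile_limits: dict[str, tuple[float, float]]


def clean_rts(trials: pd.DataFrame,
              percentile_limits: dict[str, tuple[float, float]] | None = None,
              ) -> tuple[pd.DataFrame, CleaningReport]:
    """Trial-level cleaning for one subject; returns (cleaned, report).

    Steps, in order: drop double presses; drop the first three trials of each
    block; drop trials with out-of-range ISIs; drop misses; drop RTs outside
    the 100-2000 ms window (fractions reported); drop per-condition RTs
    strictly outside that condition's 2.5-97.5 percentile interval (linear
    interpolation; boundary values retained, so re-cleaning with the
    reported limits is the identity).
    """
    t = trials.copy()
    n0 = len(t)
    if "n_presses" in t:
        t = t[t["n_presses"] <= 1]
    t = t[t["trial_idx"] >= TRAINING_TRIALS]
    t = t[(t["isi_ms"] >= ISI_RANGE_MS[0]) & (t["isi_ms"] <= ISI_RANGE_MS[1])]
    t = t[t["rt_ms"].notna()]

    n_win = len(t)
    fast = (t["rt_ms"] < RT_WINDOW_MS[0]).sum()
    slow = (t["rt_ms"] > RT_WINDOW_MS[1]).sum()
    t = t[(t["rt_ms"] >= RT_WINDOW_MS[0]) & (t["rt_ms"] <= RT_WINDOW_MS[1])]

    limits_out = {}
    keep = pd.Series(True, index=t.index)
    for c in t["condition"].unique():
        sel = t["condition"] == c
        rts = t.loc[sel, "rt_ms"].to_numpy()
        if percentile_limits is not None and c in percentile_limits:
            lo, hi = percentile_limits[c]
        elif len(rts) < 2:
            warnings.warn(f"condition {c!r}: < 2 RTs, percentile trim skipped",
                          stacklevel=2)
            limits_out[c] = (float("nan"), float("nan"))
            continue
        else:
            lo, hi = np.percentile(rts, PCT_TRIM)
        limits_out[c] = (float(lo), float(hi))
        keep &= ~sel | ((t["rt_ms"] >= lo) & (t["rt_ms"] <= hi))
    t = t[keep]

    report = CleaningReport(
        n_input=n0, n_output=len(t),
        fast_outlier_fraction=fast / n_win if n_win else 0.0,
        slow_outlier_fraction=slow / n_win if n_win else 0.0,
        percentile_limits=limits_out)
    return t, report


def clean_cohort(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply ``clean_rts`` per subject; returns (cleaned trials, reports)."""
    cleaned, reports = [], {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        ct, rep = clean_rts(sub)
        cleaned.append(ct)
        reports[sid] = rep
    return pd.concat(cleaned, ignore_index=False), reports
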