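"""Quantile-indexed empirical CDFs and conditioned (sequence-aware) subsets.

RT distributions are summarised as cumulative probabilities evaluated at 20
linearly spaced latencies between pooled 2.5/97.5 percentile cutoffs shared by
all three conditions ("vertical" CDFs: no interpolation to the time axis, so
unequal trial counts across conditions are fine). Conditioned subsets split
each condition's RTs by the preceding stimulus modality and into switch vs
repeat trials; unisensory trials preceded by AV count as neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONDITIONS

N_QUANTILES = 20
#: strata below this trial count are flagged degenerate
MIN_STRATUM_N = 5


@dataclass
class QuantileCDF:
    """Cumulative response probabilities at linearly spaced latencies."""

    probs: np.ndarray
    eval_times_ms: np.ndarray
    lo_ms: float
    hi_ms: float
    n_rts: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.eval_times_ms = np.asarray(self.eval_times_ms, dtype=float)
        if len(self.probs) != len(self.eval_times_ms):
            raise ValueError("probs and eval_times_ms must have equal length")

    @property
    def degenerate(self) -> bool:
        return self.n_rts < MIN_STRATUM_N


def check_shared_times(*cdfs: QuantileCDF) -> np.ndarray:
    times = cdfs[0].eval_times_ms
    for c in cdfs[1:]:
        if not np.array_equal(c.eval_times_ms, times):
            raise ValueError("CDFs must share identical evaluation times")
    return times


def pooled_percentile_limits(rts_by_condition: dict[str, np.ndarray],
                             lo_pct: float = 2.5,
                             hi_pct: float = 97.5) -> tuple[float, float]:
    """Pooled cutoffs: min of per-condition 2.5th / max of 97.5th percentiles.

    Using one shared window for all conditions preserves the relationship
    between their CDFs.
    """
    los, his = [], []
    for cond, rts in rts_by_condition.items():
        rts = np.asarray(rts, dtype=float)
        if len(rts) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 RTs")
        los.append(np.percentile(rts, lo_pct))
        his.append(np.percentile(rts, hi_pct))
    lo, hi = float(min(los)), float(max(his))
    if lo >= hi:
        raise ValueError("degenerate limits: lo >= hi")
    return lo, hi


def empirical_cdf(rts: np.ndarray, limits: tuple[float, float],
                  n_q: int = N_QUANTILES) -> QuantileCDF:
    """P(RT <= t_k) at ``n_q`` linearly spaced t_k on [lo, hi] (ties count <=)."""
    rts = np.asarray(rts, dtype=float)
    if len(rts) == 0:
        raise ValueError("empty RT sample")
    lo, hi = limits
    if not lo < hi:
        raise ValueError("invalid limits")
    t = np.linspace(lo, hi, n_q)
    probs = (rts[:, None] <= t[None, :]).mean(axis=0)
    return QuantileCDF(probs, t, lo, hi, len(rts))


@dataclass
class ConditionedCDFSet:
    """All CDFs one subject's models consume, on one shared time grid.

    ``by_prev[(cond, m)]`` conditions on the preceding stimulus modality m;
    ``switch``/``repeat`` partition each condition by modality transition with
    the two AV switch directions pooled; ``av_switch_from`` keeps them
    separate.  Strata with fewer than ``MIN_STRATUM_N`` RTs are flagged via
    ``QuantileCDF.degenerate`` and recorded in ``degenerate_keys``.
    """

    eval_times_ms: np.ndarray
    lo_ms: float
    hi_ms: float
    full: dict[str, QuantileCDF]
    by_prev: dict[tuple[str, str], QuantileCDF] = field(default_factory=dict)
    switch: dict[str, QuantileCDF] = field(default_factory=dict)
    repeat: dict[str, QuantileCDF] = field(default_factory=dict)
    av_switch_from: dict[str, QuantileCDF] = field(default_factory=dict)
    degenerate_keys: list = field(default_factory=list)


def _prev_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Ensure preceding-modality annotation exists (within-block only)."""
    if "prev_condition" in trials.columns:
        return trials
    trials = trials.sort_values(["block", "trial_idx"]).copy()
    prev = trials.groupby("block")["condition"].shift(1)
    trials["prev_condition"] = prev.fillna("")
    resp = (trials["n_presses"] == 1) if "n_presses" in trials else trials["rt_ms"].notna()
    prev_resp = resp.groupby(trials["block"]).shift(1)
    trials["prev_responded"] = prev_resp.notna() & prev_resp.eq(True)
    return trials


def condition_subsets(trials: pd.DataFrame,
                      limits: tuple[float, float] | None = None,
                      n_q: int = N_QUANTILES,
                      min_count: int = MIN_STRATUM_N) -> ConditionedCDFSet:
    """Build the full/preceding-modality/switch-repeat CDF set for one subject.

    ``trials`` must be cleaned single-subject rows with valid ``rt_ms``;
    preceding modality is taken from the pre-cleaning annotation when present
    (stimulus sequence within block), else recomputed from the rows given.
    Trials whose predecessor drew no valid response are excluded from the
    preceding-modality strata.
    """
    trials = _prev_columns(trials)
    trials = trials[trials["rt_ms"].notna()]
    rts_by_cond = {c: trials.loc[trials["condition"] == c, "rt_ms"].to_numpy()
                   for c in CONDITIONS}
    for c, r in rts_by_cond.items():
        if len(r) == 0:
            raise ValueError(f"no RTs in condition {c!r}")
    if limits is None:
        limits = pooled_percentile_limits(rts_by_cond)
    lo, hi = limits

    def cdf(rts):
        if len(rts) == 0:
            return None
        return empirical_cdf(rts, (lo, hi), n_q)

    out = ConditionedCDFSet(
        eval_times_ms=np.linspace(lo, hi, n_q), lo_ms=lo, hi_ms=hi,
        full={c: cdf(rts_by_cond[c]) for c in CONDITIONS})

    ok_prev = trials["prev_responded"].astype(bool) & (trials["prev_condition"] != "")
    strat = trials[ok_prev]
    for c in CONDITIONS:
        for m in CONDITIONS:
            sub = strat[(strat["condition"] == c) & (strat["prev_condition"] == m)]
            q = cdf(sub["rt_ms"].to_numpy())
            if q is None or q.n_rts < min_count:
                out.degenerate_keys.append((c, m))
                if q is None:
                    continue
            out.by_prev[(c, m)] = q

    def put(d, key, sub):
        q = cdf(sub["rt_ms"].to_numpy())
        if q is None or q.n_rts < min_count:
            out.degenerate_keys.append(("sr", key))
            if q is None:
                return
        d[key] = q

    for c in ("A", "V"):
        other = "V" if c == "A" else "A"
        sel = strat["condition"] == c
        put(out.repeat, c, strat[sel & (strat["prev_condition"] == c)])
        put(out.switch, c, strat[sel & (strat["prev_condition"] == other)])
        # AV -> unisensory is neither a switch nor a repeat: excluded
    sel = strat["condition"] == "AV"
    put(out.repeat, "AV", strat[sel & (strat["prev_condition"] == "AV")])
    put(out.switch, "AV", strat[sel & strat["prev_condition"].isin(["A", "V"])])
    for m in ("A", "V"):
        put(out.av_switch_from, m, strat[sel & (strat["prev_condition"] == m)])

    if out.degenerate_keys:
        warnings.warn(f"degenerate strata (n < {min_count}): "
                      f"{sorted(set(map(str, out.degenerate_keys)))[:6]}...",
                      stacklevel=2)
    return out


def cdf_long_table(subject_id: str, cdfset: ConditionedCDFSet) -> pd.DataFrame:
    """Serialise a CDF set to the delimited long format."""
    rows = []

    def add(cond, stratum, q):
        if q is None:
            return
        for k, (t, p) in enumerate(zip(q.eval_times_ms, q.probs)):
            rows.append((subject_id, cond, stratum, k, t, p))

    for c, q in cdfset.full.items():
        add(c, "all", q)
    for (c, m), q in cdfset.by_prev.items():
        add(c, f"prev={m}", q)
    for c, q in cdfset.switch.items():
        add(c, "switch", q)
    for c, q in cdfset.repeat.items():
        add(c, "repeat", q)
    return pd.DataFrame(rows, columns=["subject", "condition", "stratum",
                                       "t_index", "t_ms", "prob"])
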