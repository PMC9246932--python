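"""Race-model statistics: Raab's independent race, its preceding-modality
conditioned variant, Grice/Miller bounds, benefit and gain AUCs, and
per-quantile race-model violation tests.

All areas are taken over the unit quantile interval and computed as the
arithmetic mean of the per-quantile differences (rectangle rule on the 20
equally spaced quantiles), so ``gain = benefit_emp - benefit_pred`` holds as
an exact algebraic identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdf import ConditionedCDFSet, QuantileCDF, check_shared_times
from .cohort import CONDITIONS


def _like(template: QuantileCDF, probs: np.ndarray) -> QuantileCDF:
    return QuantileCDF(probs, template.eval_times_ms, template.lo_ms,
                       template.hi_ms, template.n_rts)


def raab_race(f_a: QuantileCDF, f_v: QuantileCDF) -> QuantileCDF:
    """Independent race: F_A + F_V - F_A * F_V (probability summation)."""
    check_shared_times(f_a, f_v)
    probs = f_a.probs + f_v.probs - f_a.probs * f_v.probs
    return _like(f_a, probs)


def conditioned_race(cdfset: ConditionedCDFSet) -> QuantileCDF:
    """Race model averaged over preceding-modality strata.

    For each preceding modality m in {A, V, AV}, the race of the unisensory
    CDFs conditioned on m, then the unweighted mean of the three. A
    degenerate stratum's unisensory CDF falls back to the unconditioned one
    (logged on the CDF set); if every stratum is degenerate the estimate
    equals the unconditioned race.
    """
    terms = []
    n_fallback = 0
    for m in CONDITIONS:
        fa = cdfset.by_prev.get(("A", m))
        fv = cdfset.by_prev.get(("V", m))
        if fa is None or fa.degenerate:
            fa = cdfset.full["A"]
            n_fallback += 1
        if fv is None or fv.degenerate:
            fv = cdfset.full["V"]
            n_fallback += 1
        terms.append(raab_race(fa, fv).probs)
    if n_fallback == 2 * len(CONDITIONS):
        raise ValueError("all preceding-modality strata are degenerate or missing")
    probs = np.mean(terms, axis=0)
    template = cdfset.full["A"]
    return _like(template, probs)


def bounds(f_a: QuantileCDF, f_v: QuantileCDF) -> tuple[QuantileCDF, QuantileCDF]:
    """(Grice lower bound, Miller upper bound) of statistical facilitation."""
    check_shared_times(f_a, f_v)
    grice = _like(f_a, np.maximum(f_a.probs, f_v.probs))
    miller = _like(f_a, np.minimum(f_a.probs + f_v.probs, 1.0))
    return grice, miller


def auc(diff: np.ndarray) -> float:
    """Area over the unit quantile interval: mean per-quantile difference."""
    return float(np.mean(diff))


def benefits(f_av: QuantileCDF, race: QuantileCDF,
             grice: QuantileCDF) -> tuple[float, float]:
    """(predicted, empirical) multisensory benefit relative to Grice's bound."""
    check_shared_times(f_av, race, grice)
    return auc(race.probs - grice.probs), auc(f_av.probs - grice.probs)


def multisensory_gain(f_av: QuantileCDF, race: QuantileCDF
                      ) -> tuple[float, np.ndarray, float, float]:
    """Gain = AUC of (F_AV - race); also the signed difference function and
    its positive/negative parts (gain = auc_pos + auc_neg)."""
    check_shared_times(f_av, race)
    diff = f_av.probs - race.probs
    pos = np.where(diff > 0, diff, 0.0)
    neg = np.where(diff < 0, diff, 0.0)
    return auc(diff), diff, auc(pos), auc(neg)


@dataclass
class RaceOutcome:
    """Per-subject race-model summary."""

    race_cdf: QuantileCDF
    grice_cdf: QuantileCDF
    miller_cdf: QuantileCDF
    diff_fn: np.ndarray
    benefit_pred: float
    benefit_emp: float
    gain: float
    auc_pos: float
    auc_neg: float
    conditioned: bool


def race_outcome(cdfset: ConditionedCDFSet, conditioned: bool = True) -> RaceOutcome:
    """Run the full benefit/gain pipeline on one subject's CDF set."""
    f_a, f_v, f_av = (cdfset.full[c] for c in CONDITIONS)
    grice, miller = bounds(f_a, f_v)
    race = conditioned_race(cdfset) if conditioned else raab_race(f_a, f_v)
    b_pred, b_emp = benefits(f_av, race, grice)
    gain, diff, a_pos, a_neg = multisensory_gain(f_av, race)
    return RaceOutcome(race, grice, miller, diff, b_pred, b_emp, gain,
                       a_pos, a_neg, conditioned)


def race_violation_test(diff_fns: np.ndarray, tail: str = "right",
                        n_perm: int = 10000, seed=None):
    """Per-quantile one-sample permutation test of race-model violation.

    ``diff_fns`` is (n_subjects, n_quantiles); sign-flip permutation with
    max-statistic familywise correction across quantiles. Returns the
    ``StatResult`` from the inference layer.
    """
    from .stats import permutation_test

    diff_fns = np.atleast_2d(np.asarray(diff_fns, dtype=float))
    if diff_fns.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    return permutation_test(diff_fns, tail=tail, n_perm=n_perm,
                            correction="tmax", seed=seed)


def race_table(outcomes: dict[str, RaceOutcome]) -> pd.DataFrame:
    """Export per-subject race outcomes as a flat results table."""
    rows = []
    for sid, o in outcomes.items():
        row = {"subject_id": sid, "benefit_pred": o.benefit_pred,
               "benefit_emp": o.benefit_emp, "gain": o.gain,
               "auc_pos": o.auc_pos, "auc_neg": o.auc_neg,
               "conditioned": o.conditioned}
        row.update({f"diff_q{k + 1}": v for k, v in enumerate(o.diff_fn)})
        rows.append(row)
    return pd.DataFrame(rows)
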