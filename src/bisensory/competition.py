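"""Competition bias models and the facilitation-competition mixture.

Under a competitive account, the redundant (AV) response is triggered by a
single biased channel rather than by the faster of the two. Model 1 biases a
fixed modality b (auditory: 1A, visual: 1V); Model 2 biases the previous
trial's modality, defaulting to b when the previous trial was AV. Each model
predicts an AV CDF from the preceding-modality-conditioned unisensory CDFs,
and a mixture parameter p interpolates linearly between the conditioned race
model (p = 0, pure facilitation) and the bias model (p = 1, pure
competition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdf import ConditionedCDFSet, QuantileCDF, check_shared_times
from .cohort import CONDITIONS
from .race import _like, auc

P_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
AGE_GROUP_BINS = ((6, 9), (10, 12), (13, 17), (18, 40))


@dataclass(frozen=True)
class BiasModelSpec:
    family: str          # "model1" | "model2"
    bias_modality: str   # "A" | "V"

    def __post_init__(self):
        if self.family not in ("model1", "model2"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.bias_modality not in ("A", "V"):
            raise ValueError(f"bias modality must be A or V")

    @property
    def label(self) -> str:
        return f"{self.family}{self.bias_modality}"


ALL_SPECS = tuple(BiasModelSpec(f, b) for f in ("model1", "model2")
                  for b in ("A", "V"))


def _stratum(cdfset: ConditionedCDFSet, cond: str, m: str) -> QuantileCDF:
    q = cdfset.by_prev.get((cond, m))
    if q is None or q.degenerate:
        q = cdfset.full[cond]   # documented degenerate-stratum fallback
    return q


def bias_model_cdf(spec: BiasModelSpec, cdfset: ConditionedCDFSet) -> QuantileCDF:
    """Predicted AV CDF under a competition bias model.

    model1: mean over preceding modalities m of F_b(m, .);
    model2: (F_A(A, .) + F_V(V, .) + F_b(AV, .)) / 3.
    """
    b = spec.bias_modality
    if spec.family == "model1":
        terms = [_stratum(cdfset, b, m).probs for m in CONDITIONS]
    else:
        terms = [_stratum(cdfset, "A", "A").probs,
                 _stratum(cdfset, "V", "V").probs,
                 _stratum(cdfset, b, "AV").probs]
    return _like(cdfset.full["A"], np.mean(terms, axis=0))


def mixture_benefit(p: float, race: QuantileCDF, bias: QuantileCDF,
                    grice: QuantileCDF) -> float:
    """Benefit of the p-mixture of race (facilitative) and bias (competitive)
    models relative to Grice's bound; affine in p by construction."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    check_shared_times(race, bias, grice)
    mix = (1.0 - p) * race.probs + p * bias.probs
    return auc(mix - grice.probs)


def assign_age_group(age: float) -> str:
    for lo, hi in AGE_GROUP_BINS:
        if lo <= int(age) <= hi:
            return f"{lo}-{hi}"
    return "other"


def benefit_grid(per_subject: dict[str, dict], p_grid=P_GRID) -> pd.DataFrame:
    """Mixture benefits for every (spec, p) per subject.

    ``per_subject`` maps subject_id to a dict with keys ``race``, ``grice``
    (QuantileCDFs), ``bias`` (dict spec label -> QuantileCDF) and
    ``benefit_emp``.
    """
    rows = []
    for sid, d in per_subject.items():
        for spec in ALL_SPECS:
            bias = d["bias"][spec.label]
            for p in p_grid:
                rows.append({
                    "subject_id": sid, "family": spec.family,
                    "bias": spec.bias_modality, "model": spec.label, "p": p,
                    "benefit_ib": mixture_benefit(p, d["race"], bias, d["grice"]),
                    "benefit_emp": d["benefit_emp"],
                })
    return pd.DataFrame(rows)


def _perm_corr_p(x: np.ndarray, y: np.ndarray, n_perm: int, seed) -> float:
    rng = np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r) >= r_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def evaluate_models(grid: pd.DataFrame, ages: pd.Series,
                    n_perm: int = 10000, seed=None) -> pd.DataFrame:
    """Pearson r between model-predicted and empirical benefits, by age group.

    One row per (age group, model, p); significance by two-tailed permutation
    of subject pairings. Groups with < 3 subjects, or constant predictions,
    are omitted with a warning.
    """
    grid = grid.copy()
    grid["age_group"] = grid["subject_id"].map(ages.map(assign_age_group)
                                               if isinstance(ages, pd.Series) else ages)
    rows = []
    for (group, model, p), sub in grid.groupby(["age_group", "model", "p"]):
        x = sub["benefit_ib"].to_numpy()
        y = sub["benefit_emp"].to_numpy()
        if len(x) < 3:
            warnings.warn(f"group {group}: < 3 subjects, r omitted", stacklevel=2)
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"group {group} {model} p={p}: constant benefits, "
                          "r undefined", stacklevel=2)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        p_perm = (_perm_corr_p(x, y, n_perm, seed)
                  if n_perm else np.nan)
        rows.append({"group": group, "family": model[:-1], "bias": model[-1],
                     "model": model, "p": p, "r": r, "p_perm": p_perm,
                     "n": len(x)})
    return pd.DataFrame(rows)


def sensory_dominance(grid: pd.DataFrame, ages,
                      n_perm: int = 10000, seed=None) -> pd.DataFrame:
    """Fixed-modality bias models at p = 1: the sensory-dominance profiles."""
    sub = grid[(grid["p"] == 1.0) & grid["model"].isin(["model1A", "model1V"])]
    return evaluate_models(sub, ages, n_perm=n_perm, seed=seed)
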