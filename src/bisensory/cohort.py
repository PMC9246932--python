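"""Synthetic cohort generator for a speeded bisensory (A/V/AV) detection task.

Emulates the trial and response-time structure the downstream analyses
assume: three equiprobable stimulus conditions in random order, interstimulus
intervals uniform on 1000-3000 ms, blocked presentation, unisensory RTs whose
reciprocals are approximately normal (LATER-style rate model), trial-to-trial
channel correlation on redundant trials, rate-scale switch costs on modality
transitions, and optional competition regimes in which the redundant response
is triggered by a single biased channel.

Rates are expressed in 1/s such that ``rt_ms = 1000 / rate``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("A", "V", "AV")
GROUPS = ("NT", "ASD")
COMPETITION_MODES = ("none", "model1A", "model1V", "model2A", "model2V")

#: Age-linear LATER rate parameters per diagnostic group. Rates grow with age
#: (children respond slower) up to ``age_cap``; the visual channel is slower
#: than the auditory one, and the ASD group carries a small rate decrement.
DEFAULT_CHANNEL_PARAMS: dict[str, dict[str, float]] = {
    "NT": {
        "mu_a_intercept": 2.10, "mu_a_slope": 0.062,
        "mu_v_intercept": 1.85, "mu_v_slope": 0.062,
        "sigma_a_intercept": 0.55, "sigma_a_slope": 0.008,
        "sigma_v_intercept": 0.55, "sigma_v_slope": 0.008,
        "age_cap": 24.0,
    },
    "ASD": {
        "mu_a_intercept": 1.98, "mu_a_slope": 0.062,
        "mu_v_intercept": 1.73, "mu_v_slope": 0.062,
        "sigma_a_intercept": 0.55, "sigma_a_slope": 0.008,
        "sigma_v_intercept": 0.55, "sigma_v_slope": 0.008,
        "age_cap": 24.0,
    },
}

AgeParam = float | tuple | Callable[[float], float]


def _resolve_age_param(param: AgeParam, age: float) -> float:
    """Resolve a scalar, ``(intercept, slope[, age_cap])`` tuple, or callable."""
    if callable(param):
        return float(param(age))
    if isinstance(param, tuple):
        if len(param) == 2:
            intercept, slope = param
            cap = np.inf
        else:
            intercept, slope, cap = param
        return float(intercept + slope * min(age, cap))
    return float(param)


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``rho_gen``, ``eta_gen`` and ``switch_cost`` may be scalars, an
    ``(intercept, slope[, age_cap])`` tuple evaluated at the subject's age, or
    an arbitrary callable of age — so scenario scripts can inject
    age-dependent effect sizes without subclassing.
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NT": 20, "ASD": 20})
    age_range: tuple[float, float] = (6.0, 40.0)
    trials_per_subject: int = 800
    block_size: int = 100
    isi_range_ms: tuple[float, float] = (1000.0, 3000.0)
    channel_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CHANNEL_PARAMS.items()})
    #: channel correlation on AV trials; default mirrors the developmental
    #: pattern (positive in childhood, negative by adulthood)
    rho_gen: AgeParam = (0.45, -0.03, 24.0)
    #: multiplicative SD inflation of both channels on AV trials
    eta_gen: AgeParam = 0.1
    #: rate decrement (1/s) applied to a channel absent from the previous trial
    switch_cost: AgeParam = 0.25
    #: switch cost applied to AV-trial channels; None means same as switch_cost
    switch_cost_av: float | None = None
    #: optional exponential decay of the switch cost with preceding ISI
    switch_decay_tau_ms: float | None = None
    competition_mode: str = "none"
    p_competition: float = 0.0
    miss_rate: float = 0.05
    fa_rate: float = 0.03
    double_press_rate: float = 0.005
    #: idiosyncratic between-subject spread around the age profile
    mu_subject_sd: float = 0.35
    sigma_subject_sd: float = 0.06
    switch_cost_subject_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not self.n_subjects_per_group:
            raise ValueError("at least one group is required")
        for g, n in self.n_subjects_per_group.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        lo, hi = self.isi_range_ms
        if lo <= 0 or lo >= hi:
            raise ValueError("isi_range_ms must be positive with min < max")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.trials_per_subject <= 0 or self.block_size <= 0:
            raise ValueError("trial counts must be positive")
        for p, name in [(self.p_competition, "p_competition"),
                        (self.miss_rate, "miss_rate"),
                        (self.fa_rate, "fa_rate"),
                        (self.double_press_rate, "double_press_rate")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.competition_mode not in COMPETITION_MODES:
            raise ValueError(f"unknown competition_mode {self.competition_mode!r}")
        for g in self.n_subjects_per_group:
            if g not in self.channel_params:
                raise ValueError(f"no channel parameters for group {g!r}")


@dataclass
class SubjectParams:
    """Fully resolved per-subject generator settings (rates in 1/s)."""

    mu_a: float
    sigma_a: float
    mu_v: float
    sigma_v: float
    rho: float = 0.0
    eta: float = 0.0
    switch_cost: float = 0.0
    switch_cost_av: float | None = None
    switch_decay_tau_ms: float | None = None
    competition_mode: str = "none"
    p_competition: float = 0.0
    miss_rate: float = 0.0
    double_press_rate: float = 0.0
    block_size: int = 100

    def validate(self) -> None:
        if min(self.mu_a, self.mu_v) <= 0 or min(self.sigma_a, self.sigma_v) <= 0:
            raise ValueError("channel rates and SDs must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.eta < 0 or self.switch_cost < 0:
            raise ValueError("eta and switch_cost must be non-negative")


def subject_params_from_config(cfg: CohortConfig, group: str,
                               age: float) -> SubjectParams:
    """Interpolate a subject's generator settings from group/age profiles."""
    cp = cfg.channel_params[group]
    cap = cp.get("age_cap", np.inf)
    a = min(age, cap)
    return SubjectParams(
        mu_a=cp["mu_a_intercept"] + cp["mu_a_slope"] * a,
        sigma_a=cp["sigma_a_intercept"] + cp["sigma_a_slope"] * a,
        mu_v=cp["mu_v_intercept"] + cp["mu_v_slope"] * a,
        sigma_v=cp["sigma_v_intercept"] + cp["sigma_v_slope"] * a,
        rho=float(np.clip(_resolve_age_param(cfg.rho_gen, age), -0.99, 0.99)),
        eta=max(0.0, _resolve_age_param(cfg.eta_gen, age)),
        switch_cost=max(0.0, _resolve_age_param(cfg.switch_cost, age)),
        switch_cost_av=cfg.switch_cost_av,
        switch_decay_tau_ms=cfg.switch_decay_tau_ms,
        competition_mode=cfg.competition_mode,
        p_competition=cfg.p_competition,
        miss_rate=cfg.miss_rate,
        double_press_rate=cfg.double_press_rate,
        block_size=cfg.block_size,
    )


def sample_trial_sequence(n: int, cfg: CohortConfig | None = None,
                          seed=None) -> pd.DataFrame:
    """Draw an i.i.d. trial sequence: equiprobable conditions, uniform ISIs.

    Returns a DataFrame with columns ``condition`` and ``isi_ms``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.isi_range_ms
    return pd.DataFrame({
        "condition": rng.choice(CONDITIONS, size=n),
        "isi_ms": rng.uniform(lo, hi, size=n),
    })


def component_repeat_probability(conditions: Sequence[str] | None = None) -> float:
    """P(next trial contains the current trial's unisensory component).

    With no argument, computes the exact design probability by enumerating
    the 3x3 transition table of equiprobable conditions (an A or V component
    recurs whenever the next stimulus is the same condition or AV, hence 2/3).
    With a condition sequence, estimates the same probability empirically over
    trials whose current condition is unisensory.
    """
    if conditions is None:
        num = den = 0
        for cur, nxt in itertools.product(CONDITIONS, repeat=2):
            if cur == "AV":
                continue
            den += 1
            if cur in nxt:  # component label appears in "A"/"V"/"AV"
                num += 1
        return num / den
    conditions = np.asarray(conditions)
    cur, nxt = conditions[:-1], conditions[1:]
    uni = cur != "AV"
    if not uni.any():
        raise ValueError("sequence contains no unisensory trials with a successor")
    contains = np.array([c in n for c, n in zip(cur[uni], nxt[uni])])
    return float(contains.mean())


def _truncated_normal(rng: np.random.Generator, mu: np.ndarray,
                      sigma: float) -> np.ndarray:
    """Normal draws rejected below zero (negligible mass in the default regime)."""
    x = rng.normal(mu, sigma)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(np.asarray(mu)[bad] if np.ndim(mu) else mu, sigma,
                            size=int(bad.sum()))
        bad = x <= 0
    return x


def generate_subject_trials(params: SubjectParams, sequence: pd.DataFrame,
                            seed=None) -> pd.DataFrame:
    """Realise RTs for one subject over a given condition/ISI sequence.

    Unisensory RTs are ``1000 / X`` with ``X ~ N(mu_c, sigma_c)`` truncated to
    positive rates; a channel absent from the previous stimulus has its mean
    rate reduced by the switch cost. AV RTs are ``1000 / max(X_A, X_V)`` with
    the channel pair correlated at ``rho`` and SDs inflated by ``1 + eta`` —
    except under a competition regime, where with probability
    ``p_competition`` the response is drawn solely from the biased channel.
    Misses are encoded as absent ``rt_ms``.
    """
    params.validate()
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    cond = sequence["condition"].to_numpy()
    isi = sequence["isi_ms"].to_numpy(dtype=float)
    idx = np.arange(n)
    block = idx // params.block_size
    trial_idx = idx % params.block_size

    prev = np.empty(n, dtype=object)
    prev[0] = None
    prev[1:] = cond[:-1]
    prev[trial_idx == 0] = None  # no carry across blocks

    # per-trial effective switch cost (optionally decaying with preceding ISI)
    cost = np.full(n, params.switch_cost)
    if params.switch_decay_tau_ms is not None:
        cost = cost * np.exp(-(isi - np.min(isi)) / params.switch_decay_tau_ms)
    cost_av = cost if params.switch_cost_av is None else np.full(n, float(params.switch_cost_av))

    has_prev = prev != None  # noqa: E711  (object array comparison)
    a_switch = has_prev & (prev == "V")   # auditory channel absent previously
    v_switch = has_prev & (prev == "A")

    rt = np.full(n, np.nan)

    for c, mu, sig, sw in (("A", params.mu_a, params.sigma_a, a_switch),
                           ("V", params.mu_v, params.sigma_v, v_switch)):
        m = cond == c
        if m.any():
            mu_eff = mu - cost[m] * sw[m]
            rt[m] = 1000.0 / _truncated_normal(rng, mu_eff, sig)

    m = cond == "AV"
    if m.any():
        mu_a_eff = params.mu_a - cost_av[m] * a_switch[m]
        mu_v_eff = params.mu_v - cost_av[m] * v_switch[m]
        sa = params.sigma_a * (1.0 + params.eta)
        sv = params.sigma_v * (1.0 + params.eta)
        k = int(m.sum())
        z1 = rng.standard_normal(k)
        z2 = rng.standard_normal(k)
        xa = mu_a_eff + sa * z1
        xv = mu_v_eff + sv * (params.rho * z1 + np.sqrt(1 - params.rho ** 2) * z2)
        bad = (xa <= 0) | (xv <= 0)
        while bad.any():
            kk = int(bad.sum())
            z1b = rng.standard_normal(kk)
            z2b = rng.standard_normal(kk)
            xa[bad] = mu_a_eff[bad] + sa * z1b
            xv[bad] = mu_v_eff[bad] + sv * (params.rho * z1b
                                            + np.sqrt(1 - params.rho ** 2) * z2b)
            bad = (xa <= 0) | (xv <= 0)
        rt_av = 1000.0 / np.maximum(xa, xv)

        if params.competition_mode != "none" and params.p_competition > 0:
            comp = rng.random(k) < params.p_competition
            if comp.any():
                mode = params.competition_mode
                prev_av = prev[m]
                if mode in ("model1A", "model1V"):
                    bias = np.full(k, mode[-1], dtype=object)
                else:  # previous-modality bias, default channel on AV/None
                    bias = np.where(np.isin(prev_av.astype(str), ("A", "V")),
                                    prev_av.astype(str), mode[-1])
                for b, mu_eff, sig in (("A", mu_a_eff, params.sigma_a),
                                       ("V", mu_v_eff, params.sigma_v)):
                    sel = comp & (bias == b)
                    if sel.any():
                        rt_av[sel] = 1000.0 / _truncated_normal(
                            rng, mu_eff[sel], sig)
        rt[m] = rt_av

    miss = rng.random(n) < params.miss_rate
    n_presses = np.where(miss, 0, 1)
    dbl = (~miss) & (rng.random(n) < params.double_press_rate)
    n_presses[dbl] = 2
    rt[miss] = np.nan

    return pd.DataFrame({
        "block": block,
        "trial_idx": trial_idx,
        "condition": cond,
        "isi_ms": isi,
        "rt_ms": rt,
        "n_presses": n_presses,
        "prev_condition": [p if p is not None else "" for p in prev],
        "prev_responded": np.concatenate([[False], n_presses[:-1] == 1])
        & has_prev.astype(bool),
    })


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (subject table, trial table) for a full synthetic cohort.

    Deterministic given ``cfg.seed``: all randomness flows from one seed
    sequence, with one spawned child stream per subject.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    n_total = sum(cfg.n_subjects_per_group.values())
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(n_total + 1)[1:]

    subjects = []
    trial_frames = []
    i = 0
    for group in sorted(cfg.n_subjects_per_group):
        for j in range(cfg.n_subjects_per_group[group]):
            sid = f"{group}{j:03d}"
            age = float(demo_rng.uniform(*cfg.age_range))
            sex = str(demo_rng.choice(["F", "M"]))
            piq = float(np.clip(demo_rng.normal(107, 13), 82, 145))
            viq = float(np.clip(demo_rng.normal(108, 15), 70, 150))
            fsiq = float(np.clip((piq + viq) / 2 + demo_rng.normal(0, 5), 70, 150))
            fa_count = int(demo_rng.binomial(cfg.trials_per_subject, cfg.fa_rate))
            params = subject_params_from_config(cfg, group, age)
            # idiosyncratic (non-age) individual differences
            shift = demo_rng.normal(0.0, cfg.mu_subject_sd)
            params.mu_a = max(params.mu_a + shift
                              + demo_rng.normal(0, cfg.mu_subject_sd / 2), 0.3)
            params.mu_v = max(params.mu_v + shift
                              + demo_rng.normal(0, cfg.mu_subject_sd / 2), 0.3)
            params.sigma_a = max(params.sigma_a
                                 + demo_rng.normal(0, cfg.sigma_subject_sd), 0.05)
            params.sigma_v = max(params.sigma_v
                                 + demo_rng.normal(0, cfg.sigma_subject_sd), 0.05)
            params.switch_cost = abs(params.switch_cost + demo_rng.normal(
                0, cfg.switch_cost_subject_sd))
            seq = sample_trial_sequence(cfg.trials_per_subject, cfg,
                                        seed=child_seeds[i])
            tr = generate_subject_trials(params, seq,
                                         seed=np.random.SeedSequence(
                                             entropy=child_seeds[i].entropy,
                                             spawn_key=child_seeds[i].spawn_key + (1,)))
            tr.insert(0, "subject_id", sid)
            trial_frames.append(tr)
            subjects.append({
                "subject_id": sid, "group": group, "age_years": round(age, 2),
                "sex": sex, "piq": round(piq, 1), "viq": round(viq, 1),
                "fsiq": round(fsiq, 1), "fa_count": fa_count,
            })
            i += 1
    subjects_df = pd.DataFrame(subjects)
    trials_df = pd.concat(trial_frames, ignore_index=True)
    return subjects_df, trials_df


def config_with(cfg: CohortConfig, **kwargs) -> CohortConfig:
    """Return a copy of ``cfg`` with fields replaced (dataclass convenience)."""
    return replace(cfg, **kwargs)
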