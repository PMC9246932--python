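"""Simulation benchmarks: recovery, calibration and qualitative-pattern
audits run on the synthetic generator.

These are the package's own validation experiments — each function builds
synthetic data under known conditions, runs the corresponding analysis, and
returns the measured recovery/calibration quantity. The test suite and the
acceptance script both call them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cdf import condition_subsets
from .cohort import (CohortConfig, SubjectParams, generate_cohort,
                     generate_subject_trials, sample_trial_sequence)
from .competition import ALL_SPECS, bias_model_cdf, mixture_benefit
from .context_race import fit_context_race
from .preprocess import clean_rts
from .race import race_outcome
from .stats import bayes_factor, bootstrap_ci, permutation_test
from .switch import race_by_switch

GENERATING_MODES = ("none", "model1A", "model1V", "model2A", "model2V")


def _subject_benefits(trials: pd.DataFrame) -> dict | None:
    """Clean one subject's trials and compute empirical + candidate-model
    benefits (race at p=0, each bias model at p=1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ct, _ = clean_rts(trials)
        try:
            s = condition_subsets(ct)
            o = race_outcome(s)
        except ValueError:
            return None
        out = {"emp": o.benefit_emp, "race": o.benefit_pred}
        for spec in ALL_SPECS:
            bias = bias_model_cdf(spec, s)
            out[spec.label] = mixture_benefit(1.0, o.race_cdf, bias,
                                              o.grice_cdf)
    return out


def model_recovery(n_replicates: int = 100, n_subjects: int = 40,
                   trials_per_subject: int = 1000, seed=0) -> dict:
    """Generative model selection: cohorts generated under each of the five
    coupling regimes (independent race, fixed A/V bias, previous-modality
    bias with A/V default) must hand the top between-subject correlation to
    the generating model.

    Cohorts are synthetic children (ages 6-9, the age range where the
    competitive regimes are hypothesised). Returns the overall recovery
    fraction plus the per-mode confusion counts.
    """
    rng = np.random.default_rng(seed)
    candidates = ["race"] + [sp.label for sp in ALL_SPECS]
    confusion = {m: {c: 0 for c in candidates} for m in GENERATING_MODES}
    n_correct = 0
    for rep in range(n_replicates):
        mode = GENERATING_MODES[rep % len(GENERATING_MODES)]
        cfg = CohortConfig(
            n_subjects_per_group={"NT": n_subjects},
            age_range=(6.0, 9.9), trials_per_subject=trials_per_subject,
            rho_gen=0.0, eta_gen=0.0,
            competition_mode=mode if mode != "none" else "none",
            p_competition=0.0 if mode == "none" else 1.0,
            seed=int(rng.integers(2 ** 31)))
        _, trials = generate_cohort(cfg)
        rows = []
        for _, sub in trials.groupby("subject_id", sort=True):
            b = _subject_benefits(sub)
            if b is not None:
                rows.append(b)
        df = pd.DataFrame(rows)
        rs = {c: df[c].corr(df["emp"]) for c in candidates}
        top = max(rs, key=rs.get)
        confusion[mode][top] += 1
        target = "race" if mode == "none" else mode
        n_correct += top == target
    return {"accuracy": n_correct / n_replicates, "confusion": confusion,
            "n_replicates": n_replicates}


def later_recovery(n: int = 5000, mu: float = 5.0, sigma: float = 1.0,
                   seed=0) -> dict:
    """Recover LATER rate parameters from RTs built as 1000/Normal draws."""
    from .context_race import fit_later

    rng = np.random.default_rng(seed)
    x = rng.normal(mu, sigma, n)
    x = x[x > 0]
    mu_hat, sigma_hat = fit_later(1000.0 / x)
    return {"mu": mu_hat, "sigma": sigma_hat,
            "mu_err_pct": abs(mu_hat - mu) / mu * 100,
            "sigma_err_pct": abs(sigma_hat - sigma) / sigma * 100, "n": n}


def context_race_recovery(n_replicates: int = 100, n_av: int = 400,
                          rho_true: float = -0.5, eta_true: float = 0.2,
                          seed=0) -> dict:
    """Median absolute recovery error of (rho, eta) on generator data whose
    structure matches the fitted model (no switch cost, no misses)."""
    rng = np.random.default_rng(seed)
    errs_rho, errs_eta = [], []
    for _ in range(n_replicates):
        p = SubjectParams(mu_a=3.2, sigma_a=0.7, mu_v=3.0, sigma_v=0.65,
                          rho=rho_true, eta=eta_true, switch_cost=0.0,
                          miss_rate=0.0)
        seq = sample_trial_sequence(3 * n_av, CohortConfig(),
                                    seed=rng.integers(2 ** 31))
        tr = generate_subject_trials(p, seq, seed=rng.integers(2 ** 31))
        rts = {c: tr.loc[tr.condition == c, "rt_ms"].to_numpy()
               for c in ("A", "V", "AV")}
        f = fit_context_race(rts["A"], rts["V"], rts["AV"][:n_av])
        errs_rho.append(abs(f.rho - rho_true))
        errs_eta.append(abs(f.eta - eta_true))
    return {"rho_median_abs_err": float(np.median(errs_rho)),
            "eta_median_abs_err": float(np.median(errs_eta)),
            "n_replicates": n_replicates, "n_av": n_av}


def fwer_audit(n_replicates: int = 500, n_subjects: int = 20,
               n_vars: int = 20, n_perm: int = 2000, seed=0) -> dict:
    """Familywise false-positive rate of the max-statistic permutation test
    on pure-null multivariate data."""
    rng = np.random.default_rng(seed)
    n_fp = 0
    for _ in range(n_replicates):
        x = rng.standard_normal((n_subjects, n_vars))
        res = permutation_test(x, tail="two", n_perm=n_perm,
                               correction="tmax", seed=rng.integers(2 ** 31))
        n_fp += bool(res.significant.any())
    mc_se = np.sqrt(0.05 * 0.95 / n_replicates)
    return {"fwer": n_fp / n_replicates, "mc_se": float(mc_se),
            "n_replicates": n_replicates}


def bca_coverage(n_replicates: int = 1000, n: int = 100,
                 n_boot: int = 1999, seed=0) -> dict:
    """Coverage of the nominal-95% BCa interval for a normal mean."""
    rng = np.random.default_rng(seed)
    n_cover = 0
    for _ in range(n_replicates):
        x = rng.standard_normal(n)
        lo, hi = bootstrap_ci(x, np.mean, n_boot=n_boot,
                              seed=rng.integers(2 ** 31))
        n_cover += lo <= 0.0 <= hi
    return {"coverage": n_cover / n_replicates, "n_replicates": n_replicates,
            "n": n, "n_boot": n_boot}


def null_bf01(n_replicates: int = 500, n_per_group: int = 30, seed=0) -> dict:
    """Median BF01 for two-sample null data (evidence should favour the null)."""
    rng = np.random.default_rng(seed)
    bfs = [bayes_factor(rng.standard_normal(n_per_group),
                        rng.standard_normal(n_per_group))
           for _ in range(n_replicates)]
    return {"median_bf01": float(np.median(bfs)), "n_replicates": n_replicates}


def switch_gain_direction(n_subjects: int = 40,
                          trials_per_subject: int = 800, seed=0) -> dict:
    """With switch costs confined to the unisensory channels, the race test
    run within switch trials should exceed the repeat-trial one for most
    subjects (the switch-specific violation pattern)."""
    cfg = CohortConfig(
        n_subjects_per_group={"NT": n_subjects}, age_range=(18.0, 40.0),
        trials_per_subject=trials_per_subject, rho_gen=0.0, eta_gen=0.0,
        switch_cost=0.35, switch_cost_av=0.0, miss_rate=0.02, seed=seed)
    _, trials = generate_cohort(cfg)
    n_pos = n_tot = 0
    for _, sub in trials.groupby("subject_id", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct, _ = clean_rts(sub)
            g = race_by_switch(ct)
        if g is None:
            continue
        n_tot += 1
        n_pos += g[0] > g[1]
    return {"frac_switch_gt_repeat": n_pos / n_tot, "n_subjects": n_tot}


def developmental_lag_trace(n_per_group: int = 80, lag_years: float = 5.0,
                            seed=0, permute_ages: bool = False) -> dict:
    """An injected developmental lag (one group's channel-correlation
    profile shifted ``lag_years`` later) should pull the similarity-matrix
    extremal trace above the diagonal by about ``lag_years / 2.5`` bins.

    With ``permute_ages`` the subject ages are shuffled first (null control:
    no systematic offset should survive).
    """
    def rho_nt(age):
        return float(np.clip(0.55 - 0.045 * min(age, 24.0), -0.6, 0.6))

    def rho_asd(age):
        return rho_nt(max(age - lag_years, 6.0))

    rng = np.random.default_rng(seed)
    frames = []
    for group, rho in (("NT", rho_nt), ("ASD", rho_asd)):
        cfg = CohortConfig(n_subjects_per_group={group: n_per_group},
                           age_range=(6.0, 21.0), rho_gen=rho,
                           trials_per_subject=600,
                           seed=int(rng.integers(2 ** 31)))
        frames.append(generate_cohort(cfg))
    subjects = pd.concat([f[0] for f in frames], ignore_index=True)
    trials = pd.concat([f[1] for f in frames], ignore_index=True)

    diffs, ages, groups = [], [], []
    for sid, sub in trials.groupby("subject_id", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct, _ = clean_rts(sub)
            try:
                o = race_outcome(condition_subsets(ct))
            except ValueError:
                continue
        row = subjects.set_index("subject_id").loc[sid]
        diffs.append(o.diff_fn)
        ages.append(row["age_years"])
        groups.append(row["group"])
    ages = np.asarray(ages)
    if permute_ages:
        ages = rng.permutation(ages)
    from .stats import similarity_matrices
    rmse_m, corr_m, trace = similarity_matrices(
        np.vstack(diffs), ages, groups=np.asarray(groups))
    rows_used = trace["rmse_argmin"] >= 0
    all_offsets = np.arange(len(trace["rmse_argmin"])) - trace["rmse_argmin"]
    offsets = all_offsets[rows_used]
    # rows younger than the lag cannot express it (the shifted profile is
    # clamped at the youngest age), so summarise the expressible rows too
    lag_bins = int(np.ceil(lag_years / 2.5))
    expr = all_offsets[rows_used & (np.arange(len(all_offsets)) >= lag_bins)]
    return {"mean_offset_bins": float(offsets.mean()),
            "mean_offset_expressible": float(expr.mean()) if len(expr) else np.nan,
            "offsets": offsets.tolist(),
            "expected_bins": lag_years / 2.5,
            "n_rows": int(rows_used.sum())}


def moving_window_confinement(n_per_group: int = 60, seed=0,
                              cutoff_age: float = 14.0) -> dict:
    """A group gain difference injected only below ``cutoff_age`` (via more
    positive channel correlation in the younger ASD range) should confine
    significant moving-window centres below the cutoff."""
    def rho_nt(age):
        return 0.45 - 0.03 * min(age, 24.0)

    def rho_asd(age):
        return rho_nt(age) + (0.35 if age < cutoff_age else 0.0)

    rng = np.random.default_rng(seed)
    frames = []
    for group, rho in (("NT", rho_nt), ("ASD", rho_asd)):
        cfg = CohortConfig(n_subjects_per_group={group: n_per_group},
                           age_range=(6.0, 26.0), rho_gen=rho,
                           trials_per_subject=600,
                           seed=int(rng.integers(2 ** 31)))
        frames.append(generate_cohort(cfg))
    subjects = pd.concat([f[0] for f in frames], ignore_index=True)
    trials = pd.concat([f[1] for f in frames], ignore_index=True)

    gains, ages, groups = [], [], []
    for sid, sub in trials.groupby("subject_id", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct, _ = clean_rts(sub)
            try:
                o = race_outcome(condition_subsets(ct))
            except ValueError:
                continue
        row = subjects.set_index("subject_id").loc[sid]
        gains.append(o.gain)
        ages.append(row["age_years"])
        groups.append(row["group"])
    d = pd.DataFrame({"gain": gains, "age": ages, "group": groups})
    from .stats import moving_window_compare
    win = moving_window_compare(d["gain"], d["age"], d["group"],
                                n_perm=1000, n_boot=500,
                                seed=int(rng.integers(2 ** 31)))
    sig = win[win["significant"]]
    return {"n_windows": len(win),
            "n_significant": int(len(sig)),
            "sig_centres": sig["centre"].tolist(),
            "max_sig_centre": float(sig["centre"].max()) if len(sig) else np.nan,
            "cutoff": cutoff_age}
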