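"""Resampling and Bayesian inference layer.

Permutation tests (sign-flip and label-shuffle) with max-statistic familywise
correction or Benjamini-Hochberg FDR; BCa bootstrap intervals; Hedges g;
JZS Bayes factors (Cauchy prior, scale 1); rank-based inverse normal (RIN)
transform; between-subject similarity matrices over difference functions;
covariate-matched group construction; moving-window group comparisons; the
trial-level mixed-effects RT model; ANCOVA of predicted-vs-empirical
benefits; partial correlation; and the age -> switch-cost -> gain mediation
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 10000
DEFAULT_N_BOOT = 10000


# --------------------------------------------------------------------------
# permutation tests

@dataclass
class StatResult:
    statistic: np.ndarray        # per-variable t statistic
    p_perm: np.ndarray           # per-variable permutation p (add-one rule)
    significant: np.ndarray      # after the requested correction, alpha=.05
    correction: str              # "tmax" | "fdr" | "none"
    tail: str
    n_perm: int
    effect_size_g: float | None = None
    g_ci: tuple[float, float] | None = None
    bf01: float | None = None


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    se = np.where(se == 0, np.nan, se)
    return x.mean(axis=0) / se


def _t_two_sample(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx, ny = x.shape[0], y.shape[0]
    sp2 = ((nx - 1) * x.var(axis=0, ddof=1) + (ny - 1) * y.var(axis=0, ddof=1)) \
        / (nx + ny - 2)
    se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    se = np.where(se == 0, np.nan, se)
    return (x.mean(axis=0) - y.mean(axis=0)) / se


def _tail_stat(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two":
        return np.abs(t)
    if tail == "right":
        return t
    if tail == "left":
        return -t
    raise ValueError(f"unknown tail {tail!r}")


def permutation_test(x, y=None, tail: str = "two",
                     n_perm: int = DEFAULT_N_PERM,
                     correction: str = "tmax", seed=None) -> StatResult:
    """Nonparametric permutation test on one or many variables at once.

    One-sample (or paired-difference) input flips observation signs;
    two-sample input shuffles group labels. Multivariate input is corrected
    familywise by the permutation distribution of the maximum statistic
    (``tmax``), by Benjamini-Hochberg (``fdr``), or left uncorrected.
    p-values use the add-one estimator and are never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    rng = np.random.default_rng(seed)

    if y is None:
        t_obs = _t_one_sample(x)
        n = x.shape[0]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        # sign flips leave sum(x^2) invariant, so the flipped t statistic is
        # computable from the flipped mean alone (fully vectorised null)
        mean = signs @ x / n
        ssq = (x ** 2).sum(axis=0)
        var = np.maximum(ssq[None, :] - n * mean ** 2, 0.0) / (n - 1)
        se = np.sqrt(var / n)
        se = np.where(se == 0, np.nan, se)
        t_null = mean / se
    else:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1:
            y = y.T
        if x.shape[1] != y.shape[1]:
            raise ValueError("x and y must share the variable dimension")
        t_obs = _t_two_sample(x, y)
        pooled = np.vstack([x, y])
        nx, ntot = x.shape[0], x.shape[0] + y.shape[0]
        ny = ntot - nx
        tot_sum = pooled.sum(axis=0)
        tot_ssq = (pooled ** 2).sum(axis=0)
        sq = pooled ** 2
        t_null = np.empty((n_perm, x.shape[1]))
        # label shuffles in vectorised chunks: group sums determine t
        for s in range(0, n_perm, 2000):
            e = min(s + 2000, n_perm)
            sel = np.argsort(rng.random((e - s, ntot)), axis=1)[:, :nx]
            sum_x = pooled[sel].sum(axis=1)
            ssq_x = sq[sel].sum(axis=1)
            mean_x = sum_x / nx
            mean_y = (tot_sum[None, :] - sum_x) / ny
            var_x = np.maximum(ssq_x - nx * mean_x ** 2, 0.0) / (nx - 1)
            var_y = np.maximum((tot_ssq[None, :] - ssq_x)
                               - ny * mean_y ** 2, 0.0) / (ny - 1)
            sp2 = ((nx - 1) * var_x + (ny - 1) * var_y) / (ntot - 2)
            se = np.sqrt(sp2 * (1 / nx + 1 / ny))
            se = np.where(se == 0, np.nan, se)
            t_null[s:e] = (mean_x - mean_y) / se

    s_obs = _tail_stat(t_obs, tail)
    s_null = _tail_stat(t_null, tail)

    with np.errstate(invalid="ignore"):
        p_uncorr = (1 + np.sum(s_null >= s_obs[None, :] - 1e-12, axis=0)) \
            / (n_perm + 1)
    undefined = ~np.isfinite(s_obs)   # zero-variance input: no evidence
    if correction == "tmax":
        with np.errstate(invalid="ignore", all="ignore"):
            null_max = np.nanmax(np.where(np.isfinite(s_null), s_null,
                                          -np.inf), axis=1)
            p = (1 + np.sum(null_max[:, None] >= s_obs[None, :] - 1e-12,
                            axis=0)) / (n_perm + 1)
        sig = p < 0.05
    elif correction == "fdr":
        p = p_uncorr
        sig = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    elif correction == "none":
        p = p_uncorr
        sig = p < 0.05
    else:
        raise ValueError(f"unknown correction {correction!r}")
    p = np.where(undefined, 1.0, p)
    sig = np.where(undefined, False, sig)
    return StatResult(statistic=t_obs, p_perm=p, significant=sig,
                      correction=correction, tail=tail, n_perm=n_perm)


# --------------------------------------------------------------------------
# bootstrap, effect sizes, Bayes factors

def bootstrap_ci(values, statistic_fn=np.mean, n_boot: int = DEFAULT_N_BOOT,
                 level: float = 0.95, seed=None) -> tuple[float, float]:
    """BCa bootstrap confidence interval (jackknife acceleration)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need >= 3 observations")
    if np.ptp(values) == 0:
        v = float(statistic_fn(values))
        return (v, v)
    res = sps.bootstrap((values,), statistic_fn, n_resamples=n_boot,
                        confidence_level=level, method="BCa",
                        random_state=np.random.default_rng(seed))
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def hedges_g(x, y, n_boot: int = 2000, seed=None):
    """Bias-corrected standardised mean difference with a BCa bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need >= 2 observations")

    def g_stat(a, b):
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp = np.sqrt(((na - 1) * np.var(a, ddof=1)
                      + (nb - 1) * np.var(b, ddof=1)) / df)
        if sp == 0:
            return np.nan
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        return (np.mean(a) - np.mean(b)) / sp * j

    g = g_stat(x, y)
    if np.isnan(g):
        warnings.warn("zero pooled SD: g undefined", stacklevel=2)
        return np.nan, (np.nan, np.nan)
    if n_boot:
        res = sps.bootstrap((x, y), lambda a, b: g_stat(np.asarray(a), np.asarray(b)),
                            n_resamples=n_boot, method="BCa", paired=False,
                            vectorized=False,
                            random_state=np.random.default_rng(seed))
        ci = (float(res.confidence_interval.low),
              float(res.confidence_interval.high))
    else:
        ci = (np.nan, np.nan)
    return float(g), ci


def bayes_factor(x=None, y=None, t=None, nx=None, ny=None,
                 paired: bool = False, prior_scale: float = 1.0) -> float:
    """JZS Bayes factor in favour of the null (BF01), Cauchy prior scale 1.

    Accepts either raw samples or a precomputed t statistic with sample
    sizes. Two-sample input is treated as independent unless ``paired``.
    """
    if t is None:
        x = np.asarray(x, dtype=float)
        nx = len(x)
        if y is None:
            t = float(sps.ttest_1samp(x, 0.0).statistic)
        else:
            y = np.asarray(y, dtype=float)
            ny = len(y)
            if paired:
                t = float(sps.ttest_rel(x, y).statistic)
            else:
                t = float(sps.ttest_ind(x, y).statistic)
    bf10 = float(pg.bayesfactor_ttest(t, nx, ny, paired=paired, r=prior_scale))
    if not np.isfinite(bf10) or bf10 <= 0:
        warnings.warn("Bayes factor integration failed", stacklevel=2)
        return np.nan
    return 1.0 / bf10


def rin_transform(x) -> np.ndarray:
    """Rank-based inverse normal (rankit) transform, mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all values tied: RIN transform undefined")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.5) / len(x))


# --------------------------------------------------------------------------
# similarity matrices and matching

def similarity_matrices(diff_fns: np.ndarray, ages: np.ndarray,
                        groups: np.ndarray | None = None,
                        row_group: str = "ASD", col_group: str = "NT",
                        bin_edges: np.ndarray | None = None):
    """Between-subject similarity of race-model difference functions, binned
    by age.

    Pairwise RMSE and Pearson correlation (the latter after a RIN transform
    of the pooled values) between the per-subject 20-point difference
    functions, averaged within each (row-bin, column-bin) age-bin pair. When
    ``groups`` is given, rows are ``row_group`` subjects and columns
    ``col_group`` subjects (the developmental-lag display); otherwise all
    subjects enter both axes. Returns (rmse_matrix, corr_matrix, trace) with
    ``trace`` holding each row's argmin (RMSE) and argmax (correlation)
    column index, NaN rows flagged missing.
    """
    diff_fns = np.asarray(diff_fns, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if bin_edges is None:
        bin_edges = np.arange(6.0, 21.0 + 1e-9, 2.5)  # 6 bins of 2.5 y, 6-21
    n_bins = len(bin_edges) - 1
    which = np.digitize(ages, bin_edges) - 1
    in_range = (which >= 0) & (which < n_bins) \
        & (ages <= bin_edges[-1])
    which = np.where(ages == bin_edges[-1], n_bins - 1, which)

    rin = rin_transform(diff_fns.ravel()).reshape(diff_fns.shape)
    n = diff_fns.shape[0]
    d2 = ((diff_fns[:, None, :] - diff_fns[None, :, :]) ** 2).mean(axis=2)
    rmse = np.sqrt(d2)
    cen = rin - rin.mean(axis=1, keepdims=True)
    denom = np.sqrt((cen ** 2).sum(axis=1))
    corr = (cen @ cen.T) / np.outer(denom, denom)

    if groups is not None:
        groups = np.asarray(groups)
        rows = np.where(in_range & (groups == row_group))[0]
        cols = np.where(in_range & (groups == col_group))[0]
    else:
        rows = cols = np.where(in_range)[0]

    rmse_m = np.full((n_bins, n_bins), np.nan)
    corr_m = np.full((n_bins, n_bins), np.nan)
    for i in range(n_bins):
        ri = rows[which[rows] == i]
        if len(ri) == 0:
            continue
        for j in range(n_bins):
            cj = cols[which[cols] == j]
            if len(cj) == 0:
                continue
            block_r = rmse[np.ix_(ri, cj)]
            block_c = corr[np.ix_(ri, cj)]
            if groups is None and i == j:
                # exclude self-comparisons on the diagonal
                mask = ~np.eye(len(ri), dtype=bool) if len(ri) > 1 else None
                if mask is not None:
                    block_r = block_r[mask]
                    block_c = block_c[mask]
            rmse_m[i, j] = np.nanmean(block_r)
            corr_m[i, j] = np.nanmean(block_c)

    trace = {
        "rmse_argmin": np.array([np.nanargmin(r) if not np.all(np.isnan(r))
                                 else -1 for r in rmse_m]),
        "corr_argmax": np.array([np.nanargmax(r) if not np.all(np.isnan(r))
                                 else -1 for r in corr_m]),
        "bin_edges": bin_edges,
    }
    return rmse_m, corr_m, trace


def match_participants(cases: pd.DataFrame, pool: pd.DataFrame,
                       features: tuple[str, ...] = ("age_years", "piq"),
                       sex_col: str = "sex") -> pd.DataFrame:
    """Nearest-neighbour controls: sex matched exactly, then closest on
    standardised features, sampled without replacement.

    Deterministic given input order; equidistant candidates break ties by
    the lower ``subject_id``. Cases with no same-sex control remaining are
    flagged unmatched (NaN control id).
    """
    both = pd.concat([cases[list(features)], pool[list(features)]])
    mu, sd = both.mean(), both.std(ddof=0).replace(0, 1.0)
    cz = (cases[list(features)] - mu) / sd
    pz = (pool[list(features)] - mu) / sd
    available = pool.copy()
    az = pz.copy()
    out = []
    for (idx, case), (_, z) in zip(cases.iterrows(), cz.iterrows()):
        cand = available[available[sex_col] == case[sex_col]]
        if len(cand) == 0:
            out.append({"case_id": case["subject_id"], "control_id": np.nan,
                        "distance": np.nan})
            continue
        d = np.sqrt(((az.loc[cand.index] - z.values) ** 2).sum(axis=1))
        dmin = d.min()
        ties = cand.loc[d[d <= dmin + 1e-12].index]
        chosen = ties.sort_values("subject_id").iloc[0]
        out.append({"case_id": case["subject_id"],
                    "control_id": chosen["subject_id"],
                    "distance": float(dmin)})
        available = available.drop(chosen.name)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# moving-window comparisons

def moving_window_compare(values: pd.Series, ages: pd.Series,
                          groups: pd.Series, subjects: pd.DataFrame | None = None,
                          window: float = 7.0, step: float = 1.0,
                          age_range: tuple[float, float] = (6.0, 26.0),
                          n_perm: int = 2000, n_boot: int = 2000,
                          match: bool = False, seed=None) -> pd.DataFrame:
    """Windowed two-group comparison of a per-subject metric.

    For each age window: optionally re-match the groups on sex/age/PIQ,
    compute group means with BCa CIs, a two-tailed permutation test, and
    BF01; p-values FDR-corrected across windows. Windows with fewer than 3
    subjects in either group are omitted.
    """
    starts = np.arange(age_range[0], age_range[1] - window + step / 2, step)
    if len(starts) == 0:
        starts = np.array([age_range[0]])
    glabels = sorted(groups.unique())
    if len(glabels) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)
    rows = []
    for w0 in starts:
        w1 = w0 + window
        in_w = (ages >= w0) & (ages <= w1)
        sel = {g: values[in_w & (groups == g)] for g in glabels}
        if any(len(v) < 3 for v in sel.values()):
            continue
        if match and subjects is not None:
            sub_w = subjects[in_w.reindex(subjects.index, fill_value=False)]
            cases = sub_w[sub_w["group"] == glabels[1]]
            pool = sub_w[sub_w["group"] == glabels[0]]
            m = match_participants(cases, pool)
            keep = m["control_id"].dropna()
            sel[glabels[0]] = values[values.index.isin(
                subjects[subjects["subject_id"].isin(keep)].index)]
            if len(sel[glabels[0]]) < 3:
                continue
        a, b = (sel[g].to_numpy() for g in glabels)
        res = permutation_test(a[:, None], b[:, None], tail="two",
                               n_perm=n_perm, correction="none",
                               seed=rng.integers(2 ** 31))
        row = {"window_lo": w0, "window_hi": w1,
               "centre": (w0 + w1) / 2, "p_perm": float(res.p_perm[0]),
               "t": float(res.statistic[0]),
               "bf01": bayes_factor(a, b)}
        for g, v in sel.items():
            ci = bootstrap_ci(v.to_numpy(), np.mean, n_boot=n_boot,
                              seed=rng.integers(2 ** 31))
            row[f"mean_{g}"] = float(v.mean())
            row[f"ci_lo_{g}"], row[f"ci_hi_{g}"] = ci
            row[f"n_{g}"] = len(v)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = multipletests(out["p_perm"], alpha=0.05,
                                           method="fdr_bh")[0]
    return out


# --------------------------------------------------------------------------
# models over trials / subjects

def fit_rt_lmm(trials: pd.DataFrame, subjects: pd.DataFrame,
               isi_bins: int = 10):
    """Trial-level mixed-effects RT model.

    Fixed effects: contrast-coded group, continuous age, condition with the
    AV level as reference. Random intercepts for subject, binned ISI and
    preceding modality, with by-subject and by-preceding-modality condition
    slopes; ML criterion. ISI enters the random structure discretised into
    deciles (a continuous variable cannot index a grouping factor). Returns
    (coefficient table, fitted model).
    """
    import statsmodels.formula.api as smf

    d = trials[trials["rt_ms"].notna()].merge(
        subjects[["subject_id", "group", "age_years"]], on="subject_id")
    d = d[d["prev_condition"].isin(["A", "V", "AV"])].copy()
    d["group_c"] = np.where(d["group"] == "ASD", 0.5, -0.5)
    d["isi_bin"] = pd.qcut(d["isi_ms"], isi_bins, labels=False,
                           duplicates="drop")
    vc = {
        "subject": "0 + C(subject_id)",
        "subject_cond": "0 + C(subject_id):C(condition)",
        "isi": "0 + C(isi_bin)",
        "prev": "0 + C(prev_condition)",
        "prev_cond": "0 + C(prev_condition):C(condition)",
    }
    d["one_group"] = 1
    model = smf.mixedlm(
        "rt_ms ~ group_c + age_years + C(condition, Treatment('AV'))",
        data=d, groups="one_group", vc_formula=vc, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs", maxiter=200)
    coefs = pd.DataFrame({"coef": fit.fe_params, "se": fit.bse_fe,
                          "p": fit.pvalues[fit.fe_params.index]})
    coefs.attrs["converged"] = bool(fit.converged)
    return coefs, fit


def ancova_benefit_correlation(benefit_pred, benefit_emp, age_group) -> dict:
    """Empirical benefit ~ predicted benefit x age group (one-way ANCOVA).

    The interaction term tests whether the predicted-empirical slope depends
    on age group; per-group Pearson r is reported alongside the F table and
    the partial R^2 of the predicted-benefit term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = pd.DataFrame({"pred": np.asarray(benefit_pred, dtype=float),
                      "emp": np.asarray(benefit_emp, dtype=float),
                      "grp": np.asarray(age_group)})
    groups = d["grp"].unique()
    if len(groups) < 2:
        fit = smf.ols("emp ~ pred", data=d).fit()
        return {"f_table": None, "slope": fit.params["pred"],
                "p_slope": fit.pvalues["pred"],
                "group_r": {groups[0]: float(d["pred"].corr(d["emp"]))},
                "interaction_p": np.nan, "partial_r2": fit.rsquared}
    full = smf.ols("emp ~ pred * C(grp)", data=d).fit()
    try:
        ftab = sm.stats.anova_lm(full, typ=2)
    except Exception:
        warnings.warn("rank-deficient ANCOVA design", stacklevel=2)
        ftab = None
    reduced = smf.ols("emp ~ C(grp)", data=d).fit()
    partial_r2 = 1 - full.ssr / reduced.ssr
    add = smf.ols("emp ~ pred + C(grp)", data=d).fit()
    inter_p = float(ftab.loc["pred:C(grp)", "PR(>F)"]) if ftab is not None else np.nan
    return {"f_table": ftab, "slope": float(add.params["pred"]),
            "p_slope": float(add.pvalues["pred"]),
            "group_r": {g: float(d.loc[d.grp == g, "pred"].corr(
                d.loc[d.grp == g, "emp"])) for g in groups},
            "interaction_p": inter_p, "partial_r2": float(partial_r2)}


def partial_correlation(x, y, covariate, n_perm: int = DEFAULT_N_PERM,
                        seed=None) -> tuple[float, float]:
    """Correlation of residuals after regressing the covariate out of both
    variables; permutation p over residual pairings."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not len(x) == len(y) == len(c) or len(x) < 4:
        raise ValueError("need equal lengths >= 4")

    def residualise(v):
        design = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = residualise(x), residualise(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        warnings.warn("constant residuals: partial r undefined", stacklevel=2)
        return np.nan, np.nan
    r = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return r, (1 + count) / (n_perm + 1)


# --------------------------------------------------------------------------
# mediation

@dataclass
class MediationResult:
    path_a: float       # mediator ~ cause
    path_b: float       # outcome ~ mediator | cause
    path_c: float       # outcome ~ cause (total)
    path_c_prime: float  # outcome ~ cause | mediator (direct)
    mediated_ab: float
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    classification: str = ""


def _bca_p(boot: np.ndarray, obs: float, jack: np.ndarray) -> float:
    """Two-sided BCa-adjusted bootstrap p-value for H0: parameter = 0."""
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0 or np.ptp(boot) == 0:
        return 1.0 if obs == 0 else np.nan
    z0 = sps.norm.ppf(np.clip(np.mean(boot < obs), 1e-7, 1 - 1e-7))
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    q = np.clip(np.mean(boot < 0), 1e-7, 1 - 1e-7)   # percentile of zero
    w = sps.norm.ppf(q)
    u = (w - z0) / (1.0 + a * (w - z0))
    z = u - z0
    p_one = sps.norm.cdf(z)
    return float(2 * min(p_one, 1 - p_one))


def _mediation_paths(age: np.ndarray, med: np.ndarray,
                     out: np.ndarray) -> tuple[float, float, float, float]:
    c = float(np.polyfit(age, out, 1)[0])
    a = float(np.polyfit(age, med, 1)[0])
    design = np.column_stack([np.ones_like(age), age, med])
    beta, *_ = np.linalg.lstsq(design, out, rcond=None)
    c_prime, b = float(beta[1]), float(beta[2])
    return a, b, c, c_prime


def mediation(age, mediator, outcome, n_boot: int = DEFAULT_N_BOOT,
              seed=None) -> MediationResult:
    """Three-variable mediation (cause -> mediator -> outcome), all z-scored.

    Path coefficients from three OLS regressions; the indirect effect a*b is
    bootstrapped (BCa-adjusted SE and p). The z-scored OLS algebra gives
    a*b + c' = c exactly. Classified full mediation when a*b is significant
    but the direct path c' is not, partial when both are.
    """
    arrs = [np.asarray(v, dtype=float) for v in (age, mediator, outcome)]
    n = len(arrs[0])
    if n < 10:
        raise ValueError("need n >= 10 complete triples")
    if any(np.std(v) == 0 for v in arrs):
        raise ValueError("degenerate (constant) variable")
    age_z, med_z, out_z = [(v - v.mean()) / v.std(ddof=0) for v in arrs]

    a, b, c, c_prime = _mediation_paths(age_z, med_z, out_z)
    rng = np.random.default_rng(seed)
    names = ("a", "b", "c", "c_prime", "ab")
    boot = {k: np.empty(n_boot) for k in names}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        while np.std(age_z[idx]) == 0 or np.std(med_z[idx]) == 0:
            idx = rng.integers(0, n, n)   # degenerate resample redrawn
        pa, pb, pc, pcp = _mediation_paths(age_z[idx], med_z[idx], out_z[idx])
        for k, v in zip(names, (pa, pb, pc, pcp, pa * pb)):
            boot[k][i] = v
    jack = {k: np.empty(n) for k in names}
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        pa, pb, pc, pcp = _mediation_paths(age_z[idx], med_z[idx], out_z[idx])
        for k, v in zip(names, (pa, pb, pc, pcp, pa * pb)):
            jack[k][i] = v
    obs = dict(zip(names, (a, b, c, c_prime, a * b)))
    se = {k: float(np.std(boot[k], ddof=1)) for k in names}
    p = {k: _bca_p(boot[k], obs[k], jack[k]) for k in names}

    if p["ab"] < 0.05:
        classification = "partial" if p["c_prime"] < 0.05 else "full"
    else:
        classification = "none"
    return MediationResult(path_a=a, path_b=b, path_c=c, path_c_prime=c_prime,
                           mediated_ab=a * b, se=se, p=p,
                           classification=classification)
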