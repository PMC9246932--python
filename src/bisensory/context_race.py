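"""LATER fits and the context-variant race model with channel correlation.

Unisensory RTs are modelled by the LATER framework: the reciprocal rates
``x = 1000 / rt_ms`` are normal with mean mu and SD sigma (1/s). The
context-variant race model predicts multisensory RTs as
``1000 / max(X_A, X_V)`` where (X_A, X_V) is bivariate normal with the
fitted unisensory means, SDs inflated multiplicatively by ``1 + eta``, and
correlation ``rho``. With rho = eta = 0 this reduces to Raab's independent
race of the two LATER channels; rho and eta are the two free parameters fit
to the observed multisensory sample by maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cdf import QuantileCDF, _prev_columns

MIN_FIT_RTS = 20
RHO_BOUNDS = (-0.99, 0.99)
ETA_BOUNDS = (0.0, 3.0)
#: deterministic multi-start grid for the bounded (rho, eta) search
STARTS = ((0.0, 0.0), (-0.5, 0.1), (0.5, 0.1), (-0.8, 0.5), (0.8, 0.5))


@dataclass
class ContextRaceFit:
    mu_a: float
    sigma_a: float
    mu_v: float
    sigma_v: float
    rho: float
    eta: float
    fit_objective: float     # maximised AV log-likelihood
    converged: bool = True


def fit_later(rts_ms: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood normal fit to the reciprocal rates 1000/RT.

    Returns (mu, sigma) on the rate scale (1/s). Requires at least
    ``MIN_FIT_RTS`` strictly positive RTs; a (near-)constant sample yields
    sigma ~ 0 and a degeneracy warning.
    """
    rts = np.asarray(rts_ms, dtype=float)
    if len(rts) < MIN_FIT_RTS:
        raise ValueError(f"need >= {MIN_FIT_RTS} RTs")
    if (rts <= 0).any():
        raise ValueError("RTs must be positive")
    rates = 1000.0 / rts
    mu = float(rates.mean())
    sigma = float(rates.std(ddof=0))   # MLE
    if sigma < 1e-9:
        warnings.warn("degenerate LATER fit: sigma ~ 0", stacklevel=2)
    return mu, sigma


def _max_rate_cdf(x: np.ndarray, mu_a, sa, mu_v, sv, rho) -> np.ndarray:
    """P(max(X_A, X_V) <= x) for correlated normal channel rates."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    rho = float(np.clip(rho, -0.999, 0.999))
    za = (x - mu_a) / sa
    zv = (x - mu_v) / sv
    # standard bivariate normal orthant probability at (za, zv)
    pts = np.column_stack([za, zv])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]])
    return mvn.cdf(pts)


def _max_rate_pdf(x: np.ndarray, mu_a, sa, mu_v, sv, rho) -> np.ndarray:
    """Closed-form density of max(X_A, X_V): two conditional-normal terms."""
    x = np.asarray(x, dtype=float)
    rho = float(np.clip(rho, -0.999, 0.999))
    root = np.sqrt(1.0 - rho ** 2)
    za = (x - mu_a) / sa
    zv = (x - mu_v) / sv
    term_a = stats.norm.pdf(za) / sa * stats.norm.cdf((zv - rho * za) / root)
    term_v = stats.norm.pdf(zv) / sv * stats.norm.cdf((za - rho * zv) / root)
    return term_a + term_v


def predict_av_distribution(fit: ContextRaceFit,
                            eval_times_ms: np.ndarray) -> QuantileCDF:
    """CDF of RT = 1000 / max(X_A, X_V) on the given latency grid."""
    if not -1.0 <= fit.rho <= 1.0 or fit.eta < 0:
        raise ValueError("invalid rho/eta")
    t = np.asarray(eval_times_ms, dtype=float)
    sa = fit.sigma_a * (1.0 + fit.eta)
    sv = fit.sigma_v * (1.0 + fit.eta)
    if fit.rho >= 0.999 and abs(fit.mu_a - fit.mu_v) < 1e-12 \
            and abs(sa - sv) < 1e-12:
        # perfectly coupled identical channels: max == either channel
        probs = stats.norm.sf(1000.0 / t, loc=fit.mu_a, scale=sa)
    else:
        probs = 1.0 - _max_rate_cdf(1000.0 / t, fit.mu_a, sa, fit.mu_v, sv,
                                    fit.rho)
    return QuantileCDF(np.clip(probs, 0.0, 1.0), t, float(t[0]), float(t[-1]),
                       0)


def av_log_likelihood(rts_av_ms: np.ndarray, mu_a, sigma_a, mu_v, sigma_v,
                      rho, eta) -> float:
    """Log-likelihood of an AV RT sample under the context-variant race."""
    rts = np.asarray(rts_av_ms, dtype=float)
    sa = sigma_a * (1.0 + eta)
    sv = sigma_v * (1.0 + eta)
    x = 1000.0 / rts
    dens = _max_rate_pdf(x, mu_a, sa, mu_v, sv, rho) * 1000.0 / rts ** 2
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_context_race(rts_a, rts_v, rts_av) -> ContextRaceFit:
    """Fit (rho, eta) to the AV sample with LATER channels fixed from the
    unisensory fits; bounded derivative-free search from deterministic
    multi-starts. Non-convergence is flagged with best-so-far parameters."""
    rts_av = np.asarray(rts_av, dtype=float)
    if len(rts_av) < MIN_FIT_RTS:
        raise ValueError(f"need >= {MIN_FIT_RTS} AV RTs")
    mu_a, sigma_a = fit_later(rts_a)
    mu_v, sigma_v = fit_later(rts_v)

    def nll(params):
        rho, eta = params
        return -av_log_likelihood(rts_av, mu_a, sigma_a, mu_v, sigma_v,
                                  rho, eta)

    best = None
    any_ok = False
    for start in STARTS:
        res = optimize.minimize(nll, start, method="Powell",
                                bounds=[RHO_BOUNDS, ETA_BOUNDS],
                                options={"xtol": 1e-4, "ftol": 1e-6,
                                         "maxiter": 2000})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rho, eta = best.x
    return ContextRaceFit(mu_a, sigma_a, mu_v, sigma_v, float(rho),
                          float(eta), fit_objective=-float(best.fun),
                          converged=any_ok)


def switch_repeat_frequency_profile(trials: pd.DataFrame,
                                    n_q: int = 20) -> pd.DataFrame:
    """Counts of unisensory switch vs repeat trials per RT quantile bin.

    Bins are linearly spaced between the subject's pooled 2.5/97.5 cutoffs;
    a rate-scale switch cost over-represents switch trials in slow bins
    (the signature of negative channel dependency).
    """
    from .cdf import pooled_percentile_limits

    t = _prev_columns(trials)
    t = t[t["rt_ms"].notna() & t["condition"].isin(["A", "V"])
          & t["prev_condition"].isin(["A", "V"])]
    if len(t) == 0:
        raise ValueError("no classifiable unisensory trials")
    rts = t["rt_ms"].to_numpy()
    lo, hi = np.percentile(rts, [2.5, 97.5]) if len(rts) > 1 else (rts[0] - 1,
                                                                   rts[0] + 1)
    edges = np.linspace(lo, hi, n_q + 1)
    which = np.clip(np.digitize(rts, edges) - 1, 0, n_q - 1)
    is_switch = (t["prev_condition"] != t["condition"]).to_numpy()
    rows = []
    for k in range(n_q):
        in_bin = which == k
        rows.append({"quantile_bin": k + 1,
                     "t_lo_ms": edges[k], "t_hi_ms": edges[k + 1],
                     "n_switch": int((in_bin & is_switch).sum()),
                     "n_repeat": int((in_bin & ~is_switch).sum())})
    return pd.DataFrame(rows)


def fit_table(fits: dict[str, ContextRaceFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": sid, "mu_a": f.mu_a, "sigma_a": f.sigma_a,
         "mu_v": f.mu_v, "sigma_v": f.sigma_v, "rho": f.rho, "eta": f.eta,
         "objective": f.fit_objective, "converged": f.converged}
        for sid, f in fits.items()])
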