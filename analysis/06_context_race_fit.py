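"""Channel dependency and RT variability: the (rho, eta) context race fit.

Fits LATER channels to each subject's unisensory RTs and the correlated
max-rate model to the multisensory RTs, then relates the recovered channel
correlation rho to switch costs (partial correlation controlling for age)
and summarises rho/eta by group and age.
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from bisensory.competition import assign_age_group
from bisensory.context_race import fit_context_race, fit_table
from bisensory.io import read_subject_table, read_trial_table
from bisensory.stats import partial_correlation

OUT = pathlib.Path("results/context_fit")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = read_subject_table("results/cohort/subjects.csv")
    excl = pd.read_csv("results/preprocessing/exclusions.csv")
    keep = set(excl.loc[~excl["excluded"], "subject_id"])
    trials = read_trial_table("results/preprocessing/cleaned_trials.csv")

    fits = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        if sid not in keep:
            continue
        rts = {c: sub.loc[sub["condition"] == c, "rt_ms"].to_numpy()
               for c in ("A", "V", "AV")}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[sid] = fit_context_race(rts["A"], rts["V"], rts["AV"])
        except ValueError:
            continue
    tab = fit_table(fits).merge(
        subjects[["subject_id", "group", "age_years"]], on="subject_id")
    tab["age_group"] = tab["age_years"].map(assign_age_group)
    tab.to_csv(OUT / "context_fits.csv", index=False)

    print(f"context race fits for {len(tab)} subjects "
          f"({int(tab['converged'].sum())} converged)")
    print(tab.groupby(["group", "age_group"])[["rho", "eta"]]
          .mean().round(3))
    slope = np.polyfit(tab["age_years"], tab["rho"], 1)[0]
    print(f"rho vs age slope: {slope:+.4f} per year")

    mse = pd.read_csv("results/switch/mse.csv")
    uni = (mse[mse["condition"].isin(["V->A", "A->V"])]
           .groupby("subject_id")["mse_auc"].mean().rename("mse"))
    d = tab.set_index("subject_id").join(uni).dropna(subset=["mse"])
    r, p = partial_correlation(d["mse"], d["rho"], d["age_years"],
                               n_perm=5000, seed=4)
    print(f"partial r(MSE, rho | age) = {r:+.3f} (p_perm={p:.4f})")
    pd.DataFrame([{"r_partial": r, "p_perm": p, "n": len(d)}]).to_csv(
        OUT / "rho_mse_partial_corr.csv", index=False)


if __name__ == "__main__":
    main()
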