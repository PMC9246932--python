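"""Group-level inference: the trial-level mixed model, benefit ANCOVA,
similarity matrices, matched moving-window comparisons, and the
age -> switch-cost -> gain mediation model.
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from bisensory.io import read_subject_table, read_trial_table
from bisensory.stats import (ancova_benefit_correlation, fit_rt_lmm,
                             mediation, moving_window_compare,
                             similarity_matrices)

OUT = pathlib.Path("results/inference")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = read_subject_table("results/cohort/subjects.csv")
    trials = read_trial_table("results/preprocessing/cleaned_trials.csv")
    race = pd.read_csv("results/race/race_outcomes.csv")
    mse = pd.read_csv("results/switch/mse.csv")

    # trial-level mixed-effects RT model (subsampled for tractability)
    sample_ids = subjects["subject_id"].iloc[::3]
    sub_tr = trials[trials["subject_id"].isin(sample_ids)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coefs, _ = fit_rt_lmm(sub_tr, subjects)
    coefs.to_csv(OUT / "lmm_coefficients.csv")
    print("mixed-model fixed effects (RT in ms):")
    print(coefs.round(3))

    # ANCOVA: empirical on predicted benefits across age groups
    out = ancova_benefit_correlation(race["benefit_pred"],
                                     race["benefit_emp"], race["age_group"])
    print(f"\nANCOVA: slope {out['slope']:.3f} (p={out['p_slope']:.3g}), "
          f"interaction p={out['interaction_p']:.3g}")
    print("  per-group r:", {k: round(v, 3)
                             for k, v in out["group_r"].items()})

    # similarity matrices between the groups' difference functions
    diffs = race[[f"diff_q{k}" for k in range(1, 21)]].to_numpy()
    rmse_m, corr_m, trace = similarity_matrices(
        diffs, race["age_years"].to_numpy(), groups=race["group"].to_numpy())
    np.savetxt(OUT / "similarity_rmse.csv", rmse_m, delimiter=",")
    np.savetxt(OUT / "similarity_corr.csv", corr_m, delimiter=",")
    print("\nsimilarity extremal trace (RMSE argmin per ASD age bin):",
          trace["rmse_argmin"].tolist())

    # moving-window group comparison of multisensory gain
    d = race.merge(subjects[["subject_id", "sex", "piq"]], on="subject_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = moving_window_compare(d["gain"], d["age_years"], d["group"],
                                    n_perm=2000, n_boot=1000, seed=5)
    win.to_csv(OUT / "moving_window_gain.csv", index=False)
    sig = win[win["significant"]]
    print(f"\nmoving-window gain: {len(sig)}/{len(win)} significant windows"
          + (f" (centres {sig['centre'].tolist()})" if len(sig) else ""))

    # mediation: age -> unisensory MSE -> gain, per group
    uni = (mse[mse["condition"].isin(["V->A", "A->V"])]
           .groupby("subject_id")["mse_auc"].mean().rename("mse"))
    dd = race.set_index("subject_id").join(uni).dropna(subset=["mse"])
    rows = []
    for g, sub in dd.groupby("group"):
        res = mediation(sub["age_years"], sub["mse"], sub["gain"],
                        n_boot=2000, seed=6)
        rows.append({"group": g, "a": res.path_a, "b": res.path_b,
                     "c": res.path_c, "c_prime": res.path_c_prime,
                     "ab": res.mediated_ab, "p_ab": res.p["ab"],
                     "p_c_prime": res.p["c_prime"],
                     "classification": res.classification})
        print(f"mediation [{g}]: ab={res.mediated_ab:+.3f} "
              f"(p={res.p['ab']:.4f}), c'={res.path_c_prime:+.3f} "
              f"(p={res.p['c_prime']:.4f}) -> {res.classification}")
    pd.DataFrame(rows).to_csv(OUT / "mediation.csv", index=False)


if __name__ == "__main__":
    main()
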