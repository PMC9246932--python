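"""Race-model analysis: benefits, multisensory gain, and violation tests.

For every included subject, builds the quantile CDFs, the preceding-
modality-conditioned race model, Grice/Miller bounds, and the
benefit/gain statistics; then tests race-model violations per age group
with right-tailed sign-flip permutation tests (tmax-corrected across
the 20 quantiles).
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from bisensory.cdf import condition_subsets
from bisensory.competition import assign_age_group
from bisensory.io import read_subject_table, read_trial_table
from bisensory.race import race_outcome, race_table, race_violation_test

IN_SUBJ = pathlib.Path("results/cohort/subjects.csv")
IN_TRIALS = pathlib.Path("results/preprocessing/cleaned_trials.csv")
OUT = pathlib.Path("results/race")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = read_subject_table(IN_SUBJ)
    excl = pd.read_csv("results/preprocessing/exclusions.csv")
    keep = set(excl.loc[~excl["excluded"], "subject_id"])
    trials = read_trial_table(IN_TRIALS)

    outcomes = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        if sid not in keep:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                outcomes[sid] = race_outcome(condition_subsets(sub))
            except ValueError:
                continue
    tab = race_table(outcomes).merge(
        subjects[["subject_id", "group", "age_years"]], on="subject_id")
    tab["age_group"] = tab["age_years"].map(assign_age_group)
    tab.to_csv(OUT / "race_outcomes.csv", index=False)

    print(f"race outcomes for {len(tab)} subjects")
    print(tab.groupby(["group", "age_group"])[["benefit_pred", "benefit_emp",
                                               "gain"]].mean().round(4))

    rows = []
    for (grp, ag), sub in tab.groupby(["group", "age_group"]):
        if len(sub) < 5:
            continue
        diffs = sub[[f"diff_q{k}" for k in range(1, 21)]].to_numpy()
        res = race_violation_test(diffs, tail="right", n_perm=5000, seed=1)
        n_sig = int(res.significant.sum())
        rows.append({"group": grp, "age_group": ag, "n": len(sub),
                     "n_sig_quantiles": n_sig,
                     "min_p": float(res.p_perm.min())})
        print(f"  {grp} {ag}: {n_sig}/20 quantiles violate the race model "
              f"(min p={res.p_perm.min():.4f})")
    pd.DataFrame(rows).to_csv(OUT / "violation_tests.csv", index=False)


if __name__ == "__main__":
    main()
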