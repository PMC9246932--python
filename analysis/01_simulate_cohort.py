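"""Simulate the study cohort: two diagnostic groups across ages 6-40.

Generates the default synthetic cohort (NT and ASD groups, blocked A/V/AV
detection trials, age-graded LATER channels, developmental channel
correlation, rate-scale switch costs) and writes the subject and trial
tables consumed by the downstream analysis scripts.
"""

import pathlib
import sys

from bisensory.cohort import CohortConfig, generate_cohort
from bisensory.io import write_subject_table, write_trial_table

OUT = pathlib.Path("results/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11


def main():
    cfg = CohortConfig(n_subjects_per_group={"NT": 45, "ASD": 35},
                       trials_per_subject=800, seed=SEED)
    subjects, trials = generate_cohort(cfg)
    write_subject_table(subjects, OUT / "subjects.csv")
    write_trial_table(trials, OUT / "trials.csv")

    by_group = subjects.groupby("group")["age_years"].agg(["count", "mean"])
    print(f"simulated {len(subjects)} subjects, {len(trials)} trials "
          f"(seed {SEED})")
    for g, row in by_group.iterrows():
        print(f"  {g}: n={int(row['count'])}, mean age {row['mean']:.1f} y")
    miss = trials["rt_ms"].isna().mean()
    print(f"  miss rate {miss:.1%}; conditions "
          f"{dict(trials['condition'].value_counts(normalize=True).round(3))}")


if __name__ == "__main__":
    main()
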