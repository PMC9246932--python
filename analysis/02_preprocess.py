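"""Score detection accuracy, apply exclusion criteria, and clean RTs.

Reads the simulated cohort, computes per-subject F1 accuracy, applies the
seven participant-level exclusion criteria, trims trials (training,
response window, per-condition percentile), and writes the cleaned trial
table plus the exclusion audit.
"""

import pathlib

import pandas as pd

from bisensory.io import read_subject_table, read_trial_table
from bisensory.preprocess import (apply_exclusions, clean_rts,
                                  summarise_subject)

IN = pathlib.Path("results/cohort")
OUT = pathlib.Path("results/preprocessing")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = read_subject_table(IN / "subjects.csv")
    trials = read_trial_table(IN / "trials.csv")

    summaries, cleaned_frames, clean_stats = [], [], []
    for sid, sub in trials.groupby("subject_id", sort=True):
        row = subjects[subjects["subject_id"] == sid].iloc[0]
        ct, rep = clean_rts(sub)
        cleaned_frames.append(ct)
        summaries.append(summarise_subject(row, sub, ct))
        clean_stats.append({"subject_id": sid, "n_in": rep.n_input,
                            "n_out": rep.n_output,
                            "fast_frac": rep.fast_outlier_fraction,
                            "slow_frac": rep.slow_outlier_fraction})
    reports = apply_exclusions(summaries)

    cleaned = pd.concat(cleaned_frames, ignore_index=True)
    cleaned.to_csv(OUT / "cleaned_trials.csv", index=False)
    pd.DataFrame(clean_stats).to_csv(OUT / "cleaning_report.csv", index=False)
    excl = pd.DataFrame([{"subject_id": r.subject_id, "excluded": r.excluded,
                          "reasons": ";".join(r.reasons)} for r in reports])
    excl.to_csv(OUT / "exclusions.csv", index=False)
    acc = pd.DataFrame([{"subject_id": s["subject_id"],
                         "f1": s["accuracy"].f1,
                         "fa_rate": s["accuracy"].fa_rate,
                         "miss_rate": s["accuracy"].miss_rate}
                        for s in summaries])
    acc.to_csv(OUT / "accuracy.csv", index=False)

    kept = len(cleaned) / len(trials)
    print(f"cleaned {len(trials)} -> {len(cleaned)} trials ({kept:.1%} kept)")
    print(f"mean F1 {acc['f1'].mean():.3f}; "
          f"excluded {int(excl['excluded'].sum())}/{len(excl)} subjects")
    if excl["excluded"].any():
        print("  reasons:", excl.loc[excl["excluded"], "reasons"]
              .value_counts().to_dict())


if __name__ == "__main__":
    main()
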