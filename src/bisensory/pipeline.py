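"""Generate -> clean -> analyse -> report orchestration.

Each stage draws its randomness from a named substream of one root seed, so
enabling or disabling a stage never perturbs another stage's draws. Every
run writes a machine-readable manifest (config hash, seed, package version,
stage timings) next to its result tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cdf import condition_subsets, pooled_percentile_limits
from .cohort import CohortConfig, generate_cohort
from .competition import ALL_SPECS, benefit_grid, bias_model_cdf, evaluate_models
from .context_race import fit_context_race, fit_table
from .io import (read_subject_table, read_trial_table, write_subject_table,
                 write_trial_table)
from .preprocess import apply_exclusions, clean_rts, summarise_subject
from .race import race_outcome, race_table, race_violation_test
from .switch import mse_by_condition, mse_table, race_by_switch

#: fixed per-stage substream ids (order must never change)
STAGE_SEEDS = {"generate": 1, "race": 2, "competition": 3, "mse": 4,
               "context_fit": 5, "inference": 6}


@dataclass
class PipelineConfig:
    output_dir: str = "results/run"
    seed: int = 0
    subject_table: str | None = None     # external input; None -> synthetic
    trial_table: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stages: tuple[str, ...] = ("race", "competition", "mse", "context_fit")
    n_perm: int = 10000
    n_boot: int = 10000

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, STAGE_SEEDS[stage]])


def load_config(path: str | Path) -> PipelineConfig:
    """Flat key-value YAML config; ``cohort.*`` keys configure the generator."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = {k[len("cohort."):]: v for k, v in raw.items()
                    if k.startswith("cohort.")}
    if "n_subjects_per_group" in cohort_kwargs and \
            isinstance(cohort_kwargs["n_subjects_per_group"], str):
        pairs = cohort_kwargs["n_subjects_per_group"].split(",")
        cohort_kwargs["n_subjects_per_group"] = {
            g: int(n) for g, n in (p.split(":") for p in pairs)}
    top = {k: v for k, v in raw.items() if not k.startswith("cohort.")}
    cfg = PipelineConfig(**top)
    if cohort_kwargs:
        for k, v in cohort_kwargs.items():
            setattr(cfg.cohort, k, v)
    if "seed" in top:
        cfg.cohort.seed = cfg.seed
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)
    blob = json.dumps(asdict(cfg) if not callable(cfg.cohort.rho_gen)
                      else {**asdict(cfg), "cohort": "callable-params"},
                      sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the bundle.

    Result tables are written under ``cfg.output_dir``; stages needing a
    disabled prerequisite raise a dependency error.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "version": __version__, "stages": {}, "tables": []}
    bundle: dict = {}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}

    def done(name):
        manifest["stages"][name]["elapsed_s"] = round(
            time.time() - manifest["stages"][name].pop("t_start"), 3)

    # ---- input data -----------------------------------------------------
    stage("generate")
    if cfg.subject_table and cfg.trial_table:
        subjects = read_subject_table(cfg.subject_table)
        trials = read_trial_table(cfg.trial_table)
    else:
        cfg.cohort.seed = int(np.random.default_rng(
            cfg.stage_seed("generate")).integers(2 ** 31))
        subjects, trials = generate_cohort(cfg.cohort)
    write_subject_table(subjects, out / "subjects.csv")
    write_trial_table(trials, out / "trials.csv")
    done("generate")

    # ---- clean + exclude ------------------------------------------------
    stage("clean")
    cleaned, summaries, per_subject = {}, [], {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        ct, rep = clean_rts(sub)
        cleaned[sid] = ct
        row = subjects.set_index("subject_id").loc[sid]
        row = pd.concat([pd.Series({"subject_id": sid}), row])
        summaries.append(summarise_subject(row, sub, ct))
    reports = apply_exclusions(summaries)
    excl = pd.DataFrame([{"subject_id": r.subject_id, "excluded": r.excluded,
                          "reasons": ";".join(r.reasons)} for r in reports])
    excl.to_csv(out / "exclusions.csv", index=False)
    included = {r.subject_id for r in reports if not r.excluded}
    done("clean")
    bundle["exclusions"] = excl
    bundle["n_included"] = len(included)

    # ---- per-subject CDF sets -------------------------------------------
    cdfsets = {}
    for sid in sorted(included):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cdfsets[sid] = condition_subsets(cleaned[sid])
        except ValueError:
            continue

    ages = subjects.set_index("subject_id")["age_years"]

    if "race" in cfg.stages:
        stage("race")
        outcomes = {sid: race_outcome(s) for sid, s in cdfsets.items()}
        rt_tab = race_table(outcomes)
        rt_tab.to_csv(out / "race_outcomes.csv", index=False)
        diffs = np.vstack([o.diff_fn for o in outcomes.values()])
        viol = race_violation_test(
            diffs, n_perm=cfg.n_perm,
            seed=cfg.stage_seed("race")) if len(diffs) > 1 else None
        bundle["race"] = {"outcomes": outcomes, "table": rt_tab,
                          "violation": viol}
        done("race")

    if "competition" in cfg.stages:
        if "race" not in cfg.stages:
            raise ValueError("competition stage requires the race stage")
        stage("competition")
        per_subject = {}
        for sid, s in cdfsets.items():
            o = bundle["race"]["outcomes"][sid]
            per_subject[sid] = {
                "race": o.race_cdf, "grice": o.grice_cdf,
                "benefit_emp": o.benefit_emp,
                "bias": {sp.label: bias_model_cdf(sp, s) for sp in ALL_SPECS}}
        grid = benefit_grid(per_subject)
        ev = evaluate_models(grid, ages, n_perm=0)
        grid.to_csv(out / "competition_grid.csv", index=False)
        ev.to_csv(out / "competition_eval.csv", index=False)
        bundle["competition"] = {"grid": grid, "eval": ev}
        done("competition")

    if "mse" in cfg.stages:
        stage("mse")
        per_mse = {sid: mse_by_condition(s, normalise=True)
                   for sid, s in cdfsets.items()}
        mt = mse_table(per_mse)
        mt.to_csv(out / "mse.csv", index=False)
        sr = {}
        for sid in cdfsets:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = race_by_switch(cleaned[sid])
            if g is not None:
                sr[sid] = g
        sr_tab = pd.DataFrame([{"subject_id": k, "gain_switch": v[0],
                                "gain_repeat": v[1]} for k, v in sr.items()])
        sr_tab.to_csv(out / "race_by_switch.csv", index=False)
        bundle["mse"] = {"table": mt, "race_by_switch": sr_tab}
        done("mse")

    if "context_fit" in cfg.stages:
        stage("context_fit")
        fits = {}
        for sid, ct in cleaned.items():
            if sid not in cdfsets:
                continue
            rts = {c: ct.loc[ct["condition"] == c, "rt_ms"].to_numpy()
                   for c in ("A", "V", "AV")}
            try:
                fits[sid] = fit_context_race(rts["A"], rts["V"], rts["AV"])
            except ValueError:
                continue
        ft = fit_table(fits)
        ft.to_csv(out / "context_fits.csv", index=False)
        bundle["context_fit"] = {"fits": fits, "table": ft}
        done("context_fit")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
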