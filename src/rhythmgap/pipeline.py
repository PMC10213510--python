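"""End-to-end simulated experiment: cohort -> staircases -> statistics.

A run draws a cohort of simulated observers, puts every subject through
the full procedure (three rhythm conditions in per-subject random
order, three 40-trial interleaved blocks per condition), estimates the
six cell thresholds per subject from staircase reversals, and feeds the
resulting table to the analysis stage.  One master seed spawns an
independent child stream per subject (keyed by subject index), so any
subject's data are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .observer import CohortSpec, ObserverProfile, make_responder, sample_cohort
from .staircase import TrackState, estimate_threshold, run_block
from .stats import (
    CELL_ORDER,
    SubjectResult,
    correlation_table,
    difference_scores,
    paired_t_and_d,
    split_plot_anova,
)
from .trials import RHYTHM_CONDITIONS, SentenceTemplate, make_trial

__all__ = [
    "subject_rng",
    "simulate_subject",
    "simulate_cohort",
    "analyze_results",
    "run_full_pipeline",
]


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Child generator for one subject, independent of execution order."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    )


def _templates(config: ExperimentConfig) -> tuple[SentenceTemplate, SentenceTemplate]:
    return (
        SentenceTemplate("male", config.early_ms_male, config.gap_ms_male,
                         config.final_ms_male),
        SentenceTemplate("female", config.early_ms_female, config.gap_ms_female,
                         config.final_ms_female),
    )


def simulate_subject(
    profile: ObserverProfile,
    config: ExperimentConfig,
    rng: np.random.Generator,
    subject_id: str = "s0",
    collect_trials: bool = False,
):
    """Run one subject through all conditions and blocks.

    Returns a :class:`SubjectResult`; with ``collect_trials`` also a
    list of per-trial log rows (speakers alternate across trials within
    a block, per the stimulus design).
    """
    templates = _templates(config)
    condition_order = [RHYTHM_CONDITIONS[i] for i in rng.permutation(len(RHYTHM_CONDITIONS))]
    thresholds: dict = {}
    trial_rows: list[dict] = []
    for condition in condition_order:
        reversals = {"early": [], "late": []}
        final_levels = {"early": [], "late": []}
        respond = make_responder(profile, condition)
        for block in range(config.n_blocks):
            tracks = {
                "early": TrackState("early", config.start_early, *config.bounds_early),
                "late": TrackState("late", config.start_late, *config.bounds_late),
            }
            counter = [0]

            def trial_factory(direction, level, rng_, _cond=condition):
                template = templates[counter[0] % 2]  # speakers alternate by trial
                counter[0] += 1
                return make_trial(template, _cond, direction, level, rng_)

            result = run_block(
                tracks, respond, rng,
                trials_per_track=config.trials_per_block // 2,
                trial_factory=trial_factory if collect_trials else None,
            )
            for direction in ("early", "late"):
                reversals[direction].append(result.reversals(direction))
                final_levels[direction].append(result.tracks[direction].level)
            if collect_trials:
                for row in result.trial_log:
                    row.update(subject_id=subject_id, block=block,
                               rhythm_condition=condition)
                trial_rows.extend(result.trial_log)
        for direction in ("early", "late"):
            try:
                est = estimate_threshold(reversals[direction], direction,
                                         config.n_reversals_for_threshold)
                thresholds[(condition, direction)] = est.mean_threshold
            except ValueError:
                # degenerate cell: no block reached the reversal count
                # (e.g. a track pinned at a bound); fall back to the mean
                # final track level across blocks
                thresholds[(condition, direction)] = float(
                    np.mean(final_levels[direction])
                )
    result = SubjectResult(
        subject_id=subject_id,
        group=profile.group,
        thresholds=thresholds,
        battery_scores=dict(profile.battery_scores),
    )
    return (result, trial_rows) if collect_trials else result


def simulate_cohort(
    cohort_spec: CohortSpec,
    config: ExperimentConfig,
    master_seed: int | None = None,
) -> list[SubjectResult]:
    """Sample a cohort and run every subject through the experiment."""
    seed = config.seed if master_seed is None else master_seed
    cohort = sample_cohort(cohort_spec,
                           np.random.default_rng(np.random.SeedSequence(seed)))
    results = []
    for i, profile in enumerate(cohort):
        rng = subject_rng(seed, i)
        results.append(simulate_subject(profile, config, rng, subject_id=f"s{i:02d}"))
    return results


def results_frame(results: list[SubjectResult]) -> pd.DataFrame:
    """Tidy per-subject table: 6 cells, difference scores, battery."""
    rows = []
    for r in results:
        row = {"subject_id": r.subject_id, "group": r.group}
        for rhythm, direction in CELL_ORDER:
            row[f"{rhythm}_{direction}"] = r.thresholds[(rhythm, direction)]
        row["late_early_diff"], row["rhythm_diff"] = difference_scores(r)
        row["mean_threshold"] = r.mean_threshold
        for name, value in r.battery_scores.items():
            row[f"battery_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_results(results: list[SubjectResult]) -> dict:
    """ANOVA, post-hoc paired tests and battery correlations.

    Correlations are computed within the older group (the group the
    battery covariates describe); paired direction contrasts are run
    per group.
    """
    Y = np.vstack([r.cells() for r in results])
    groups = np.array([r.group for r in results])
    anova = split_plot_anova(Y, groups)

    posthoc = {}
    for group in dict.fromkeys(groups):
        sub = [r for r in results if r.group == group]
        early = np.array([np.mean([r.thresholds[(c, "early")] for c in RHYTHM_CONDITIONS])
                          for r in sub])
        late = np.array([np.mean([r.thresholds[(c, "late")] for c in RHYTHM_CONDITIONS])
                         for r in sub])
        posthoc[f"{group}_early_vs_late"] = paired_t_and_d(early, late)

    older = [r for r in results if r.group == "older" and r.battery_scores]
    correlations = correlation_table(older) if len(older) >= 3 else None
    return {"anova": anova, "posthoc": posthoc, "correlations": correlations}


def run_full_pipeline(
    config: ExperimentConfig,
    cohort_spec: CohortSpec,
    out_dir: str | Path,
) -> dict:
    """Run the complete simulated experiment and write all outputs.

    Writes thresholds.csv, anova.csv, posthoc.csv, correlations.csv and
    manifest.json (config hash, seed, file inventory with content
    hashes) into ``out_dir`` and returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = simulate_cohort(cohort_spec, config)
    frame = results_frame(results)
    analysis = analyze_results(results)

    files = {}
    frame.to_csv(out / "thresholds.csv", index=False)
    files["thresholds.csv"] = None
    analysis["anova"].table.to_csv(out / "anova.csv")
    files["anova.csv"] = None
    posthoc_frame = pd.DataFrame(
        {name: dataclasses.asdict(res) for name, res in analysis["posthoc"].items()}
    ).T
    posthoc_frame.to_csv(out / "posthoc.csv")
    files["posthoc.csv"] = None
    if analysis["correlations"] is not None:
        analysis["correlations"].to_csv(out / "correlations.csv")
        files["correlations.csv"] = None

    for name in files:
        files[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": len(results),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
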