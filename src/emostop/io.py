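"""File formats, run configuration, cohort simulation and the pipeline.

All artifacts are plain UTF-8 CSV (dot decimal, times in milliseconds)
so that runs diff cleanly. The trial log is long-format, one row per
trial; missing values are empty fields. The run configuration is a flat
key-value YAML mapping mirroring the task and cohort parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from . import stats as stats_mod
from .participants import ParticipantParams, sample_participant
from .protocol import (
    GO_IMAGE,
    GO_SHAPE,
    STOP,
    VALENCES,
    TaskSpec,
    TrialRecord,
    build_schedule,
    run_session,
)
from .ratings import affective_bias, simulate_ratings
from .ssrt import SSRTEstimate, estimate_participant

log = logging.getLogger(__name__)

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "age_group",
    "block",
    "trial_index",
    "trial_type",
    "shape",
    "image_id",
    "image_valence",
    "stop_valence_instruction",
    "ssd_ms",
    "delay_ms",
    "rt_ms",
    "response",
    "correct",
    "stop_outcome",
]


@dataclass
class RunConfig:
    """Cohort-level run configuration."""

    n_younger: int = 39
    n_older: int = 40
    seed: int = 0
    dispersion_scale: float = 1.0
    task: TaskSpec = field(default_factory=TaskSpec)

    def __post_init__(self) -> None:
        if self.n_younger < 1 or self.n_older < 1:
            raise ValueError("cohort sizes must be >= 1")


def save_config(config: RunConfig, path: str | Path) -> None:
    flat = {
        "n_younger": config.n_younger,
        "n_older": config.n_older,
        "seed": config.seed,
        "dispersion_scale": config.dispersion_scale,
    }
    for f in dataclasses.fields(TaskSpec):
        value = getattr(config.task, f.name)
        flat[f"task_{f.name}"] = list(value) if isinstance(value, tuple) else value
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    flat = yaml.safe_load(Path(path).read_text()) or {}
    task_kw = {}
    run_kw = {}
    for key, value in flat.items():
        if key.startswith("task_"):
            name = key[len("task_") :]
            task_kw[name] = tuple(value) if isinstance(value, list) else value
        else:
            run_kw[key] = value
    return RunConfig(task=TaskSpec(**task_kw), **run_kw)


def default_image_pool(n_per_valence: int = 120) -> list[tuple[str, str]]:
    """Synthetic image identifiers standing in for the scene-image set."""
    pool = [(f"img_p_{i:03d}", "pleasant") for i in range(1, n_per_valence + 1)]
    pool += [(f"img_u_{i:03d}", "unpleasant") for i in range(1, n_per_valence + 1)]
    return pool


def records_to_frame(
    participant_id: str, age_group: str, records: list[TrialRecord]
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": participant_id,
                "age_group": age_group,
                "block": r.block,
                "trial_index": r.trial_index,
                "trial_type": r.trial_type,
                "shape": r.shape,
                "image_id": r.image_id,
                "image_valence": r.image_valence,
                "stop_valence_instruction": r.stop_valence_instruction,
                "ssd_ms": r.ssd if r.trial_type == STOP else None,
                "delay_ms": r.ssd if r.trial_type == GO_IMAGE else None,
                "rt_ms": r.rt,
                "response": r.response,
                "correct": int(r.correct),
                "stop_outcome": r.stop_outcome,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> tuple[str, str, list[TrialRecord]]:
    """Rebuild trial records from a single-participant trial-log frame."""
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("trial-log frame must hold exactly one participant")
    records = []
    for row in frame.itertuples(index=False):
        ssd = row.ssd_ms if row.trial_type == STOP else row.delay_ms
        records.append(
            TrialRecord(
                block=int(row.block),
                trial_index=int(row.trial_index),
                trial_type=row.trial_type,
                shape=row.shape,
                stop_valence_instruction=row.stop_valence_instruction,
                image_id=None if pd.isna(row.image_id) else row.image_id,
                image_valence=None if pd.isna(row.image_valence) else row.image_valence,
                ssd=None if pd.isna(ssd) else float(ssd),
                rt=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                response=row.response,
                correct=bool(int(row.correct)),
                stop_outcome=None if pd.isna(row.stop_outcome) else row.stop_outcome,
            )
        )
    return str(pids[0]), str(frame["age_group"].iloc[0]), records


def write_trial_log(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        Path(path),
        dtype={"participant_id": str, "age_group": str},
        keep_default_na=True,
        float_precision="round_trip",
    )


@dataclass
class Session:
    participant_id: str
    age_group: str
    params: ParticipantParams
    records: list[TrialRecord]


def simulate_cohort(
    config: RunConfig,
    out_dir: Optional[str | Path] = None,
    with_ratings: bool = True,
) -> tuple[dict[str, Session], Optional[pd.DataFrame]]:
    """Simulate a full cohort, optionally writing one log CSV per participant.

    The instruction order alternates across participants within each age
    group (counterbalancing). Child seeds for schedule, participant
    sampling, session noise and ratings are spawned deterministically
    from the root seed, so the schedule is invariant to participant
    parameters.
    """
    pool = default_image_pool()
    sessions: dict[str, Session] = {}
    ratings_frames = []
    manifest = {"seed": config.seed, "participants": {}}
    groups = [("younger", config.n_younger), ("older", config.n_older)]
    for group_idx, (group, n) in enumerate(groups):
        for i in range(n):
            pid = f"{group}_{i + 1:03d}"
            child = np.random.SeedSequence(entropy=config.seed, spawn_key=(group_idx, i))
            s_sched, s_part, s_sess, s_rate = [
                int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4)
            ]
            order = "stop-pleasant-first" if i % 2 == 0 else "stop-unpleasant-first"
            spec = dataclasses.replace(config.task, instruction_order=order)
            params = sample_participant(group, s_part, config.dispersion_scale)
            schedule = build_schedule(spec, pool, s_sched)
            records = run_session(spec, schedule, params, s_sess)
            sessions[pid] = Session(pid, group, params, records)
            manifest["participants"][pid] = {
                "age_group": group,
                "instruction_order": order,
                "seeds": [s_sched, s_part, s_sess, s_rate],
            }
            if with_ratings:
                ratings_frames.append(simulate_ratings(pid, params, pool, s_rate))
    ratings = pd.concat(ratings_frames, ignore_index=True) if ratings_frames else None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, sess in sessions.items():
            write_trial_log(out / f"{pid}.csv", records_to_frame(pid, sess.age_group, sess.records))
        if ratings is not None:
            ratings.to_csv(out / "ratings.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("wrote %d trial logs to %s", len(sessions), out)
    return sessions, ratings


def _participant_measures(
    records: list[TrialRecord], estimates: dict[str, SSRTEstimate]
) -> dict:
    go_shape = [r for r in records if r.trial_type == GO_SHAPE]
    out = {
        "go_shape_accuracy_pct": 100.0 * np.mean([r.correct for r in go_shape]),
        "go_shape_omissions_pct": 100.0 * np.mean([r.rt is None for r in go_shape]),
        "go_shape_rt_ms": float(
            np.mean([r.rt for r in go_shape if r.correct and r.rt is not None])
        ),
    }
    for v in VALENCES:
        stops = [
            r for r in records if r.trial_type == STOP and r.stop_valence_instruction == v
        ]
        go_imgs = [r for r in records if r.trial_type == GO_IMAGE and r.image_valence == v]
        sr_rts = [r.rt for r in stops if r.stop_outcome == "responded" and r.rt is not None]
        out[f"inhibition_{v}_pct"] = 100.0 * np.mean(
            [r.stop_outcome == "inhibited" for r in stops]
        )
        out[f"ssd_{v}_ms"] = float(np.mean([r.ssd for r in stops]))
        out[f"go_image_{v}_accuracy_pct"] = 100.0 * np.mean([r.correct for r in go_imgs])
        out[f"go_image_{v}_rt_ms"] = float(
            np.mean([r.rt for r in go_imgs if r.correct and r.rt is not None])
        )
        out[f"failed_stop_{v}_rt_ms"] = float(np.mean(sr_rts)) if sr_rts else np.nan
        est = estimates.get(v)
        out[f"ssrt_{v}_ms"] = est.ssrt if est is not None else np.nan
        out[f"n_blocks_{v}"] = est.n_blocks_used if est is not None else 0
    return out


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    ssrt: pd.DataFrame  # long: participant, age_group, condition, ssrt_ms, n_blocks_used
    measures: pd.DataFrame  # wide per-participant descriptive measures
    descriptives: pd.DataFrame  # group-level M (SD) per measure
    anova: dict[str, stats_mod.TestResult]
    race_checks: pd.DataFrame
    ancova: Optional[dict[str, stats_mod.TestResult]] = None
    bias_scores: Optional[pd.DataFrame] = None


DESCRIPTIVE_MEASURES = [
    "inhibition_unpleasant_pct",
    "inhibition_pleasant_pct",
    "ssd_unpleasant_ms",
    "ssd_pleasant_ms",
    "ssrt_unpleasant_ms",
    "ssrt_pleasant_ms",
    "go_shape_accuracy_pct",
    "go_shape_omissions_pct",
    "go_shape_rt_ms",
    "go_image_unpleasant_rt_ms",
    "go_image_pleasant_rt_ms",
    "failed_stop_unpleasant_rt_ms",
    "failed_stop_pleasant_rt_ms",
]


def run_pipeline(
    sessions: dict[str, Session],
    ratings: Optional[pd.DataFrame] = None,
    with_ancova: bool = False,
) -> PipelineResult:
    """QC → SSRT estimation → descriptives → mixed ANOVA (± ANCOVA)."""
    qc_rows, measure_rows, ssrt_rows = [], [], []
    retained_sessions: dict[str, list[TrialRecord]] = {}
    for pid, sess in sessions.items():
        report = qc_mod.qc_participant(pid, sess.records)
        qc_rows.append(
            {
                "participant_id": pid,
                "age_group": sess.age_group,
                "excluded": report.participant_excluded,
                "reason": report.exclusion_reason,
                "n_blocks_excluded": len(report.blocks_excluded),
                "blocks_excluded": ";".join(f"{b}:{r}" for b, r in report.blocks_excluded),
                "fast_go_flags": report.fast_go_flags,
            }
        )
        if report.participant_excluded:
            log.info("excluding %s: %s", pid, report.exclusion_reason)
            continue
        retained_sessions[pid] = sess.records
        retained = report.retained_blocks
        estimable = [c for c, ok in sorted(report.estimable.items()) if ok]
        for condition in set(report.estimable) - set(estimable):
            log.info("%s/%s not estimable (<2 retained blocks)", pid, condition)
        estimates = estimate_participant(sess.records, retained, conditions=estimable)
        measures = _participant_measures(sess.records, estimates)
        measures.update({"participant_id": pid, "age_group": sess.age_group})
        measure_rows.append(measures)
        for condition, est in estimates.items():
            ssrt_rows.append(
                {
                    "participant_id": pid,
                    "age_group": sess.age_group,
                    "condition": condition,
                    "ssrt_ms": est.ssrt,
                    "n_blocks_used": est.n_blocks_used,
                }
            )
    qc_df = pd.DataFrame(qc_rows)
    ssrt_df = pd.DataFrame(ssrt_rows)
    measures_df = pd.DataFrame(measure_rows)

    rows = []
    for measure in DESCRIPTIVE_MEASURES:
        row = {"measure": measure}
        for group, sub in measures_df.groupby("age_group"):
            row[f"{group}_mean"] = float(sub[measure].mean())
            row[f"{group}_sd"] = float(sub[measure].std(ddof=1))
        rows.append(row)
    descriptives = pd.DataFrame(rows)

    complete = ssrt_df.groupby("participant_id")["condition"].nunique()
    keep = complete[complete == 2].index
    anova_data = ssrt_df[ssrt_df["participant_id"].isin(keep)].rename(
        columns={"age_group": "group", "condition": "condition", "ssrt_ms": "value"}
    )
    anova = stats_mod.mixed_anova_2x2(anova_data)

    per_rows, _cohort = qc_mod.race_model_check(retained_sessions)
    race_df = pd.DataFrame(per_rows)

    ancova = bias_scores = None
    if with_ancova:
        if ratings is None:
            raise ValueError("ANCOVA requested but no ratings table supplied")
        bias_scores = affective_bias(ratings)
        ancova = stats_mod.ancova_2x2_mixed(anova_data, bias_scores["bias"])
    return PipelineResult(
        qc=qc_df,
        ssrt=ssrt_df,
        measures=measures_df,
        descriptives=descriptives,
        anova=anova,
        race_checks=race_df,
        ancova=ancova,
        bias_scores=bias_scores,
    )


def anova_table(results: dict[str, stats_mod.TestResult]) -> pd.DataFrame:
    rows = []
    for effect, res in results.items():
        rows.append(
            {
                "effect": effect,
                "F": res.statistic,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "partial_eta_sq": res.effect_size,
            }
        )
    return pd.DataFrame(rows)
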