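"""Data-validity screening for stop-signal sessions.

Three layers, applied before estimation and inference:

* participant screening — a session is dropped when the go-image miss
  rate exceeds 33% for either valence (possible instruction confusion or
  atypical valence interpretation);
* block filtering — a block is dropped when go-image accuracy falls
  below 66% or when stopping accuracy leaves the 25-75% band in which
  the adaptive staircase can be trusted;
* race-model checks — mean signal-respond RT must be faster than mean
  go RT of every go trial type, per participant and stop-valence
  condition; violation questions the independent-race assumptions that
  give the SSRT its meaning.

A participant-condition enters analysis only with at least two retained
blocks under that stop instruction. Go-shape RTs under 150 ms are
counted as a diagnostic (anticipations), not an exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .protocol import GO_IMAGE, GO_SHAPE, STOP, VALENCES, TrialRecord
from .ssrt import BlockData, blocks_from_records

__all__ = [
    "QCReport",
    "screen_participant",
    "filter_blocks",
    "min_blocks_gate",
    "race_model_check",
    "qc_participant",
]

MISS_RATE_LIMIT = 1 / 3  # participant excluded strictly above this, per valence
GO_IMAGE_ACCURACY_MIN = 0.66  # block dropped strictly below
STOP_ACCURACY_BOUNDS = (0.25, 0.75)  # inclusive band; blocks outside dropped
FAST_GO_THRESHOLD = 150.0  # ms; anticipation diagnostic


@dataclass
class QCReport:
    participant_id: str
    participant_excluded: bool = False
    exclusion_reason: Optional[str] = None
    blocks_excluded: list[tuple[int, str]] = field(default_factory=list)
    blocks_retained_per_instruction: dict[str, int] = field(default_factory=dict)
    estimable: dict[str, bool] = field(default_factory=dict)
    fast_go_flags: int = 0

    @property
    def retained_blocks(self) -> set[int]:
        excluded = {b for b, _ in self.blocks_excluded}
        total = sum(self.blocks_retained_per_instruction.values()) + len(excluded)
        return {b for b in range(1, total + 1)} - excluded


def _go_image_miss_rates(records: Iterable[TrialRecord]) -> dict[str, float]:
    counts = {v: [0, 0] for v in VALENCES}  # misses, total
    for rec in records:
        if rec.trial_type != GO_IMAGE:
            continue
        misses, total = counts[rec.image_valence]
        counts[rec.image_valence] = [misses + (not rec.correct), total + 1]
    for v, (_, total) in counts.items():
        if total == 0:
            raise ValueError(f"session has no {v} go-image trials")
    return {v: m / t for v, (m, t) in counts.items()}


def screen_participant(records: Sequence[TrialRecord]) -> tuple[bool, Optional[str]]:
    """Participant-level gate on go-image miss rate.

    A miss is any go-image trial without a correct completed response
    (omission, incorrect withhold, or wrong key). Returns
    ``(excluded, reason)``; the boundary itself (exactly 33%) is
    retained.
    """
    rates = _go_image_miss_rates(records)
    for valence, rate in rates.items():
        if rate > MISS_RATE_LIMIT:
            return True, f"go-image miss rate {rate:.1%} for {valence} images exceeds 33%"
    return False, None


def filter_blocks(records: Sequence[TrialRecord]) -> list[tuple[int, str]]:
    """Block-level exclusions; returns ``(block, primary rule)`` pairs.

    The go-image accuracy rule is evaluated first; a block failing both
    rules is labelled with it.
    """
    excluded = []
    for blk in blocks_from_records(records):
        if blk.go_image_accuracy < GO_IMAGE_ACCURACY_MIN:
            excluded.append((blk.block, "go_image_accuracy<66%"))
            continue
        lo, hi = STOP_ACCURACY_BOUNDS
        if not lo <= blk.stop_accuracy <= hi:
            excluded.append((blk.block, "stop_accuracy_outside_25-75%"))
    return excluded


def min_blocks_gate(retained_per_instruction: dict[str, int], minimum: int = 2) -> dict[str, bool]:
    """Per stop instruction: estimable iff at least ``minimum`` retained blocks."""
    return {cond: n >= minimum for cond, n in retained_per_instruction.items()}


def qc_participant(participant_id: str, records: Sequence[TrialRecord]) -> QCReport:
    """Run the participant and block rules for one session."""
    report = QCReport(participant_id=participant_id)
    report.participant_excluded, report.exclusion_reason = screen_participant(records)
    report.blocks_excluded = filter_blocks(records)
    dropped = {b for b, _ in report.blocks_excluded}
    blocks = blocks_from_records(records)
    per_instruction: dict[str, int] = {v: 0 for v in VALENCES}
    for blk in blocks:
        if blk.block not in dropped:
            per_instruction[blk.stop_valence_instruction] += 1
    report.blocks_retained_per_instruction = per_instruction
    report.estimable = min_blocks_gate(per_instruction)
    report.fast_go_flags = sum(
        1
        for rec in records
        if rec.trial_type == GO_SHAPE and rec.rt is not None and rec.rt < FAST_GO_THRESHOLD
    )
    return report


def _participant_check_row(
    participant_id: str, records: Sequence[TrialRecord], condition: str
) -> Optional[dict]:
    srrt = [
        rec.rt
        for rec in records
        if rec.trial_type == STOP
        and rec.stop_valence_instruction == condition
        and rec.stop_outcome == "responded"
        and rec.rt is not None
    ]
    if not srrt:
        return None
    go_shape = [r.rt for r in records if r.trial_type == GO_SHAPE and r.rt is not None]
    go_image = {
        v: [
            r.rt
            for r in records
            if r.trial_type == GO_IMAGE and r.image_valence == v and r.rt is not None
        ]
        for v in VALENCES
    }
    row = {
        "participant_id": participant_id,
        "condition": condition,
        "mean_signal_respond_rt": float(np.mean(srrt)),
        "mean_go_shape_rt": float(np.mean(go_shape)) if go_shape else np.nan,
    }
    for v in VALENCES:
        row[f"mean_go_image_{v}_rt"] = float(np.mean(go_image[v])) if go_image[v] else np.nan
    go_means = [row["mean_go_shape_rt"]] + [row[f"mean_go_image_{v}_rt"] for v in VALENCES]
    row["passes"] = bool(
        all(np.isnan(m) or row["mean_signal_respond_rt"] < m for m in go_means)
    )
    return row


def race_model_check(
    sessions: dict[str, Sequence[TrialRecord]],
) -> tuple[list[dict], list[dict]]:
    """Race-model validity over a cohort.

    For every participant and stop-valence condition, compares mean
    signal-respond RT with the mean RT of each go trial type; at cohort
    level, paired t-tests over participants for each comparison.
    Returns ``(per_participant_rows, cohort_tests)``. Participants
    without signal-respond trials in a condition are skipped with a
    flag row.
    """
    rows: list[dict] = []
    for pid, records in sessions.items():
        for condition in VALENCES:
            row = _participant_check_row(pid, records, condition)
            if row is None:
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": condition,
                        "skipped": True,
                        "passes": None,
                    }
                )
            else:
                row["skipped"] = False
                rows.append(row)
    cohort: list[dict] = []
    usable = [r for r in rows if not r["skipped"]]
    go_columns = ["mean_go_shape_rt"] + [f"mean_go_image_{v}_rt" for v in VALENCES]
    for condition in VALENCES:
        sub = [r for r in usable if r["condition"] == condition]
        for col in go_columns:
            pairs = [
                (r["mean_signal_respond_rt"], r[col]) for r in sub if not np.isnan(r[col])
            ]
            if len(pairs) < 2:
                continue
            sr, go = map(np.asarray, zip(*pairs))
            t, p = sps.ttest_rel(sr, go)
            cohort.append(
                {
                    "condition": condition,
                    "go_measure": col,
                    "n": len(pairs),
                    "mean_signal_respond": float(np.mean(sr)),
                    "mean_go": float(np.mean(go)),
                    "t": float(t),
                    "p": float(p),
                    "passes": bool(np.mean(sr) < np.mean(go)),
                }
            )
    return rows, cohort
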