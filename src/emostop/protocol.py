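"""Emotional stop-signal task protocol: schedule, staircase, session runner.

The task interleaves three trial types. On *go-shape* trials a circle or
square appears and the participant presses the left (circle) or right
(square) arrow key. On *stop* trials an emotional scene image of the
block's stop valence appears inside the shape after the stop-signal delay
(SSD) and the response must be withheld. On *go-image* trials an image of
the opposite valence appears after a delay yoked to the most recent SSD
and the response must be completed.

A session is 480 trials in six 80-trial blocks (20 stop / 40 go-shape /
20 go-image each). Blocks 1-3 carry one stop-valence instruction, blocks
4-6 the other. Each stop-valence condition has its own one-up/one-down
SSD staircase (50 ms steps, start 250 ms, bounds 50-950 ms) which starts
fresh when the instruction changes between blocks three and four.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .participants import ParticipantParams, respond_go, respond_stop

GO_SHAPE = "go_shape"
GO_IMAGE = "go_image"
STOP = "stop"

PLEASANT = "pleasant"
UNPLEASANT = "unpleasant"
VALENCES = (PLEASANT, UNPLEASANT)

SHAPE_KEY = {"circle": "left", "square": "right"}


@dataclass(frozen=True)
class TaskSpec:
    """Structural parameters of the task protocol (times in ms)."""

    n_blocks: int = 6
    trials_per_block: int = 80
    n_stop_per_block: int = 20
    n_go_shape_per_block: int = 40
    n_go_image_per_block: int = 20
    shape_duration: float = 1000.0
    image_duration: float = 2000.0
    trial_duration: float = 3000.0
    iti_range: tuple[float, float] = (900.0, 1100.0)
    ssd_start: float = 250.0
    ssd_step: float = 50.0
    ssd_min: float = 50.0
    ssd_max: float = 950.0
    max_go_rt: float = 1000.0
    instruction_order: str = "stop-pleasant-first"
    # Pseudo-randomization constraints (configurable; see build_schedule).
    n_leading_go_shape: int = 2
    max_consecutive_non_shape: int = 2

    def __post_init__(self) -> None:
        if (
            self.n_stop_per_block
            + self.n_go_shape_per_block
            + self.n_go_image_per_block
            != self.trials_per_block
        ):
            raise ValueError("per-block trial counts must sum to trials_per_block")
        if not self.ssd_min <= self.ssd_start <= self.ssd_max:
            raise ValueError("ssd_start must lie within [ssd_min, ssd_max]")
        for span in (self.ssd_start - self.ssd_min, self.ssd_max - self.ssd_start):
            if abs(span / self.ssd_step - round(span / self.ssd_step)) > 1e-9:
                raise ValueError("SSD bounds must be integer multiples of ssd_step from ssd_start")
        if self.instruction_order not in ("stop-pleasant-first", "stop-unpleasant-first"):
            raise ValueError(f"unknown instruction_order: {self.instruction_order!r}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def stop_valence_for_block(self, block: int) -> str:
        """Stop-valence instruction in effect for 1-based block index."""
        first = PLEASANT if self.instruction_order == "stop-pleasant-first" else UNPLEASANT
        second = UNPLEASANT if first == PLEASANT else PLEASANT
        return first if block <= self.n_blocks // 2 else second


class SSDTracker:
    """One-up/one-down staircase for one stop-valence condition.

    ``current_ssd`` is the delay the *next* stop trial will use. The
    history stores ``(trial_index, ssd_used, stop_outcome)`` for every
    stop trial run under this tracker.
    """

    def __init__(self, spec: TaskSpec, condition: str):
        self.spec = spec
        self.condition = condition
        self.current_ssd = float(spec.ssd_start)
        self.history: list[tuple[int, float, str]] = []

    @property
    def last_used_ssd(self) -> Optional[float]:
        return self.history[-1][1] if self.history else None

    def update(self, stop_outcome: str, trial_index: int = -1) -> "SSDTracker":
        """Record a stop trial at the current SSD and step the staircase.

        Successful inhibition lengthens the next delay by one step
        (harder); a responded stop trial shortens it (easier). The delay
        is clamped to [ssd_min, ssd_max].
        """
        if stop_outcome not in ("inhibited", "responded"):
            raise ValueError(f"unknown stop outcome: {stop_outcome!r}")
        self.history.append((trial_index, self.current_ssd, stop_outcome))
        step = self.spec.ssd_step if stop_outcome == "inhibited" else -self.spec.ssd_step
        self.current_ssd = float(
            min(self.spec.ssd_max, max(self.spec.ssd_min, self.current_ssd + step))
        )
        return self


def staircase_update(tracker: SSDTracker, stop_outcome: str, trial_index: int = -1) -> SSDTracker:
    """Functional wrapper around :meth:`SSDTracker.update`."""
    return tracker.update(stop_outcome, trial_index)


def yoke_go_image_delay(tracker: SSDTracker) -> float:
    """Delay between shape onset and go-image onset.

    Yoked to the SSD actually used on the most recent stop trial of the
    current instruction half; before any stop trial has run it equals the
    staircase starting value. Go-image outcomes never feed back into the
    staircase.
    """
    last = tracker.last_used_ssd
    return float(last) if last is not None else float(tracker.spec.ssd_start)


@dataclass(frozen=True)
class TrialPlan:
    block: int
    trial_index: int
    trial_type: str
    shape: str
    stop_valence_instruction: str
    image_id: Optional[str] = None
    image_valence: Optional[str] = None


@dataclass
class TrialRecord:
    block: int
    trial_index: int
    trial_type: str
    shape: str
    stop_valence_instruction: str
    image_id: Optional[str] = None
    image_valence: Optional[str] = None
    ssd: Optional[float] = None  # stop trials: SSD; go-image trials: yoked delay
    rt: Optional[float] = None
    response: str = "none"
    correct: bool = False
    stop_outcome: Optional[str] = None


def _check_image_pool(pool: Sequence[tuple[str, str]], needed_per_valence: int) -> dict:
    by_valence: dict[str, list[str]] = {PLEASANT: [], UNPLEASANT: []}
    seen = set()
    for image_id, valence in pool:
        if image_id in seen:
            raise ValueError(f"duplicate image id in pool: {image_id!r}")
        seen.add(image_id)
        if valence not in by_valence:
            raise ValueError(f"unknown valence {valence!r} for image {image_id!r}")
        by_valence[valence].append(image_id)
    for valence, ids in by_valence.items():
        if len(ids) < needed_per_valence:
            raise ValueError(
                f"image pool has {len(ids)} {valence} images; {needed_per_valence} required"
            )
    return by_valence


def _block_type_sequence(spec: TaskSpec, rng: np.random.Generator) -> list[str]:
    """Pseudo-randomized trial-type order for one block.

    Constrained shuffle: the first ``n_leading_go_shape`` trials are
    go-shape (to establish response prepotency) and runs of non-go-shape
    trials are capped at ``max_consecutive_non_shape``. Non-shape slots
    are allocated into the gaps around the remaining go-shape trials,
    then stop / go-image labels are shuffled over them.
    """
    n_lead = spec.n_leading_go_shape
    n_shape_rest = spec.n_go_shape_per_block - n_lead
    n_other = spec.n_stop_per_block + spec.n_go_image_per_block
    cap = spec.max_consecutive_non_shape
    n_gaps = n_shape_rest + 1  # after the lead block: before each G and after the last
    if n_gaps * cap < n_other:
        raise ValueError("randomization constraints are infeasible for this composition")
    gap_counts = np.zeros(n_gaps, dtype=int)
    for _ in range(n_other):
        open_gaps = np.flatnonzero(gap_counts < cap)
        gap_counts[int(rng.choice(open_gaps))] += 1

    labels = [STOP] * spec.n_stop_per_block + [GO_IMAGE] * spec.n_go_image_per_block
    labels = [labels[i] for i in rng.permutation(n_other)]
    it = iter(labels)

    seq = [GO_SHAPE] * n_lead
    for g in range(n_gaps):
        seq.extend(next(it) for _ in range(gap_counts[g]))
        if g < n_shape_rest:
            seq.append(GO_SHAPE)
    assert len(seq) == spec.trials_per_block
    return seq


def build_schedule(
    spec: TaskSpec,
    image_pool: Sequence[tuple[str, str]],
    seed: int,
) -> list[TrialPlan]:
    """Build the full pseudo-randomized session schedule.

    Each scene image occurs exactly once per session: per half, stop
    trials draw images of the instruction valence and go-image trials
    draw the opposite valence, without replacement. The schedule is a
    deterministic function of ``(spec, image_pool, seed)`` and does not
    depend on who performs it.
    """
    half_blocks = spec.n_blocks // 2
    needed = spec.n_stop_per_block * half_blocks + spec.n_go_image_per_block * half_blocks
    by_valence = _check_image_pool(image_pool, needed)
    rng = np.random.default_rng(seed)
    stacks = {v: list(np.array(ids)[rng.permutation(len(ids))]) for v, ids in by_valence.items()}

    plans: list[TrialPlan] = []
    trial_index = 0
    for block in range(1, spec.n_blocks + 1):
        stop_valence = spec.stop_valence_for_block(block)
        go_valence = UNPLEASANT if stop_valence == PLEASANT else PLEASANT
        types = _block_type_sequence(spec, rng)
        n_circle = spec.trials_per_block // 2
        shapes = ["circle"] * n_circle + ["square"] * (spec.trials_per_block - n_circle)
        shapes = [shapes[i] for i in rng.permutation(spec.trials_per_block)]
        for ttype, shape in zip(types, shapes):
            trial_index += 1
            image_id = image_valence = None
            if ttype == STOP:
                image_id, image_valence = stacks[stop_valence].pop(), stop_valence
            elif ttype == GO_IMAGE:
                image_id, image_valence = stacks[go_valence].pop(), go_valence
            plans.append(
                TrialPlan(
                    block=block,
                    trial_index=trial_index,
                    trial_type=ttype,
                    shape=shape,
                    stop_valence_instruction=stop_valence,
                    image_id=image_id,
                    image_valence=image_valence,
                )
            )
    return plans


def _keypress(shape: str, pressed_correct_key: bool) -> str:
    correct = SHAPE_KEY[shape]
    if pressed_correct_key:
        return correct
    return "right" if correct == "left" else "left"


def run_session(
    spec: TaskSpec,
    schedule: Sequence[TrialPlan],
    participant: ParticipantParams,
    seed: int,
) -> list[TrialRecord]:
    """Drive a race-model participant through a schedule.

    Separate SSD staircases are maintained for the pleasant and
    unpleasant stop conditions; each starts at ``ssd_start`` when its
    instruction half begins. Responses later than the trial window
    (``trial_duration``) count as omissions; responses between
    ``max_go_rt`` and the window end are retained as (slow) responses.
    """
    rng = np.random.default_rng(seed)
    trackers = {v: SSDTracker(spec, v) for v in VALENCES}
    records: list[TrialRecord] = []
    for plan in schedule:
        rec = TrialRecord(
            block=plan.block,
            trial_index=plan.trial_index,
            trial_type=plan.trial_type,
            shape=plan.shape,
            stop_valence_instruction=plan.stop_valence_instruction,
            image_id=plan.image_id,
            image_valence=plan.image_valence,
        )
        if plan.trial_type == STOP:
            tracker = trackers[plan.stop_valence_instruction]
            ssd = tracker.current_ssd
            outcome, rt = respond_stop(participant, ssd, rng)
            if rt is not None and rt > spec.trial_duration:
                outcome, rt = "inhibited", None  # escaped response landed after the window
            tracker.update(outcome, plan.trial_index)
            rec.ssd = ssd
            rec.stop_outcome = outcome
            if outcome == "responded":
                pressed_ok = rng.random() >= participant.p_choice_error
                rec.rt = rt
                rec.response = _keypress(plan.shape, pressed_ok)
            rec.correct = outcome == "inhibited"
        else:
            if plan.trial_type == GO_IMAGE:
                rec.ssd = yoke_go_image_delay(trackers[plan.stop_valence_instruction])
            rt, pressed_ok = respond_go(
                participant, plan.trial_type, plan.image_valence, rng
            )
            if rt is not None and rt > spec.trial_duration:
                rt, pressed_ok = None, None
            if rt is None:
                rec.response, rec.correct = "none", False
            else:
                rec.rt = rt
                rec.response = _keypress(plan.shape, bool(pressed_ok))
                rec.correct = bool(pressed_ok)
        records.append(rec)
    return records
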