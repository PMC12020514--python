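"""Block-based integration estimation of stop-signal reaction time.

SSRT is the latent latency of the stopping process. The integration
estimator assumes the independent race model: on a stop trial with delay
SSD the response escapes iff the go process finishes before SSD + SSRT,
so the fraction of stop trials with a response, p(respond|signal),
identifies the point of the go-RT distribution that the stopping process
cuts off. Per block:

    nth_go_rt  = go-shape RT at rank ceil(p_respond * N_go)  (sorted, 1-based)
    block_ssrt = nth_go_rt - mean SSD over the block's stop trials

with each go-shape omission replaced by the maximum allowable go
response time (1000 ms by default) before sorting. Choice-error go
trials keep their RTs in the distribution by default. A participant's
per-condition SSRT is the arithmetic mean of block SSRTs over retained
blocks (at least two per stop instruction); estimating per block and
averaging absorbs slow drifts in go RT (strategic slowing, fatigue)
that would bias a whole-session estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .protocol import GO_IMAGE, GO_SHAPE, STOP, TrialRecord

__all__ = [
    "BlockData",
    "SSRTEstimate",
    "blocks_from_records",
    "p_respond",
    "integration_ssrt_block",
    "ssrt_condition",
    "estimate_participant",
]


@dataclass
class BlockData:
    """Per-block trial data needed by QC and the integration estimator."""

    block: int
    stop_valence_instruction: str
    go_shape_rts: list[Optional[float]]  # None marks an omission
    go_shape_correct: list[bool]  # aligned with go_shape_rts; omissions False
    stop_ssds: list[float]
    stop_outcomes: list[str]
    signal_respond_rts: list[float]
    go_image_valence: list[str]
    go_image_correct: list[bool]
    go_image_rts: list[Optional[float]]

    @property
    def n_go_shape(self) -> int:
        return len(self.go_shape_rts)

    @property
    def n_stop(self) -> int:
        return len(self.stop_ssds)

    @property
    def stop_accuracy(self) -> float:
        """Fraction of stop trials successfully inhibited."""
        return 1.0 - p_respond(self)

    @property
    def go_image_accuracy(self) -> float:
        if not self.go_image_correct:
            raise ValueError(f"block {self.block} has no go-image trials")
        return float(np.mean(self.go_image_correct))


def blocks_from_records(records: Iterable[TrialRecord]) -> list[BlockData]:
    """Group a session's trial records into per-block data."""
    by_block: dict[int, BlockData] = {}
    for rec in records:
        blk = by_block.get(rec.block)
        if blk is None:
            blk = by_block[rec.block] = BlockData(
                block=rec.block,
                stop_valence_instruction=rec.stop_valence_instruction,
                go_shape_rts=[],
                go_shape_correct=[],
                stop_ssds=[],
                stop_outcomes=[],
                signal_respond_rts=[],
                go_image_valence=[],
                go_image_correct=[],
                go_image_rts=[],
            )
        if rec.trial_type == GO_SHAPE:
            blk.go_shape_rts.append(rec.rt)
            blk.go_shape_correct.append(bool(rec.correct))
        elif rec.trial_type == STOP:
            blk.stop_ssds.append(float(rec.ssd))
            blk.stop_outcomes.append(rec.stop_outcome)
            if rec.stop_outcome == "responded" and rec.rt is not None:
                blk.signal_respond_rts.append(float(rec.rt))
        elif rec.trial_type == GO_IMAGE:
            blk.go_image_valence.append(rec.image_valence)
            blk.go_image_correct.append(bool(rec.correct))
            blk.go_image_rts.append(rec.rt)
    return [by_block[b] for b in sorted(by_block)]


def p_respond(block: BlockData) -> float:
    """Fraction of the block's stop trials on which a response escaped."""
    if block.n_stop == 0:
        raise ValueError(f"block {block.block} has no stop trials")
    responded = sum(1 for o in block.stop_outcomes if o == "responded")
    return responded / block.n_stop


def _go_distribution(
    block: BlockData, max_go_rt: float, include_choice_errors: bool
) -> np.ndarray:
    rts = []
    for rt, correct in zip(block.go_shape_rts, block.go_shape_correct):
        if rt is None:
            rts.append(max_go_rt)  # omission replacement
        elif correct or include_choice_errors:
            rts.append(rt)
    return np.sort(np.asarray(rts, dtype=float))


def integration_ssrt_block(
    block: BlockData,
    max_go_rt: float = 1000.0,
    include_choice_errors: bool = True,
    rank_method: str = "ceiling",
) -> tuple[float, dict]:
    """Integration SSRT for a single block.

    ``rank_method='ceiling'`` takes the sorted go RT at 1-based rank
    ``ceil(p_respond * N)``; ``'interpolate'`` instead evaluates the
    linearly interpolated empirical quantile at ``p_respond``. Blocks
    where every stop trial was (or was not) inhibited do not identify
    the quantile and raise.
    """
    pr = p_respond(block)
    if pr <= 0.0 or pr >= 1.0:
        raise ValueError(
            f"block {block.block}: p_respond={pr:g} leaves the integration SSRT undefined"
        )
    go = _go_distribution(block, max_go_rt, include_choice_errors)
    if go.size == 0:
        raise ValueError(f"block {block.block} has an empty go distribution")
    if rank_method == "ceiling":
        rank = math.ceil(pr * go.size)
        nth_go_rt = float(go[rank - 1])
    elif rank_method == "interpolate":
        nth_go_rt = float(np.quantile(go, pr))
    else:
        raise ValueError(f"unknown rank_method {rank_method!r}")
    mean_ssd = float(np.mean(block.stop_ssds))
    ssrt = nth_go_rt - mean_ssd
    diagnostics = {
        "block": block.block,
        "p_respond": pr,
        "n_go": int(go.size),
        "n_omissions": sum(1 for rt in block.go_shape_rts if rt is None),
        "nth_go_rt": nth_go_rt,
        "mean_ssd": mean_ssd,
        "block_ssrt": ssrt,
    }
    return ssrt, diagnostics


@dataclass
class SSRTEstimate:
    """Per-condition SSRT with per-block components."""

    condition: str
    per_block: list[dict] = field(default_factory=list)
    ssrt: float = float("nan")
    n_blocks_used: int = 0

    @property
    def estimable(self) -> bool:
        return self.n_blocks_used >= 2


def ssrt_condition(
    blocks: Sequence[BlockData],
    retained: Optional[set[int]] = None,
    condition: Optional[str] = None,
    max_go_rt: float = 1000.0,
    include_choice_errors: bool = True,
    rank_method: str = "ceiling",
    min_blocks: int = 2,
) -> SSRTEstimate:
    """Average block SSRTs over retained blocks of one stop instruction.

    Raises if fewer than ``min_blocks`` retained blocks exist for the
    condition (the participant-condition is then not estimable).
    """
    use = [
        b
        for b in blocks
        if (condition is None or b.stop_valence_instruction == condition)
        and (retained is None or b.block in retained)
    ]
    if condition is None:
        conditions = {b.stop_valence_instruction for b in use}
        if len(conditions) > 1:
            raise ValueError("blocks span multiple stop instructions; pass condition=")
        condition = conditions.pop() if conditions else "unknown"
    if len(use) < min_blocks:
        raise ValueError(
            f"condition {condition!r}: only {len(use)} retained block(s); {min_blocks} required"
        )
    per_block = []
    for b in use:
        _, diag = integration_ssrt_block(b, max_go_rt, include_choice_errors, rank_method)
        per_block.append(diag)
    ssrt = float(np.mean([d["block_ssrt"] for d in per_block]))
    return SSRTEstimate(
        condition=condition, per_block=per_block, ssrt=ssrt, n_blocks_used=len(per_block)
    )


def estimate_participant(
    records: Iterable[TrialRecord],
    retained: Optional[set[int]] = None,
    conditions: Optional[Iterable[str]] = None,
    **kwargs,
) -> dict[str, SSRTEstimate]:
    """Estimate SSRT per stop-valence condition of one session.

    ``conditions`` restricts estimation to the listed instructions
    (e.g. the ones QC judged estimable); by default all instructions
    present in the records are estimated.
    """
    blocks = blocks_from_records(records)
    if conditions is None:
        conditions = sorted({b.stop_valence_instruction for b in blocks})
    out: dict[str, SSRTEstimate] = {}
    for condition in conditions:
        out[condition] = ssrt_condition(blocks, retained, condition=condition, **kwargs)
    return out
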