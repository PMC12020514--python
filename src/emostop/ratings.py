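"""Post-task image ratings: concordance and affective bias.

After the task, participants rate every scene image as pleasant or
unpleasant. Agreement with the published normative label is computed
separately per normative valence; the affective bias score is

    bias = agree_pleasant − agree_unpleasant

so a participant who calls some normatively unpleasant images pleasant
scores positive (a more positive outlook than the norms) and vice
versa. The bias score is the subject-level covariate for the
covariate-adjusted SSRT analyses.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .participants import ParticipantParams

log = logging.getLogger(__name__)

__all__ = ["validate_ratings", "concordance", "affective_bias", "simulate_ratings"]

REQUIRED_COLUMNS = ["participant_id", "image_id", "normative_valence", "rating"]


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Check the ratings table schema and drop non-responses (logged)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    if table.duplicated(["participant_id", "image_id"]).any():
        raise ValueError("duplicate (participant, image) rating rows")
    n_blank = int(table["rating"].isna().sum())
    if n_blank:
        log.info("dropping %d rating non-responses", n_blank)
    table = table.dropna(subset=["rating"])
    bad = set(table["normative_valence"]) | set(table["rating"])
    if not bad <= {"pleasant", "unpleasant"}:
        raise ValueError(f"unexpected valence labels: {sorted(bad - {'pleasant', 'unpleasant'})}")
    return table


def concordance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant agreement with normative labels, split by valence.

    Returns a frame indexed by participant with columns
    ``agree_pleasant`` and ``agree_unpleasant``. Every participant must
    have rated images of both normative valences.
    """
    table = validate_ratings(table)
    if table.empty:
        raise ValueError("empty ratings table")
    agree = (
        table.assign(agree=(table["rating"] == table["normative_valence"]).astype(float))
        .groupby(["participant_id", "normative_valence"])["agree"]
        .mean()
        .unstack("normative_valence")
    )
    for valence in ("pleasant", "unpleasant"):
        if valence not in agree.columns or agree[valence].isna().any():
            bad = (
                list(agree.index[agree[valence].isna()])
                if valence in agree.columns
                else list(agree.index)
            )
            raise ValueError(f"participants missing {valence} normative images: {bad[:5]}")
    return agree.rename(
        columns={"pleasant": "agree_pleasant", "unpleasant": "agree_unpleasant"}
    )[["agree_pleasant", "agree_unpleasant"]]


def affective_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Concordance plus the bias score (agree_pleasant − agree_unpleasant)."""
    scores = concordance(table)
    scores["bias"] = scores["agree_pleasant"] - scores["agree_unpleasant"]
    return scores


def simulate_ratings(
    participant_id: str,
    params: ParticipantParams,
    image_pool: list[tuple[str, str]],
    seed: int,
) -> pd.DataFrame:
    """Synthesize one participant's binary ratings of the image pool.

    Each rating independently matches the normative label with the
    participant's per-valence agreement probability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for image_id, valence in image_pool:
        agree = rng.random() < params.p_rating_agreement[valence]
        rating = valence if agree else ("unpleasant" if valence == "pleasant" else "pleasant")
        rows.append(
            {
                "participant_id": participant_id,
                "image_id": image_id,
                "normative_valence": valence,
                "rating": rating,
            }
        )
    return pd.DataFrame(rows)
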