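"""Synthetic participants: independent horse-race generative model.

Each participant is a set of generative parameters for the independent
race model. Go finishing times on shape trials are ex-Gaussian
(Gaussian ``mu, sigma`` plus exponential ``tau``); on go-image trials a
valence-specific appraisal cost is added, reflecting the extra time
needed to classify the scene image as "continue" before completing the
keypress. The stop process finishing time is normal (``ssrt_mean,
ssrt_sd``), truncated at zero. On a stop trial the response escapes
inhibition iff the go process finishes before SSD + stop finishing
time; the racing go process is the shape-discrimination process, so
signal-respond times are a censored (fast) sample of the go-shape
distribution — the context-independence tenet the estimator relies on.

Age-group presets are calibrated so that cohorts simulated through the
full protocol reproduce the qualitative structure of observed younger /
older behavior: older adults respond more slowly, stop more slowly, and
make more errors on unpleasant go-images, with only a small valence gap
in younger adults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ParticipantParams",
    "AgePreset",
    "PRESETS",
    "preset_names",
    "sample_participant",
    "respond_go",
    "respond_stop",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Race-model generative parameters for one synthetic subject (ms)."""

    go_mu: float
    go_sigma: float
    go_tau: float
    image_appraisal_shift: dict[str, float]  # per valence, added on go-image trials
    ssrt_mean: float
    ssrt_sd: float
    p_go_omission: float
    p_choice_error: float
    p_trigger_failure: float
    p_image_wrong_action: dict[str, float]  # per valence
    p_rating_agreement: dict[str, float]  # post-task image rating vs normative label
    age_group: str

    def __post_init__(self) -> None:
        probs = [self.p_go_omission, self.p_choice_error, self.p_trigger_failure]
        probs += list(self.p_image_wrong_action.values())
        probs += list(self.p_rating_agreement.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.go_sigma, self.go_tau, self.ssrt_sd) < 0:
            raise ValueError("scale parameters must be non-negative")


@dataclass(frozen=True)
class AgePreset:
    """Template parameters plus between-subject dispersion (SD per field)."""

    template: ParticipantParams
    dispersion: dict[str, float]
    valence_dispersion: dict[str, float] = field(default_factory=dict)


def _params(age_group: str, **kw) -> ParticipantParams:
    return ParticipantParams(age_group=age_group, **kw)


# Between-subject means target observed cohort descriptives: mean go-shape
# RT ~733 ms (younger) / ~797 ms (older); SSRT ~215 / ~253 ms; omission
# ~1.9% / 2.8%; go-image error higher for unpleasant images in older
# adults. Rating agreement near ceiling for both groups.
PRESETS: dict[str, AgePreset] = {
    "younger": AgePreset(
        template=_params(
            "younger",
            go_mu=580.0,
            go_sigma=80.0,
            go_tau=150.0,
            image_appraisal_shift={"pleasant": 108.0, "unpleasant": 161.0},
            ssrt_mean=215.0,
            ssrt_sd=40.0,
            p_go_omission=0.019,
            p_choice_error=0.010,
            p_trigger_failure=0.0,
            p_image_wrong_action={"pleasant": 0.025, "unpleasant": 0.035},
            p_rating_agreement={"pleasant": 0.98, "unpleasant": 0.99},
        ),
        dispersion={
            "go_mu": 90.0,
            "go_sigma": 15.0,
            "go_tau": 40.0,
            "ssrt_mean": 45.0,
            "ssrt_sd": 10.0,
            "p_go_omission": 0.015,
            "p_choice_error": 0.007,
        },
        valence_dispersion={
            "image_appraisal_shift": 30.0,
            "p_image_wrong_action": 0.02,
            "p_rating_agreement": 0.012,
        },
    ),
    "older": AgePreset(
        template=_params(
            "older",
            go_mu=650.0,
            go_sigma=70.0,
            go_tau=147.0,
            image_appraisal_shift={"pleasant": 160.0, "unpleasant": 222.0},
            ssrt_mean=253.0,
            ssrt_sd=45.0,
            p_go_omission=0.028,
            p_choice_error=0.013,
            p_trigger_failure=0.0,
            p_image_wrong_action={"pleasant": 0.035, "unpleasant": 0.075},
            p_rating_agreement={"pleasant": 0.99, "unpleasant": 0.96},
        ),
        dispersion={
            "go_mu": 50.0,
            "go_sigma": 12.0,
            "go_tau": 35.0,
            "ssrt_mean": 52.0,
            "ssrt_sd": 10.0,
            "p_go_omission": 0.020,
            "p_choice_error": 0.008,
        },
        valence_dispersion={
            "image_appraisal_shift": 35.0,
            "p_image_wrong_action": 0.030,
            "p_rating_agreement": 0.020,
        },
    ),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def _clip_prob(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def sample_participant(
    preset: str, seed: int, dispersion_scale: float = 1.0
) -> ParticipantParams:
    """Draw one participant from a preset's between-subject distributions.

    Scalar parameters are normal around the template (positive ones
    floored at a small positive value, probabilities clipped to [0, 1]).
    ``dispersion_scale=0`` returns the template exactly.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {preset_names()}")
    lib = PRESETS[preset]
    t = lib.template
    rng = np.random.default_rng(seed)
    out: dict = {}
    for name, sd in lib.dispersion.items():
        value = getattr(t, name) + dispersion_scale * sd * rng.standard_normal()
        if name.startswith("p_"):
            value = _clip_prob(value)
        else:
            value = max(1.0, value)
        out[name] = float(value)
    for name, sd in lib.valence_dispersion.items():
        base = getattr(t, name)
        drawn = {}
        for valence in ("pleasant", "unpleasant"):
            value = base[valence] + dispersion_scale * sd * rng.standard_normal()
            drawn[valence] = _clip_prob(value) if name.startswith("p_") else max(0.0, value)
        out[name] = drawn
    return dataclasses.replace(t, **out)


def _ex_gaussian(params: ParticipantParams, rng: np.random.Generator) -> float:
    rt = params.go_mu + params.go_sigma * rng.standard_normal() + rng.exponential(params.go_tau)
    while rt <= 0:  # finishing times are positive; resample the rare negative draw
        rt = (
            params.go_mu
            + params.go_sigma * rng.standard_normal()
            + rng.exponential(params.go_tau)
        )
    return float(rt)


def _stop_finish_time(params: ParticipantParams, rng: np.random.Generator) -> float:
    if params.ssrt_sd == 0:
        return max(float(params.ssrt_mean), 0.0)
    s = params.ssrt_mean + params.ssrt_sd * rng.standard_normal()
    while s <= 0:  # truncate at zero
        s = params.ssrt_mean + params.ssrt_sd * rng.standard_normal()
    return float(s)


def respond_go(
    params: ParticipantParams,
    trial_type: str,
    valence: Optional[str],
    rng: np.random.Generator,
) -> tuple[Optional[float], Optional[bool]]:
    """Simulate a go trial.

    Returns ``(rt, pressed_correct_key)``; ``(None, None)`` on omission.
    Go-image trials add the valence-specific appraisal cost to the
    finishing time, and a wrong action (withholding or hitting the wrong
    key, equiprobable) occurs with ``p_image_wrong_action[valence]``.
    """
    if trial_type not in ("go_shape", "go_image"):
        raise ValueError(f"not a go trial type: {trial_type!r}")
    if rng.random() < params.p_go_omission:
        return None, None
    rt = _ex_gaussian(params, rng)
    if trial_type == "go_image":
        if valence is None:
            raise ValueError("go_image trials require a valence")
        rt += params.image_appraisal_shift[valence]
        if rng.random() < params.p_image_wrong_action[valence]:
            if rng.random() < 0.5:
                return None, None  # incorrectly withheld
            return rt, False  # wrong key
        return rt, True
    return rt, rng.random() >= params.p_choice_error


def respond_stop(
    params: ParticipantParams,
    ssd: float,
    rng: np.random.Generator,
) -> tuple[str, Optional[float]]:
    """Simulate a stop trial: race the go process against SSD + stop process.

    The go finishing time is the plain shape-discrimination ex-Gaussian
    (context independence: no image-appraisal cost enters the race). A
    trigger failure guarantees a response regardless of SSD.
    """
    g = _ex_gaussian(params, rng)
    if params.p_trigger_failure > 0 and rng.random() < params.p_trigger_failure:
        return "responded", g
    s = _stop_finish_time(params, rng)
    if g < ssd + s:
        return "responded", g
    return "inhibited", None
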