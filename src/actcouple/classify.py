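"""Non-wear detection, epoch classification, and valid-day selection.

Classification rules (all thresholds in milligravities, read literally):

* an epoch is *stationary* when all three axis SDs are strictly below 13.0;
  a maximal run of at least 60 consecutive stationary epochs is non-wear;
* the *hybrid* rule labels worn epochs with vector magnitude >= 100 as MVPA,
  then takes sleep and sedentary from the ML prediction, and assigns every
  other worn epoch (including ML "walking" or a missing prediction) to light;
* the *ML-only* rule uses the ML prediction for every worn epoch, mapping
  walking according to a policy (merged into light by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    LIGHT,
    MINUTES_PER_DAY,
    MISSING,
    ML_CODES,
    MVPA,
    OBSERVED,
    SEDENTARY,
    SLEEP,
    WALKING,
    EpochSeries,
    LabelSeries,
)

logger = logging.getLogger(__name__)

STATIONARY_SD_MGRAV = 13.0
NONWEAR_MIN_MINUTES = 60
MVPA_VM_MGRAV = 100.0
MIN_WEAR_HOURS = 72


def detect_nonwear(series: EpochSeries) -> np.ndarray:
    """Per-epoch wear mask (True = worn).

    Stationary epochs have all three axis SDs strictly below 13.0 m-grav;
    every maximal run of >= 60 consecutive stationary epochs is non-wear.
    """
    if series.n_epochs == 0:
        raise ValueError("empty epoch series")
    stationary = np.all(series.sd < STATIONARY_SD_MGRAV, axis=1)
    wear = np.ones(series.n_epochs, dtype=bool)
    padded = np.concatenate([[False], stationary, [False]]).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= NONWEAR_MIN_MINUTES:
            wear[start:stop] = False
    return wear


def classify_hybrid(series: EpochSeries, wear: np.ndarray) -> LabelSeries:
    """Hybrid threshold + ML classification of worn epochs.

    Precedence: non-worn -> missing; vm >= 100 -> MVPA (inclusive threshold,
    overriding the ML label); ML sleep -> sleep; ML sedentary -> sedentary;
    everything else (ML walking, light, MVPA, or absent) -> light.
    """
    if len(wear) != series.n_epochs:
        raise ValueError("wear mask not aligned to series")
    codes = np.full(series.n_epochs, LIGHT, dtype=np.int8)
    codes[series.ml_label == ML_CODES["sleep"]] = SLEEP
    codes[series.ml_label == ML_CODES["sedentary"]] = SEDENTARY
    codes[series.vm >= MVPA_VM_MGRAV] = MVPA
    codes[~wear] = MISSING
    return LabelSeries(series.participant_id, series.start_clock_minute, codes)


def classify_ml_only(
    series: EpochSeries, wear: np.ndarray, walking_policy: str = "merge_to_light"
) -> LabelSeries:
    """ML-only sensitivity classification: the ML label defines every category.

    The vector-magnitude threshold is *not* applied. Every worn epoch must
    carry an ML prediction. ``walking_policy`` is ``merge_to_light`` (default,
    keeping a 4-part composition) or ``keep_separate`` (emits the extra
    walking code).
    """
    if len(wear) != series.n_epochs:
        raise ValueError("wear mask not aligned to series")
    if walking_policy not in ("merge_to_light", "keep_separate"):
        raise ValueError(f"unknown walking_policy {walking_policy!r}")
    if np.any(wear & (series.ml_label < 0)):
        raise ValueError("ML-only classification requires an ML label for every worn epoch")
    ml_to_cat = {
        ML_CODES["sleep"]: SLEEP,
        ML_CODES["sedentary"]: SEDENTARY,
        ML_CODES["light"]: LIGHT,
        ML_CODES["mvpa"]: MVPA,
        ML_CODES["walking"]: LIGHT if walking_policy == "merge_to_light" else WALKING,
    }
    lut = np.full(len(ml_to_cat) + 1, MISSING, dtype=np.int8)
    for ml_code, cat in ml_to_cat.items():
        lut[ml_code] = cat
    codes = lut[np.where(series.ml_label < 0, len(ml_to_cat), series.ml_label)]
    codes[~wear] = MISSING
    return LabelSeries(series.participant_id, series.start_clock_minute, codes)


@dataclass
class InclusionDecision:
    """Valid days plus the cohort inclusion decision for one participant."""

    participant_id: str
    valid_days: list[int]
    included: bool
    observed_wear_minutes: int
    exclusion_reason: str | None = None


def select_valid_days(labels: LabelSeries, mode: str = "complete") -> InclusionDecision:
    """Valid calendar days and the participant-level inclusion decision.

    A day is valid when all of its 1,440 epochs are in-series and none is
    missing; under ``mode="complete"`` imputed epochs count as missing, under
    ``mode="imputed"`` they count as present. Partial leading/trailing
    calendar days are never valid. A participant is included with at least
    72 h of observed worn time and at least one valid day.
    """
    if mode not in ("complete", "imputed"):
        raise ValueError(f"unknown mode {mode!r}")
    n = labels.n_epochs
    if (labels.start_clock_minute + n) % MINUTES_PER_DAY != 0 or labels.start_clock_minute:
        logger.warning(
            "participant %s: series does not cover whole calendar days; "
            "partial days are never valid",
            labels.participant_id,
        )
    usable = labels.codes != MISSING
    if mode == "complete":
        usable &= labels.provenance == OBSERVED
    valid: list[int] = []
    for day in range(labels.n_days()):
        if labels.day_is_complete(day) and bool(np.all(usable[labels.day_slice(day)])):
            valid.append(day)
    observed_wear = int(np.sum((labels.codes != MISSING) & (labels.provenance == OBSERVED)))
    reason = None
    if observed_wear < MIN_WEAR_HOURS * 60:
        reason = "wear<72h"
    elif not valid:
        reason = "no_valid_days"
    return InclusionDecision(
        labels.participant_id, valid, reason is None, observed_wear, reason
    )
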