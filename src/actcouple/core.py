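"""Core containers and category coding shared across the pipeline.

Activity is represented at 1-minute epoch resolution. Epoch-level label
sequences use small integer codes so that whole-cohort operations stay
vectorised; the string names used in files and model output are defined here
once.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

#: The four analysis categories that partition worn time.
CATEGORIES: tuple[str, ...] = ("sleep", "sedentary", "light", "mvpa")
SLEEP, SEDENTARY, LIGHT, MVPA = 0, 1, 2, 3
#: Extra code available only when an ML-only classification keeps walking
#: as its own category.
WALKING = 4
MISSING = -1

CATEGORY_CODES = {name: i for i, name in enumerate(CATEGORIES)}

#: Labels emitted by the epoch-level machine-learning activity classifier.
#: These include a walking class that the analysis categories do not.
ML_LABELS: tuple[str, ...] = ("sleep", "sedentary", "walking", "light", "mvpa")
ML_CODES = {name: i for i, name in enumerate(ML_LABELS)}
ML_ABSENT = -1

OBSERVED, IMPUTED = 0, 1


def category_name(code: int) -> str:
    if code == MISSING:
        return "missing"
    if code == WALKING:
        return "walking"
    return CATEGORIES[code]


@dataclass
class EpochSeries:
    """One participant's minute-resolution accelerometer record.

    ``vm`` is the mean vector magnitude per epoch in milligravities (m-grav);
    ``sd`` holds the three per-axis standard deviations (n, 3), also m-grav.
    ``ml_label`` holds ML classifier codes (``ML_CODES``) or ``ML_ABSENT``.
    """

    participant_id: str
    start_datetime: pd.Timestamp
    vm: np.ndarray
    sd: np.ndarray
    ml_label: np.ndarray

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.ml_label = np.asarray(self.ml_label, dtype=np.int8)
        n = len(self.vm)
        if self.sd.shape != (n, 3):
            raise ValueError(f"sd must have shape ({n}, 3), got {self.sd.shape}")
        if len(self.ml_label) != n:
            raise ValueError("ml_label length mismatch")
        if np.any(self.vm < 0) or np.any(self.sd < 0):
            raise ValueError("vector magnitude and axis SDs must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.vm)

    @property
    def start_clock_minute(self) -> int:
        t = self.start_datetime
        return int(t.hour) * 60 + int(t.minute)

    def clock_minute(self) -> np.ndarray:
        """Minute within the calendar day, 0..1439, per epoch."""
        return (self.start_clock_minute + np.arange(self.n_epochs)) % MINUTES_PER_DAY

    def day_index(self) -> np.ndarray:
        """Calendar day offset from the start date, per epoch."""
        return (self.start_clock_minute + np.arange(self.n_epochs)) // MINUTES_PER_DAY


@dataclass
class LabelSeries:
    """Per-epoch activity categories, aligned to a source :class:`EpochSeries`.

    ``codes`` uses ``CATEGORY_CODES`` plus ``MISSING`` (and ``WALKING`` only
    for ML-only classification with ``keep_separate``). ``provenance`` is
    ``OBSERVED`` or ``IMPUTED`` per epoch.
    """

    participant_id: str
    start_clock_minute: int
    codes: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.provenance is None:
            self.provenance = np.zeros(len(self.codes), dtype=np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
        if len(self.provenance) != len(self.codes):
            raise ValueError("provenance length mismatch")

    @property
    def n_epochs(self) -> int:
        return len(self.codes)

    def clock_minute(self) -> np.ndarray:
        return (self.start_clock_minute + np.arange(self.n_epochs)) % MINUTES_PER_DAY

    def day_index(self) -> np.ndarray:
        return (self.start_clock_minute + np.arange(self.n_epochs)) // MINUTES_PER_DAY

    def n_days(self) -> int:
        """Number of calendar days touched by the series (incl. partial)."""
        if self.n_epochs == 0:
            return 0
        return int((self.start_clock_minute + self.n_epochs - 1) // MINUTES_PER_DAY) + 1

    def day_slice(self, day: int) -> slice:
        """Epoch index range of calendar day ``day`` (clipped to the series)."""
        lo = day * MINUTES_PER_DAY - self.start_clock_minute
        hi = lo + MINUTES_PER_DAY
        return slice(max(lo, 0), min(hi, self.n_epochs))

    def day_is_complete(self, day: int) -> bool:
        """True when all 1,440 epochs of calendar day ``day`` are in-series."""
        lo = day * MINUTES_PER_DAY - self.start_clock_minute
        return lo >= 0 and lo + MINUTES_PER_DAY <= self.n_epochs

    def copy(self) -> "LabelSeries":
        return LabelSeries(
            self.participant_id,
            self.start_clock_minute,
            self.codes.copy(),
            self.provenance.copy(),
        )


# Bout-length strata (closed integer intervals on whole-minute bout lengths;
# upper bound None means unbounded).
SEDENTARY_STRATA: tuple[tuple[int, int | None], ...] = ((1, 15), (16, 40), (41, None))
MVPA_STRATA: tuple[tuple[int, int | None], ...] = ((1, 9), (10, 15), (16, 40), (41, None))


def stratum_label(category: str, bounds: tuple[int, int | None]) -> str:
    lo, hi = bounds
    return f"{category}_bout_{lo}_{hi}" if hi is not None else f"{category}_bout_{lo}plus"


#: Wide-format column names for the two stratified categories.
SEDENTARY_STRATA_COLS = tuple(stratum_label("sedentary", b) for b in SEDENTARY_STRATA)
MVPA_STRATA_COLS = tuple(stratum_label("mvpa", b) for b in MVPA_STRATA)


@dataclass
class StratumScheme:
    """Bout-length stratification for one category (closed minute intervals)."""

    category: str
    boundaries: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        lo_expected = 1
        for lo, hi in self.boundaries:
            if lo != lo_expected:
                raise ValueError("strata must partition [1, inf) without gaps")
            lo_expected = (hi + 1) if hi is not None else None
        if lo_expected is not None:
            raise ValueError("last stratum must be unbounded")

    def stratum_of(self, length: int) -> int:
        for i, (lo, hi) in enumerate(self.boundaries):
            if length >= lo and (hi is None or length <= hi):
                return i
        raise ValueError(f"bout length {length} outside scheme")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(stratum_label(self.category, b) for b in self.boundaries)


SEDENTARY_SCHEME = StratumScheme("sedentary", SEDENTARY_STRATA)
MVPA_SCHEME = StratumScheme("mvpa", MVPA_STRATA)


@dataclass
class ParticipantSummary:
    """Average daily minutes per category and bout-length stratum.

    Category averages close to 1,440 min/day; stratum averages partition
    their category's total.
    """

    participant_id: str
    n_valid_days: int
    minutes_per_day: dict[str, float]
    sedentary_strata_minutes: dict[str, float]
    mvpa_strata_minutes: dict[str, float]

    def validate(self, tol: float = 1e-9) -> None:
        total = sum(self.minutes_per_day.values())
        if abs(total - MINUTES_PER_DAY) > tol:
            raise ValueError(f"category averages sum to {total}, not {MINUTES_PER_DAY}")
        if any(v < -tol for v in self.minutes_per_day.values()):
            raise ValueError("negative category average")
        sed = sum(self.sedentary_strata_minutes.values())
        if abs(sed - self.minutes_per_day.get("sedentary", 0.0)) > tol:
            raise ValueError("sedentary strata do not partition sedentary total")
        mv = sum(self.mvpa_strata_minutes.values())
        if abs(mv - self.minutes_per_day.get("mvpa", 0.0)) > tol:
            raise ValueError("MVPA strata do not partition MVPA total")

    def to_row(self) -> dict:
        row: dict = {"participant_id": self.participant_id, "n_valid_days": self.n_valid_days}
        row.update(self.minutes_per_day)
        row.update(self.sedentary_strata_minutes)
        row.update(self.mvpa_strata_minutes)
        return row


def summaries_to_frame(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    cols = (
        ["participant_id", "n_valid_days"]
        + list(CATEGORIES)
        + list(SEDENTARY_STRATA_COLS)
        + list(MVPA_STRATA_COLS)
    )
    if not summaries:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([s.to_row() for s in summaries])[cols]


@dataclass
class SurvivalRecord:
    """Left-truncated, right-censored follow-up on the age scale (years)."""

    participant_id: str
    entry_age: float
    exit_age: float
    event: bool

    def __post_init__(self) -> None:
        if self.exit_age < self.entry_age:
            raise ValueError("exit_age must be >= entry_age")


@dataclass
class CovariateRecord:
    """Baseline confounders plus the day of year accelerometer wear began."""

    participant_id: str
    sex: int  # 1 = male, 0 = female
    ethnicity: str
    smoking: str
    education: str
    income: str
    townsend: float
    bmi: float
    prior_cvd: bool
    prior_cancer: bool
    prior_respiratory: bool
    wear_day_of_year: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.wear_day_of_year) <= 365:
            raise ValueError("wear_day_of_year must be in [1, 365]")
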