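"""Other-day imputation of non-wear gaps.

Each maximal missing run (split at midnight so that "the same time period"
is well defined) is filled, when possible, by the label sequence of the same
clock-time window from another day chosen uniformly at random among days
whose window is fully observed. Days missing data at *other* times remain
eligible donors. Observed epochs are never modified, so imputation can only
increase the number of valid days.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IMPUTED, MINUTES_PER_DAY, MISSING, LabelSeries


@dataclass(frozen=True)
class MissingInterval:
    """A maximal missing run within one calendar day."""

    day_index: int
    start_clock_minute: int
    length: int

    def __post_init__(self) -> None:
        if self.start_clock_minute + self.length > MINUTES_PER_DAY:
            raise ValueError("interval crosses midnight; split it at the day boundary")


def missing_intervals(labels: LabelSeries) -> list[MissingInterval]:
    """Maximal missing runs, split at calendar-day boundaries, in series order."""
    miss = (labels.codes == MISSING).astype(np.int8)
    padded = np.concatenate([[0], miss, [0]])
    edges = np.flatnonzero(np.diff(padded))
    clock0 = labels.start_clock_minute
    out: list[MissingInterval] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        pos = start
        while pos < stop:
            day = (clock0 + pos) // MINUTES_PER_DAY
            day_end = (day + 1) * MINUTES_PER_DAY - clock0
            seg_end = min(stop, day_end)
            out.append(
                MissingInterval(int(day), int((clock0 + pos) % MINUTES_PER_DAY), int(seg_end - pos))
            )
            pos = seg_end
    return out


def _window_slice(labels: LabelSeries, day: int, start_clock: int, length: int) -> slice | None:
    """Epoch index range of a clock window on a given day, or None if not fully in-series."""
    lo = day * MINUTES_PER_DAY - labels.start_clock_minute + start_clock
    hi = lo + length
    if lo < 0 or hi > labels.n_epochs:
        return None
    return slice(lo, hi)


def find_candidate_windows(interval: MissingInterval, labels: LabelSeries) -> list[int]:
    """Days whose same-clock-time window is fully observed (donor candidates)."""
    out: list[int] = []
    for day in range(labels.n_days()):
        if day == interval.day_index:
            continue
        sl = _window_slice(labels, day, interval.start_clock_minute, interval.length)
        if sl is not None and bool(np.all(labels.codes[sl] != MISSING)):
            out.append(day)
    return out


def impute_other_day(labels: LabelSeries, rng_seed: int) -> LabelSeries:
    """Fill each missing interval from a uniformly chosen donor day.

    Candidates are judged against the *pre-imputation* series; intervals with
    no candidate stay missing. Imputed epochs get provenance ``IMPUTED``.
    Deterministic given ``labels`` and ``rng_seed``; a no-missing input is
    returned unchanged (idempotence).
    """
    rng = np.random.default_rng(rng_seed)
    out = labels.copy()
    for interval in missing_intervals(labels):
        candidates = find_candidate_windows(interval, labels)
        if not candidates:
            continue
        donor = candidates[int(rng.integers(len(candidates)))]
        src = _window_slice(labels, donor, interval.start_clock_minute, interval.length)
        dst = _window_slice(labels, interval.day_index, interval.start_clock_minute, interval.length)
        out.codes[dst] = labels.codes[src]
        out.provenance[dst] = IMPUTED
    return out
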