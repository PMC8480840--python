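"""Activity bouts, bout-length stratification, and per-participant summaries.

A bout is a maximal run of consecutive 1-minute epochs sharing one activity
category. Bouts are derived within maximal blocks of consecutive valid days,
so a bout may span midnight between adjacent valid days but never an invalid
day. Every minute of a bout is attributed to the bout-length stratum of the
bout's *total* length and to the calendar day on which the minute occurs —
preserving both per-day closure to 1,440 minutes and bout-length semantics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    CATEGORIES,
    CATEGORY_CODES,
    MINUTES_PER_DAY,
    MISSING,
    MVPA_SCHEME,
    SEDENTARY_SCHEME,
    LabelSeries,
    ParticipantSummary,
    StratumScheme,
)


@dataclass(frozen=True)
class Bout:
    """A maximal constant-category run: category code, start epoch, minutes."""

    category: int
    start_index: int
    length: int


def _consecutive_blocks(valid_days: Sequence[int]) -> list[list[int]]:
    days = sorted(valid_days)
    blocks: list[list[int]] = []
    for d in days:
        if blocks and d == blocks[-1][-1] + 1:
            blocks[-1].append(d)
        else:
            blocks.append([d])
    return blocks


def derive_bouts(labels: LabelSeries, valid_days: Iterable[int]) -> list[Bout]:
    """Run-length encode labels over each block of consecutive valid days.

    A gap of one or more invalid days breaks contiguity; a category run that
    crosses midnight between adjacent valid days is a single bout. Missing
    labels inside a valid day are an internal consistency error.
    """
    bouts: list[Bout] = []
    for block in _consecutive_blocks(list(valid_days)):
        lo = labels.day_slice(block[0]).start
        hi = labels.day_slice(block[-1]).stop
        codes = labels.codes[lo:hi]
        if np.any(codes == MISSING):
            raise ValueError(
                f"participant {labels.participant_id}: missing label inside valid day"
            )
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(codes)]])
        for s, e in zip(starts, ends):
            bouts.append(Bout(int(codes[s]), int(lo + s), int(e - s)))
    return bouts


def stratify_bout_minutes(
    bouts: Sequence[Bout],
    scheme: StratumScheme,
    valid_days: Iterable[int],
    start_clock_minute: int = 0,
) -> dict[int, np.ndarray]:
    """Per-day minutes in each bout-length stratum for the scheme's category.

    Returns ``{day: minutes_per_stratum}`` over the valid days. Each minute
    counts toward the stratum of its bout's total length and toward the
    calendar day on which it occurs (relevant for midnight-spanning bouts).
    """
    cat_code = CATEGORY_CODES[scheme.category]
    days = sorted(valid_days)
    per_day = {d: np.zeros(len(scheme.boundaries)) for d in days}
    for bout in bouts:
        if bout.category != cat_code:
            continue
        stratum = scheme.stratum_of(bout.length)
        pos = bout.start_index
        remaining = bout.length
        while remaining > 0:
            day = (start_clock_minute + pos) // MINUTES_PER_DAY
            day_end = (day + 1) * MINUTES_PER_DAY - start_clock_minute
            take = min(remaining, day_end - pos)
            if day in per_day:
                per_day[day][stratum] += take
            pos += take
            remaining -= take
    return per_day


def summarize_participant(
    labels: LabelSeries,
    valid_days: Iterable[int],
    schemes: tuple[StratumScheme, StratumScheme] = (SEDENTARY_SCHEME, MVPA_SCHEME),
) -> ParticipantSummary:
    """Average daily minutes per category and bout-length stratum.

    Averages are totals over the valid days divided by the number of valid
    days, so the four category averages close to 1,440 and each scheme's
    strata partition its category total.
    """
    days = sorted(valid_days)
    if not days:
        raise ValueError(
            f"participant {labels.participant_id}: no valid days to summarize"
        )
    n_days = len(days)
    totals = np.zeros(len(CATEGORIES))
    for d in days:
        codes = labels.codes[labels.day_slice(d)]
        if np.any(codes == MISSING):
            raise ValueError(
                f"participant {labels.participant_id}: missing label inside valid day"
            )
        totals += np.bincount(codes, minlength=len(CATEGORIES))[: len(CATEGORIES)]
    bouts = derive_bouts(labels, days)
    strata_minutes = {}
    for scheme in schemes:
        per_day = stratify_bout_minutes(bouts, scheme, days, labels.start_clock_minute)
        strata_minutes[scheme.category] = sum(per_day.values()) / n_days
    summary = ParticipantSummary(
        participant_id=labels.participant_id,
        n_valid_days=n_days,
        minutes_per_day={cat: totals[k] / n_days for k, cat in enumerate(CATEGORIES)},
        sedentary_strata_minutes=dict(
            zip(schemes[0].labels, strata_minutes[schemes[0].category])
        ),
        mvpa_strata_minutes=dict(zip(schemes[1].labels, strata_minutes[schemes[1].category])),
    )
    summary.validate()
    return summary
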