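"""Brute-force reference implementations used only to check the package.

These deliberately use naive scalar loops so they stay independent of the
vectorised implementations they validate.
"""
from __future__ import annotations

import numpy as np


def nonwear_oracle(sd: np.ndarray, threshold: float = 13.0, min_run: int = 60) -> np.ndarray:
    """Worn mask by scanning every maximal stationary run with a plain loop."""
    n = len(sd)
    stationary = [all(sd[i, a] < threshold for a in range(3)) for i in range(n)]
    worn = [True] * n
    i = 0
    while i < n:
        if stationary[i]:
            j = i
            while j < n and stationary[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    worn[k] = False
            i = j
        else:
            i += 1
    return np.array(worn)


def rle_oracle(codes) -> list[tuple[int, int, int]]:
    """(value, start, length) runs via an explicit scan."""
    runs = []
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            runs.append((int(codes[start]), start, i - start))
            start = i
    return runs


def ilr_basis_oracle(partition, parts):
    """Orthonormal ILR basis matrix for a sequential binary partition.

    Row i has +sqrt(s/(r(r+s))) on numerator parts and -sqrt(r/(s(r+s))) on
    denominator parts; coordinates are basis @ ln(x). An algebraically
    different route to the balance formula.
    """
    B = np.zeros((len(partition), len(parts)))
    index = {p: j for j, p in enumerate(parts)}
    for i, (num, den) in enumerate(partition):
        r, s = len(num), len(den)
        for p in num:
            B[i, index[p]] = np.sqrt(s / (r * (r + s)))
        for p in den:
            B[i, index[p]] = -np.sqrt(r / (s * (r + s)))
    return B


def summary_oracle(codes: np.ndarray, valid_days: list[int], start_clock: int = 0) -> dict:
    """Per-category and per-stratum average daily minutes by direct counting."""
    from collections import defaultdict

    n_days = len(valid_days)
    cat_minutes = defaultdict(float)
    day_of = lambda idx: (start_clock + idx) // 1440
    for d in valid_days:
        lo, hi = d * 1440 - start_clock, (d + 1) * 1440 - start_clock
        for i in range(lo, hi):
            cat_minutes[int(codes[i])] += 1.0

    # bouts within maximal blocks of consecutive valid days
    blocks = []
    for d in sorted(valid_days):
        if blocks and d == blocks[-1][-1] + 1:
            blocks[-1].append(d)
        else:
            blocks.append([d])
    sed_strata = [0.0, 0.0, 0.0]
    mvpa_strata = [0.0, 0.0, 0.0, 0.0]
    for block in blocks:
        lo = block[0] * 1440 - start_clock
        hi = (block[-1] + 1) * 1440 - start_clock
        for value, start, length in rle_oracle(codes[lo:hi]):
            if value == 1:  # sedentary
                stratum = 0 if length <= 15 else (1 if length <= 40 else 2)
                sed_strata[stratum] += length
            elif value == 3:  # MVPA
                stratum = (
                    0 if length <= 9 else (1 if length <= 15 else (2 if length <= 40 else 3))
                )
                mvpa_strata[stratum] += length
    return {
        "minutes": {k: v / n_days for k, v in cat_minutes.items()},
        "sed_strata": [v / n_days for v in sed_strata],
        "mvpa_strata": [v / n_days for v in mvpa_strata],
    }
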