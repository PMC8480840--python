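"""Flat-file schemas for pipeline artefacts.

Everything is plain CSV so intermediate stages are inspectable: epoch series
in long format (one row per participant-minute), label series with
provenance, and one-row-per-participant tables for covariates, survival and
summaries.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CATEGORIES,
    MISSING,
    ML_ABSENT,
    ML_LABELS,
    EpochSeries,
    LabelSeries,
    category_name,
)

EPOCH_COLUMNS = ["participant_id", "timestamp", "vm_mgrav", "sd_x", "sd_y", "sd_z", "ml_label"]
LABEL_COLUMNS = ["participant_id", "index", "label", "provenance"]


def epochs_to_frame(series_list: Sequence[EpochSeries]) -> pd.DataFrame:
    frames = []
    for s in series_list:
        ts = s.start_datetime + pd.to_timedelta(np.arange(s.n_epochs), unit="min")
        ml = np.array(["", *ML_LABELS], dtype=object)[s.ml_label + 1]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "timestamp": ts,
                    "vm_mgrav": s.vm,
                    "sd_x": s.sd[:, 0],
                    "sd_y": s.sd[:, 1],
                    "sd_z": s.sd[:, 2],
                    "ml_label": ml,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=EPOCH_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_epochs_csv(series_list: Sequence[EpochSeries], path: str | Path) -> None:
    epochs_to_frame(series_list).to_csv(path, index=False, float_format="%.3f")


def read_epochs_csv(path: str | Path) -> list[EpochSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"], keep_default_na=False)
    ml_code = {name: i for i, name in enumerate(ML_LABELS)}
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp")
        ml = grp["ml_label"].map(lambda s: ml_code.get(s, ML_ABSENT)).to_numpy(np.int8)
        out.append(
            EpochSeries(
                participant_id=str(pid),
                start_datetime=grp["timestamp"].iloc[0],
                vm=grp["vm_mgrav"].to_numpy(float),
                sd=grp[["sd_x", "sd_y", "sd_z"]].to_numpy(float),
                ml_label=ml,
            )
        )
    return out


def labels_to_frame(labels_list: Sequence[LabelSeries]) -> pd.DataFrame:
    frames = []
    for ls in labels_list:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ls.participant_id,
                    "index": np.arange(ls.n_epochs),
                    "start_clock_minute": ls.start_clock_minute,
                    "label": [category_name(c) for c in ls.codes],
                    "provenance": np.where(ls.provenance == 0, "observed", "imputed"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=LABEL_COLUMNS + ["start_clock_minute"])
    return pd.concat(frames, ignore_index=True)


def write_labels_csv(labels_list: Sequence[LabelSeries], path: str | Path) -> None:
    labels_to_frame(labels_list).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[LabelSeries]:
    df = pd.read_csv(path)
    code = {name: i for i, name in enumerate(CATEGORIES)}
    code["missing"] = MISSING
    code["walking"] = 4
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("index")
        out.append(
            LabelSeries(
                participant_id=str(pid),
                start_clock_minute=int(grp["start_clock_minute"].iloc[0]),
                codes=grp["label"].map(code).to_numpy(np.int8),
                provenance=(grp["provenance"] == "imputed").to_numpy(np.uint8),
            )
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
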