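import numpy as np
import pandas as pd
import pytest

from actcouple.core import EpochSeries, LabelSeries
from actcouple.synthetic import SimulationConfig


def make_series(
    sd_rows,
    vm=None,
    ml=None,
    participant_id="P1",
    start="2014-06-02 00:00",
):
    """Build an EpochSeries from per-epoch sd rows (scalars broadcast to 3 axes)."""
    sd = np.array([[r] * 3 if np.isscalar(r) else list(r) for r in sd_rows], dtype=float)
    n = len(sd)
    vm = np.full(n, 30.0) if vm is None else np.asarray(vm, dtype=float)
    ml = np.full(n, -1, dtype=np.int8) if ml is None else np.asarray(ml, dtype=np.int8)
    return EpochSeries(participant_id, pd.Timestamp(start), vm, sd, ml)


def make_labels(codes, start_clock=0, provenance=None, participant_id="P1"):
    return LabelSeries(participant_id, start_clock, np.asarray(codes, dtype=np.int8), provenance)


@pytest.fixture
def tiny_config():
    return SimulationConfig(n_participants=5, n_days=7, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20210915)
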