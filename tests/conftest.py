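import numpy as np
import pytest

from scedmed import SCEDDataset, SCEDSeries


@pytest.fixture
def simple_dataset():
    """10 complete days, phases B(5)/C(5), mediator improving in C."""
    time = np.arange(1, 11)
    phase = np.array(["B"] * 5 + ["C"] * 5, dtype=object)
    med = np.array([2, 3, 2, 3, 2, 5, 6, 5, 6, 7], dtype=float)
    out = np.array([6, 5, 6, 5, 6, 4, 3, 4, 3, 2], dtype=float)
    return SCEDDataset(SCEDSeries(time, med, phase, name="coping"),
                       SCEDSeries(time, out, phase.copy(), name="anxiety"))


@pytest.fixture
def dataset_with_gap():
    """Days 1..7, day 3 missing in both variables."""
    time = np.arange(1, 8)
    phase = np.array(["B", "B", "B", "B", "C", "C", "C"], dtype=object)
    med = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
    out = np.array([7.0, 6.0, np.nan, 4.0, 3.0, 2.0, 1.0])
    return SCEDDataset(SCEDSeries(time, med, phase, name="m"),
                       SCEDSeries(time, out, phase.copy(), name="y"))


def make_series(values, phases, time=None, **kw):
    values = np.asarray(values, dtype=float)
    if time is None:
        time = np.arange(1, len(values) + 1)
    return SCEDSeries(np.asarray(time), values,
                      np.asarray(phases, dtype=object), **kw)
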