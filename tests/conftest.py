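import numpy as np
import pytest

from wearsim.preprocess import PreprocessedRecord
from wearsim.synthdata import CohortConfig, generate_cohort
from wearsim.types import ActivityInterval, MinuteSeries, NNISeries, StepSeries


def make_minutes(values, start=0, kind="hr", index=None):
    values = np.asarray(values, dtype=float)
    if index is None:
        index = np.arange(start, start + values.size)
    return MinuteSeries(np.asarray(index), values, kind=kind)


def make_nni(values_ms, t0=0.0):
    """NNI series whose beat times are the cumulative intervals."""
    v = np.asarray(values_ms, dtype=float)
    return NNISeries(t0 + np.cumsum(v) / 1000.0, v)


def make_record(hr, nni, pmsc, diary, age=25, latent=None, id="T01"):
    return PreprocessedRecord(
        id=id, age=age, hr=hr, nni=nni, pmsc=pmsc, diary=diary, latent=latent
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants, 3-hour records, 1-bpm jitter."""
    cfg = CohortConfig(n=3, duration_s=3 * 3600.0, jitter_bpm=1.0)
    return generate_cohort(seed=42, config=cfg)


@pytest.fixture()
def simple_diary():
    return [
        ActivityInterval(0.0, 3600.0, "sleep"),
        ActivityInterval(3600.0, 7200.0, "rest"),
        ActivityInterval(7200.0, 9000.0, "heavy_exercise"),
        ActivityInterval(9000.0, 10800.0, "rest"),
    ]
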