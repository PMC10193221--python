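"""Core containers shared by every stage of the pipeline.

All times are seconds from the record origin; NNIs are milliseconds;
per-minute series are indexed by integer minute number.  Minute series may
have holes (absent minutes are simply not present in ``index``), which is how
empty HR minutes and sleep-removed step minutes are represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Diary activity categories, ordered roughly by exertion.
CATEGORIES = ("sleep", "rest", "light", "medium", "heavy_exercise")

#: Categories counted as "periods of rest" for the baseline-HR definition
#: (lying down or sitting).
REST_CATEGORIES = ("rest",)


@dataclass(frozen=True)
class ActivityInterval:
    """One diary entry: [start, end) seconds with an activity category."""

    start: float
    end: float
    category: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown activity category {self.category!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_diary(diary: list[ActivityInterval], duration_s: float | None = None) -> None:
    """Check that a diary is ordered, non-overlapping and gap-free."""
    if not diary:
        raise ValueError("diary is empty")
    for a, b in zip(diary, diary[1:]):
        if not np.isclose(a.end, b.start):
            raise ValueError(f"diary gap/overlap between {a} and {b}")
    if duration_s is not None:
        if not (np.isclose(diary[0].start, 0.0) and np.isclose(diary[-1].end, duration_s)):
            raise ValueError("diary does not cover the full record duration")


@dataclass
class NNISeries:
    """Beat-to-beat (N-N) intervals.

    ``times`` are beat arrival times (s, strictly increasing); ``values`` are
    the intervals in milliseconds, with ``values[i]`` the interval ending at
    ``times[i]``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("NNI values must be positive")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "NNISeries":
        return NNISeries(self.times.copy(), self.values.copy())


@dataclass
class StepSeries:
    """Step counts on a uniform epoch grid (epoch start times)."""

    times: np.ndarray
    values: np.ndarray
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and np.any(self.values < 0):
            raise ValueError("step counts must be non-negative")
        if self.times.size > 1:
            d = np.diff(self.times)
            if not np.allclose(d, self.epoch_s):
                raise ValueError("step epochs must form a uniform grid")

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "StepSeries":
        return StepSeries(self.times.copy(), self.values.copy(), self.epoch_s)


@dataclass
class MinuteSeries:
    """Per-minute values (HR in bpm or PMSC in steps/min), possibly with holes.

    ``kind`` distinguishes heart rate ('hr') from per-minute step count
    ('pmsc'); the perturbation floor rules depend on it.
    """

    index: np.ndarray
    values: np.ndarray
    kind: str = "hr"

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.index.shape != self.values.shape:
            raise ValueError("index and values must have equal length")
        if self.index.size > 1 and np.any(np.diff(self.index) <= 0):
            raise ValueError("minute indices must be strictly increasing")
        if self.kind not in ("hr", "pmsc"):
            raise ValueError(f"unknown minute-series kind {self.kind!r}")

    def __len__(self) -> int:
        return self.index.size

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.index.copy(), self.values.copy(), self.kind)


@dataclass(frozen=True)
class SynthTruth:
    """Latent ground truth of a synthetic participant."""

    baseline_hr_true: float
    peak_hr_true: float
    age: int

    def __post_init__(self) -> None:
        if not self.peak_hr_true > self.baseline_hr_true:
            raise ValueError("peak HR must exceed baseline HR")

    @property
    def predicted_hr_true(self) -> float:
        return 220.0 - self.age

    @property
    def cci_true(self) -> float:
        return (self.peak_hr_true - self.baseline_hr_true) / (
            self.predicted_hr_true - self.baseline_hr_true
        )


@dataclass
class ParticipantRecord:
    """One subject's raw streams plus demographics.

    ``latent`` is present only for synthetic records and carries the ground
    truth that the pipeline is expected to recover.
    """

    id: str
    age: int
    nni: NNISeries
    steps: StepSeries
    diary: list[ActivityInterval]
    latent: Optional[SynthTruth] = None

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 80:
            raise ValueError(f"age {self.age} outside the supported range [18, 80]")

    @property
    def duration_s(self) -> float:
        return self.diary[-1].end if self.diary else 0.0
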