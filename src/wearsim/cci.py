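"""Cardiac competence index (CCI), the prediction target.

CCI = (peak HR − baseline HR) / ((220 − age) − baseline HR), where baseline
HR is the minimum of a rolling 2-minute mean of per-minute HR over periods of
rest (lying down or sitting), and peak HR is the maximum of the same rolling
mean over heavy-exercise periods.  The target is computed once per
participant from unperturbed data and held fixed across every perturbation
condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PreprocessedRecord
from .types import ActivityInterval, MinuteSeries, REST_CATEGORIES

__all__ = ["CCIResult", "rolling_2min_mean", "baseline_hr", "peak_hr", "compute_cci"]


@dataclass(frozen=True)
class CCIResult:
    baseline_hr: float
    peak_hr: float
    predicted_hr: float
    cci: float


def rolling_2min_mean(hr: MinuteSeries) -> MinuteSeries:
    """Mean over each pair of consecutive present minutes.

    Emitted at the window's first minute; windows spanning an absent minute
    are skipped.
    """
    if len(hr) < 2:
        raise ValueError("need at least 2 minutes for a 2-minute rolling mean")
    adjacent = np.diff(hr.index) == 1
    starts = hr.index[:-1][adjacent]
    means = 0.5 * (hr.values[:-1] + hr.values[1:])[adjacent]
    return MinuteSeries(starts, means, kind=hr.kind)


def _extreme_in(
    hr: MinuteSeries, diary: list[ActivityInterval], categories: tuple[str, ...], fn
) -> float:
    """Extreme of the rolling 2-min mean over windows fully inside intervals
    of the given categories.  A window starting at minute m spans
    [60m, 60(m+2)) and must lie within a single interval."""
    roll = rolling_2min_mean(hr)
    w_start = roll.index * 60.0
    w_end = w_start + 120.0
    mask = np.zeros(len(roll), dtype=bool)
    for iv in diary:
        if iv.category in categories:
            mask |= (w_start >= iv.start - 1e-9) & (w_end <= iv.end + 1e-9)
    if not mask.any():
        raise ValueError(
            f"no 2-minute HR window lies fully inside a {'/'.join(categories)} interval"
        )
    return float(fn(roll.values[mask]))


def baseline_hr(hr: MinuteSeries, diary: list[ActivityInterval]) -> float:
    """Minimum rolling 2-minute HR mean during periods of rest."""
    return _extreme_in(hr, diary, REST_CATEGORIES, np.min)


def peak_hr(hr: MinuteSeries, diary: list[ActivityInterval]) -> float:
    """Maximum rolling 2-minute HR mean during heavy exercise."""
    return _extreme_in(hr, diary, ("heavy_exercise",), np.max)


def compute_cci(record: PreprocessedRecord) -> CCIResult:
    """CCI for one preprocessed participant from unperturbed series."""
    base = baseline_hr(record.hr, record.diary)
    peak = peak_hr(record.hr, record.diary)
    predicted = 220.0 - record.age
    if predicted <= base:
        raise ValueError(
            f"predicted HR {predicted} does not exceed baseline HR {base}; "
            "CCI denominator non-positive"
        )
    return CCIResult(
        baseline_hr=base,
        peak_hr=peak,
        predicted_hr=predicted,
        cci=(peak - base) / (predicted - base),
    )
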