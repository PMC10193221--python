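"""Raw streams -> analysis series.

Turns a participant record into the three series everything downstream runs
on: the trimmed NNI stream, per-minute heart rate (beat-mean per 60-s window,
floored at 35 bpm), and the per-minute step count (PMSC) with sleep minutes
removed.  Also reads MMASH-style per-participant CSV directories.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ActivityInterval,
    MinuteSeries,
    NNISeries,
    ParticipantRecord,
    StepSeries,
)

__all__ = [
    "HR_FLOOR_BPM",
    "trim_initial",
    "compute_pmsc",
    "remove_sleep_pmsc",
    "nni_to_minute_hr",
    "read_mmash_participant",
    "preprocess_record",
    "PreprocessedRecord",
]

#: Lowest plausible per-minute heart rate; minutes below it are set to it.
HR_FLOOR_BPM = 35.0


def trim_initial(record: ParticipantRecord, minutes: float = 5) -> ParticipantRecord:
    """Drop the first ``minutes`` of every stream (device placement window).

    The record origin shifts to the cut point; diary intervals are clipped
    accordingly.  ``minutes=0`` is the identity.
    """
    cut = minutes * 60.0
    if record.duration_s <= cut:
        raise ValueError(
            f"record of {record.duration_s} s shorter than the {cut} s trim window"
        )
    if cut == 0:
        return record

    keep_n = record.nni.times >= cut
    nni = NNISeries(record.nni.times[keep_n] - cut, record.nni.values[keep_n])
    keep_s = record.steps.times >= cut
    steps = StepSeries(
        record.steps.times[keep_s] - cut, record.steps.values[keep_s], record.steps.epoch_s
    )
    diary = [
        ActivityInterval(max(iv.start, cut) - cut, iv.end - cut, iv.category)
        for iv in record.diary
        if iv.end > cut
    ]
    return ParticipantRecord(
        id=record.id, age=record.age, nni=nni, steps=steps, diary=diary, latent=record.latent
    )


def compute_pmsc(steps: StepSeries) -> MinuteSeries:
    """Per-minute step count: sum of step epochs in each [60m, 60(m+1))."""
    per_min = 60.0 / steps.epoch_s
    if not np.isclose(per_min, round(per_min)):
        raise ValueError(f"epoch of {steps.epoch_s} s does not divide 60 s")
    minute = np.floor(steps.times / 60.0).astype(int)
    uniq, inv = np.unique(minute, return_inverse=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inv, steps.values.astype(float))
    return MinuteSeries(uniq, sums, kind="pmsc")


def remove_sleep_pmsc(
    pmsc: MinuteSeries, diary: list[ActivityInterval]
) -> MinuteSeries:
    """Delete (not zero-fill) minutes whose midpoint falls in a sleep interval."""
    mid = pmsc.index * 60.0 + 30.0
    in_sleep = np.zeros(len(pmsc), dtype=bool)
    for iv in diary:
        if iv.category == "sleep":
            in_sleep |= (mid >= iv.start) & (mid < iv.end)
    return MinuteSeries(pmsc.index[~in_sleep], pmsc.values[~in_sleep], kind="pmsc")


def nni_to_minute_hr(nni: NNISeries, floor_bpm: float = HR_FLOOR_BPM) -> MinuteSeries:
    """Per-minute HR: mean of per-beat 60/NNI within each minute, floored.

    A beat belongs to minute ``floor(t/60)``.  Minutes containing no beats are
    absent from the output.  Values below ``floor_bpm`` are set to it.
    """
    if len(nni) == 0:
        raise ValueError("empty NNI series")
    hr_beats = 60.0 / (nni.values / 1000.0)
    minute = np.floor(nni.times / 60.0).astype(int)
    uniq, inv, counts = np.unique(minute, return_inverse=True, return_counts=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inv, hr_beats)
    hr = sums / counts
    return MinuteSeries(uniq, np.maximum(hr, floor_bpm), kind="hr")


def read_mmash_participant(path: str) -> ParticipantRecord:
    """Read one MMASH-style CSV directory back into a record.

    Expects RR.csv, Actigraph.csv, Activity.csv and user.csv as written by
    :func:`wearsim.synthdata.write_mmash_participant`.  Diary rows that are
    out of order are sorted with a warning; missing files raise with the
    offending filename.
    """
    frames = {}
    for name in ("RR.csv", "Actigraph.csv", "Activity.csv", "user.csv"):
        fp = os.path.join(path, name)
        if not os.path.exists(fp):
            raise FileNotFoundError(f"missing MMASH file {name} in {path}")
        try:
            frames[name] = pd.read_csv(fp, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error context
            raise ValueError(f"unparsable CSV {fp}: {exc}") from exc

    act = frames["Activity.csv"]
    if not act["start_s"].is_monotonic_increasing:
        warnings.warn(f"diary rows out of order in {path}; sorting by start time")
        act = act.sort_values("start_s").reset_index(drop=True)
    diary = [
        ActivityInterval(float(r.start_s), float(r.end_s), str(r.category))
        for r in act.itertuples()
    ]
    user = frames["user.csv"].iloc[0]
    epochs = frames["Actigraph.csv"]["time_s"].to_numpy()
    epoch_s = float(epochs[1] - epochs[0]) if epochs.size > 1 else 1.0
    return ParticipantRecord(
        id=str(user["id"]),
        age=int(user["age"]),
        nni=NNISeries(
            frames["RR.csv"]["time_s"].to_numpy(), frames["RR.csv"]["ibi_ms"].to_numpy()
        ),
        steps=StepSeries(epochs, frames["Actigraph.csv"]["steps"].to_numpy(), epoch_s),
        diary=diary,
    )


@dataclass
class PreprocessedRecord:
    """The three analysis series of one participant plus metadata."""

    id: str
    age: int
    hr: MinuteSeries
    nni: NNISeries
    pmsc: MinuteSeries
    diary: list[ActivityInterval]
    latent: object = None

    @property
    def n_minutes(self) -> int:
        return int(np.ceil((self.diary[-1].end if self.diary else 0.0) / 60.0))


def preprocess_record(record: ParticipantRecord, trim_minutes: float = 5) -> PreprocessedRecord:
    """Standard preprocessing: trim, minute HR, PMSC with sleep removed."""
    trimmed = trim_initial(record, trim_minutes)
    hr = nni_to_minute_hr(trimmed.nni)
    pmsc = remove_sleep_pmsc(compute_pmsc(trimmed.steps), trimmed.diary)
    return PreprocessedRecord(
        id=trimmed.id,
        age=trimmed.age,
        hr=hr,
        nni=trimmed.nni,
        pmsc=pmsc,
        diary=trimmed.diary,
        latent=trimmed.latent,
    )
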