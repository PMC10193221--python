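"""Synthetic free-living cohorts with a known latent cardiac competence.

The generator emulates one day of wearable monitoring per participant: an
activity diary partitioning the record into sleep / rest / light / medium /
heavy-exercise blocks, a beat-to-beat NNI stream whose minute-averaged heart
rate sits on a low plateau (the latent baseline HR) during sleep and rest and
a high plateau (the latent peak HR) during heavy exercise, and a step-event
stream that is silent during sleep and elevated during exercise.  Because
baseline and peak HR are drawn explicitly and the cardiac competence index
(CCI) is derived from them, every downstream stage can be validated against
ground truth without any external data.

Model choices, deliberately minimal:

* HR between plateaus ramps linearly over ``transition_s`` seconds at the
  start of each diary interval (from the previous plateau to the new one).
* Sleep shares the rest plateau, so the minimum of the rolling 2-minute HR
  mean over rest windows recovers ``baseline_hr_true`` exactly at zero jitter.
* Beat-level jitter is i.i.d. Gaussian on instantaneous HR, clipped from
  below so NNIs stay positive.
* Steps are Poisson counts per epoch with a per-category rate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ActivityInterval,
    NNISeries,
    ParticipantRecord,
    StepSeries,
    SynthTruth,
    validate_diary,
)

__all__ = [
    "DiaryConfig",
    "StepRateConfig",
    "CohortConfig",
    "generate_activity_diary",
    "generate_nni_stream",
    "generate_step_stream",
    "generate_cohort",
    "write_mmash_participant",
]

#: Waking-block template after the sleep block, in order.  Activity bouts
#: carry a duration range as a fraction of the record (so a 20–40-minute
#: heavy-exercise bout at 24 h scales to 5–10 minutes on a 6-h record);
#: rest blocks (None) absorb the remaining time — a free-living day is
#: dominated by sitting/lying.
_DAY_TEMPLATE: tuple[tuple[str, tuple[float, float] | None], ...] = (
    ("rest", None),
    ("light", (0.030, 0.060)),
    ("rest", None),
    ("medium", (0.020, 0.042)),
    ("rest", None),
    ("heavy_exercise", (0.014, 0.028)),
    ("rest", None),
    ("light", (0.030, 0.060)),
    ("medium", (0.020, 0.042)),
    ("rest", None),
    ("heavy_exercise", (0.014, 0.028)),
    ("rest", None),
)


@dataclass(frozen=True)
class DiaryConfig:
    """Schedule parameters for the synthetic activity diary."""

    sleep_frac_range: tuple[float, float] = (0.28, 0.34)
    min_block_s: float = 120.0
    #: absolute floor on activity-bout length; keeps a full 2-minute window
    #: past the HR transition ramp even on short records
    min_bout_s: float = 300.0
    template: tuple[tuple[str, tuple[float, float] | None], ...] = _DAY_TEMPLATE


@dataclass(frozen=True)
class StepRateConfig:
    """Mean steps per minute by activity category; sleep must be 0."""

    sleep: float = 0.0
    rest: float = 3.0
    light: float = 40.0
    medium: float = 70.0
    heavy_exercise: float = 130.0

    def rate(self, category: str) -> float:
        return getattr(self, category)


@dataclass(frozen=True)
class CohortConfig:
    """Population-level parameters of the synthetic cohort.

    Defaults mirror a one-day, 21-subject study of healthy young adults.
    """

    n: int = 21
    duration_s: float = 86_400.0
    age_range: tuple[int, int] = (20, 30)
    baseline_hr_mean: float = 62.0
    baseline_hr_sd: float = 4.0
    cci_range: tuple[float, float] = (0.55, 1.05)
    jitter_bpm: float = 1.0
    transition_s: float = 60.0
    step_epoch_s: float = 1.0
    diary: DiaryConfig = field(default_factory=DiaryConfig)
    steps: StepRateConfig = field(default_factory=StepRateConfig)


def generate_activity_diary(
    duration_s: float, seed: int, config: DiaryConfig | None = None
) -> list[ActivityInterval]:
    """Partition ``[0, duration_s)`` into a sleep block plus activity blocks.

    The partition is gap-free and deterministic for a fixed seed.  Raises
    ``ValueError`` when the duration cannot accommodate the required blocks
    (at least one sleep, rest and heavy-exercise block).
    """
    config = config or DiaryConfig()
    if duration_s < 7200.0:
        raise ValueError(
            f"duration {duration_s} s too short: need at least 2 h to place "
            "sleep, rest and heavy-exercise blocks"
        )
    rng = np.random.default_rng(seed)
    sleep_s = duration_s * rng.uniform(*config.sleep_frac_range)
    remaining = duration_s - sleep_s

    durations = np.empty(len(config.template))
    for i, (_, frac) in enumerate(config.template):
        if frac is not None:
            durations[i] = max(duration_s * rng.uniform(*frac), config.min_bout_s)
    rest_idx = [i for i, (_, frac) in enumerate(config.template) if frac is None]
    rest_total = remaining - durations[[i for i in range(len(durations)) if i not in rest_idx]].sum()
    if rest_total < len(rest_idx) * config.min_block_s:
        raise ValueError("duration too short for the configured activity template")
    weights = rng.gamma(shape=2.0, scale=1.0, size=len(rest_idx))
    extra = rest_total - len(rest_idx) * config.min_block_s
    for j, i in enumerate(rest_idx):
        durations[i] = config.min_block_s + weights[j] / weights.sum() * extra

    bounds = np.concatenate([[0.0, sleep_s], sleep_s + np.cumsum(durations)])
    bounds[-1] = duration_s  # absorb float rounding in the last block
    categories = ("sleep",) + tuple(cat for cat, _ in config.template)
    diary = [
        ActivityInterval(start=float(a), end=float(b), category=c)
        for a, b, c in zip(bounds[:-1], bounds[1:], categories)
    ]
    validate_diary(diary, duration_s)
    return diary


def _category_plateau(category: str, truth: SynthTruth) -> float:
    """Target instantaneous HR plateau for a diary category."""
    base, peak = truth.baseline_hr_true, truth.peak_hr_true
    return {
        "sleep": base,
        "rest": base,
        "light": base + 0.25 * (peak - base),
        "medium": base + 0.60 * (peak - base),
        "heavy_exercise": peak,
    }[category]


def generate_nni_stream(
    diary: list[ActivityInterval],
    truth: SynthTruth,
    seed: int,
    jitter_bpm: float = 1.0,
    transition_s: float = 60.0,
    hr_clip_bpm: float = 20.0,
) -> NNISeries:
    """Simulate a beat-to-beat interval stream following the diary plateaus.

    Each beat's instantaneous HR is the diary-driven profile value at the
    beat's start plus Gaussian jitter (clipped at ``hr_clip_bpm`` from below);
    its NNI is 60/HR seconds and the next beat starts one NNI later.
    """
    validate_diary(diary)
    if jitter_bpm < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    values: list[np.ndarray] = []

    t = diary[0].start
    prev_plateau = _category_plateau(diary[0].category, truth)
    for interval in diary:
        plateau = _category_plateau(interval.category, truth)
        ramp_end = min(interval.start + transition_s, interval.end)
        # ramp: beat-by-beat, HR interpolates prev_plateau -> plateau
        while t < ramp_end:
            frac = (t - interval.start) / (ramp_end - interval.start)
            hr = prev_plateau + frac * (plateau - prev_plateau)
            if jitter_bpm:
                hr += rng.normal(0.0, jitter_bpm)
            hr = max(hr, hr_clip_bpm)
            nni_s = 60.0 / hr
            t += nni_s
            times.append(np.array([t]))
            values.append(np.array([nni_s * 1000.0]))
        # plateau: constant-HR stretch, generated in one batch
        while t < interval.end:
            span = interval.end - t
            n_est = int(span * (plateau + 4 * jitter_bpm) / 60.0 * 1.1) + 16
            hrs = np.full(n_est, plateau)
            if jitter_bpm:
                hrs = hrs + rng.normal(0.0, jitter_bpm, size=n_est)
            hrs = np.maximum(hrs, hr_clip_bpm)
            nni_s = 60.0 / hrs
            beat_t = t + np.cumsum(nni_s)
            keep = beat_t <= interval.end + 1e-12
            if not keep.any():
                t = beat_t[0]  # single beat crossing the boundary
                times.append(beat_t[:1])
                values.append(nni_s[:1] * 1000.0)
                break
            times.append(beat_t[keep])
            values.append(nni_s[keep] * 1000.0)
            t = beat_t[keep][-1]
        prev_plateau = plateau

    all_t = np.concatenate(times)
    all_v = np.concatenate(values)
    end = diary[-1].end
    inside = all_t <= end + 1e-9
    return NNISeries(all_t[inside], all_v[inside])


def generate_step_stream(
    diary: list[ActivityInterval],
    seed: int,
    rate_cfg: StepRateConfig | None = None,
    epoch_s: float = 1.0,
) -> StepSeries:
    """Poisson step counts on a uniform epoch grid, rate set by the diary."""
    rate_cfg = rate_cfg or StepRateConfig()
    for c in ("sleep", "rest", "light", "medium", "heavy_exercise"):
        if rate_cfg.rate(c) < 0:
            raise ValueError(f"negative step rate for category {c!r}")
    validate_diary(diary)
    rng = np.random.default_rng(seed)
    duration = diary[-1].end - diary[0].start
    n_epochs = int(np.floor(duration / epoch_s))
    epoch_t = diary[0].start + np.arange(n_epochs) * epoch_s

    starts = np.array([iv.start for iv in diary])
    rates_per_s = np.array([rate_cfg.rate(iv.category) / 60.0 for iv in diary])
    idx = np.searchsorted(starts, epoch_t, side="right") - 1
    lam = rates_per_s[idx] * epoch_s
    counts = rng.poisson(lam)
    return StepSeries(epoch_t, counts, epoch_s)


def generate_cohort(
    n: int | None = None, seed: int = 0, config: CohortConfig | None = None
) -> list[ParticipantRecord]:
    """Generate ``n`` participants with latent baseline/peak HR and CCI.

    Baseline and peak HR are drawn (peak via a uniform latent CCI), so every
    record carries a physically realizable NNI stream together with its
    ground-truth CCI.
    """
    config = config or CohortConfig()
    if n is None:
        n = config.n
    if n < 2:
        raise ValueError("need at least 2 participants (cross-validation undefined)")
    root = np.random.default_rng(seed)
    participant_seeds = root.integers(0, 2**31 - 1, size=(n, 3))

    cohort: list[ParticipantRecord] = []
    for i in range(n):
        rng = np.random.default_rng(int(participant_seeds[i, 0]))
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        baseline = float(
            np.clip(
                rng.normal(config.baseline_hr_mean, config.baseline_hr_sd), 45.0, 80.0
            )
        )
        cci = float(rng.uniform(*config.cci_range))
        peak = baseline + cci * ((220.0 - age) - baseline)
        truth = SynthTruth(baseline_hr_true=baseline, peak_hr_true=peak, age=age)

        diary = generate_activity_diary(config.duration_s, int(participant_seeds[i, 1]), config.diary)
        nni = generate_nni_stream(
            diary,
            truth,
            int(participant_seeds[i, 1]) ^ 0x5A5A5A,
            jitter_bpm=config.jitter_bpm,
            transition_s=config.transition_s,
        )
        steps = generate_step_stream(
            diary, int(participant_seeds[i, 2]), config.steps, config.step_epoch_s
        )
        cohort.append(
            ParticipantRecord(
                id=f"S{i + 1:02d}", age=age, nni=nni, steps=steps, diary=diary, latent=truth
            )
        )
    return cohort


def write_mmash_participant(record: ParticipantRecord, path: str) -> None:
    """Write one record as MMASH-style CSVs into ``path``.

    Files: ``RR.csv`` (time_s, ibi_ms), ``Actigraph.csv`` (time_s, steps),
    ``Activity.csv`` (start_s, end_s, category), ``user.csv`` (id, age).
    Times are seconds from the record origin.  Latent truth is not written.
    """
    os.makedirs(path, exist_ok=True)
    pd.DataFrame({"time_s": record.nni.times, "ibi_ms": record.nni.values}).to_csv(
        os.path.join(path, "RR.csv"), index=False
    )
    pd.DataFrame({"time_s": record.steps.times, "steps": record.steps.values}).to_csv(
        os.path.join(path, "Actigraph.csv"), index=False
    )
    pd.DataFrame(
        {
            "start_s": [iv.start for iv in record.diary],
            "end_s": [iv.end for iv in record.diary],
            "category": [iv.category for iv in record.diary],
        }
    ).to_csv(os.path.join(path, "Activity.csv"), index=False)
    pd.DataFrame({"id": [record.id], "age": [record.age]}).to_csv(
        os.path.join(path, "user.csv"), index=False
    )
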