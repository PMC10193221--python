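"""Graded degradation of the analysis series: missingness, flicker noise,
positive bias, and all three combined.

Missingness removes randomly placed segments of 1–5 minutes until the
target fraction of the record is covered; inside removed segments HR is set
to 35 bpm, NNI to 500 ms and PMSC to 0.  Flicker (pink, 1/f) noise is
generated by FFT spectral shaping, rescaled so its standard deviation equals
``level`` times the series mean, and added; HR and NNI are then rectified
(absolute value, floor 1) and PMSC floored at 0.  Bias adds ``level`` times
the series mean to every value.  The combined family applies noise, then
bias, then missingness, so the replacement values inside removed segments
are exact.

Each family has a 75-level grid: missingness 5%→93.8% in 1.2% steps,
noise/bias 2%→150% in 2% steps, and the combined grid pairs levels by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessedRecord
from .types import MinuteSeries, NNISeries

__all__ = [
    "KINDS",
    "MISSING_HR_BPM",
    "MISSING_NNI_MS",
    "PerturbationSpec",
    "PerturbationGrid",
    "build_grid",
    "pink_noise",
    "draw_removal_mask",
    "apply_missingness",
    "apply_flicker_noise",
    "apply_bias",
    "apply_combined",
    "apply_spec",
]

KINDS = ("missing", "noise", "bias", "combined")

#: Replacement values inside removed segments.
MISSING_HR_BPM = 35.0
MISSING_NNI_MS = 500.0
MISSING_PMSC = 0.0

GRID_SIZE = 75


@dataclass(frozen=True)
class PerturbationSpec:
    """One grid cell: a perturbation family at one level.

    ``level`` is the removed fraction for missingness and the noise/bias
    magnitude as a fraction of the series mean otherwise; for the combined
    family it is the 1-based grid index shared by the three components.
    """

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass(frozen=True)
class PerturbationGrid:
    kind: str
    specs: tuple[PerturbationSpec, ...]

    def __len__(self) -> int:
        return len(self.specs)


def grid_levels(kind: str) -> np.ndarray:
    """The 75 grid levels of a family (fractions; combined: 1-based indices)."""
    if kind == "missing":
        return (5.0 + 1.2 * np.arange(GRID_SIZE)) / 100.0
    if kind in ("noise", "bias"):
        return (2.0 * np.arange(1, GRID_SIZE + 1)) / 100.0
    if kind == "combined":
        return np.arange(1, GRID_SIZE + 1, dtype=float)
    raise ValueError(f"unknown perturbation kind {kind!r}")


def build_grid(kind: str, seed: int = 0) -> PerturbationGrid:
    """The ordered 75-spec grid of one family."""
    specs = tuple(
        PerturbationSpec(kind=kind, level=float(lv), seed=seed) for lv in grid_levels(kind)
    )
    return PerturbationGrid(kind=kind, specs=specs)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean 1/f (flicker) noise of length ``n``, unit standard deviation.

    Gaussian Fourier coefficients are shaped by f^{-1/2} (so the power
    spectral density falls as 1/f) and inverse-transformed; the DC component
    is zeroed.
    """
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** -0.5
    coeff = amp * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    y = np.fft.irfft(coeff, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def draw_removal_mask(
    n_minutes: int,
    p: float,
    seg_min: int = 1,
    seg_max: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean mask of removed minutes, drawn segment by segment.

    Segment lengths are uniform on [seg_min, seg_max] minutes and starts
    uniform over positions where the whole segment is still free; drawing
    stops once at least ``p·n_minutes`` minutes are removed (the last segment
    may overshoot by less than its own length).
    """
    if not 0.0 <= p <= 0.95:
        raise ValueError(f"missingness fraction {p} outside [0, 0.95]")
    rng = rng if rng is not None else np.random.default_rng()
    mask = np.zeros(n_minutes, dtype=bool)
    target = p * n_minutes
    while mask.sum() < target:
        length = int(rng.integers(seg_min, seg_max + 1))
        while length >= 1:
            # starts whose whole segment is free
            free = ~mask
            ok = np.ones(n_minutes - length + 1, dtype=bool)
            for off in range(length):
                ok &= free[off : n_minutes - length + 1 + off]
            candidates = np.flatnonzero(ok)
            if candidates.size:
                start = int(rng.choice(candidates))
                mask[start : start + length] = True
                break
            length -= 1
        else:
            break  # no free minute left
    return mask


def _minutes_to_mask(index: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Which entries of a minute index array fall on removed minutes."""
    out = np.zeros(index.size, dtype=bool)
    valid = (index >= 0) & (index < mask.size)
    out[valid] = mask[index[valid]]
    return out


def apply_missingness(
    record: PreprocessedRecord,
    p: float,
    seg_min: int = 1,
    seg_max: int = 5,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> PreprocessedRecord:
    """Remove 1–5-minute segments totalling fraction ``p`` of the record.

    One removal mask over the record's minute timeline is shared by all
    three series: removed HR minutes become 35 bpm, removed NNIs 500 ms, and
    removed PMSC minutes 0.  ``p=0`` is the identity.
    """
    n_minutes = record.n_minutes
    if mask is None:
        mask = draw_removal_mask(n_minutes, p, seg_min, seg_max, np.random.default_rng(seed))
    hr = record.hr.copy()
    hr.values[_minutes_to_mask(hr.index, mask)] = MISSING_HR_BPM
    pmsc = record.pmsc.copy()
    pmsc.values[_minutes_to_mask(pmsc.index, mask)] = MISSING_PMSC
    nni = record.nni.copy()
    beat_minute = np.floor(nni.times / 60.0).astype(int)
    nni.values[_minutes_to_mask(beat_minute, mask)] = MISSING_NNI_MS
    return PreprocessedRecord(
        id=record.id, age=record.age, hr=hr, nni=nni, pmsc=pmsc,
        diary=record.diary, latent=record.latent,
    )


def _check_level(level: float) -> None:
    if not 0.0 <= level <= 1.5:
        raise ValueError(f"perturbation level {level} outside [0, 1.5]")


def _post_noise(values: np.ndarray, kind: str) -> np.ndarray:
    """Post-processing after additive noise: rectify HR/NNI, floor PMSC."""
    if kind in ("hr", "nni"):
        return np.maximum(np.abs(values), 1.0)
    return np.maximum(values, 0.0)


def apply_flicker_noise(series, level: float, seed: int = 0):
    """Add 1/f noise with SD = level × mean(series); rectify per series kind.

    Accepts a :class:`MinuteSeries` (HR or PMSC) or an :class:`NNISeries`;
    ``level=0`` returns an identical copy.
    """
    _check_level(level)
    out = series.copy()
    if level == 0.0 or len(out) < 2:
        return out
    rng = np.random.default_rng(seed)
    noise = pink_noise(len(out), rng) * level * float(np.mean(out.values))
    kind = "nni" if isinstance(series, NNISeries) else series.kind
    out.values = _post_noise(out.values + noise, kind)
    return out


def apply_bias(series, level: float):
    """Shift every value by +level × mean(series); deterministic."""
    _check_level(level)
    out = series.copy()
    if level == 0.0:
        return out
    out.values = out.values + level * float(np.mean(out.values))
    return out


def _perturb_all_series(record: PreprocessedRecord, fn) -> PreprocessedRecord:
    return PreprocessedRecord(
        id=record.id, age=record.age,
        hr=fn(record.hr, "hr"), nni=fn(record.nni, "nni"), pmsc=fn(record.pmsc, "pmsc"),
        diary=record.diary, latent=record.latent,
    )


def apply_combined(record: PreprocessedRecord, idx: int, seed: int = 0) -> PreprocessedRecord:
    """Noise, then bias, then missingness at index-paired levels.

    Grid index ``idx`` in [1, 75] maps to a 2·idx % noise and bias level and
    a (5 + 1.2·(idx−1)) % missingness fraction.  Missingness is applied last
    so removed segments contain exactly the replacement values.
    """
    if not 1 <= idx <= GRID_SIZE:
        raise ValueError(f"combined grid index {idx} outside [1, {GRID_SIZE}]")
    noise_level = 0.02 * idx
    missing_p = (5.0 + 1.2 * (idx - 1)) / 100.0
    ss = np.random.SeedSequence([seed, idx])
    noise_seeds = ss.generate_state(3) >> 1  # independent noise per series
    out = _perturb_all_series(
        record,
        lambda s, k, _ns=noise_seeds: apply_flicker_noise(
            s, noise_level, int(_ns[("hr", "nni", "pmsc").index(k)])
        ),
    )
    out = _perturb_all_series(out, lambda s, k: apply_bias(s, noise_level))
    return apply_missingness(out, missing_p, seed=int(ss.generate_state(4)[3] >> 1))


def apply_spec(record: PreprocessedRecord, spec: PerturbationSpec) -> PreprocessedRecord:
    """Dispatch one grid cell to its family."""
    if spec.kind == "missing":
        return apply_missingness(record, spec.level, seed=spec.seed)
    if spec.kind == "noise":
        ss = np.random.SeedSequence([spec.seed, int(round(spec.level * 1000))])
        seeds = ss.generate_state(3) >> 1
        return _perturb_all_series(
            record,
            lambda s, k, _sd=seeds: apply_flicker_noise(
                s, spec.level, int(_sd[("hr", "nni", "pmsc").index(k)])
            ),
        )
    if spec.kind == "bias":
        return _perturb_all_series(record, lambda s, k: apply_bias(s, spec.level))
    if spec.kind == "combined":
        return apply_combined(record, int(spec.level), seed=spec.seed)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")
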