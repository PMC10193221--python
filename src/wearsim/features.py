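"""Per-participant feature vectors from the HR, NNI and PMSC series.

Five families:

* time-domain NNI statistics (median, mean, SD, RMSSD, RMS of the values,
  range, pNN50) and HR statistics (max, min, mean, SD);
* frequency-domain HRV: VLF/LF/HF band powers of the NNI tachogram
  (linearly interpolated to a uniform 4 Hz grid, Welch spectrum), the LF/HF
  ratio and the normalized LF/HF powers;
* Poincaré plot dispersion: SD1 (perpendicular to the line of identity),
  SD2 (along it) and their ratio;
* PMSC summaries: max, median, 25th and 75th percentile;
* a generic time-series catalog applied to each of the three series:
  autocorrelations at lags 1–10, partial autocorrelations at lags 1–5, the
  lag-1 autocorrelation of the differenced series, quantiles at
  {1,5,25,50,75,95,99}%, and the proportion of lag-1 jumps whose magnitude
  exceeds k·SD for k in {1,2,3}.

Conventions declared once and used everywhere: population (ddof=0) variance;
quantiles by linear interpolation between order statistics; autocorrelation
features of a constant series are 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .preprocess import PreprocessedRecord
from .types import MinuteSeries, NNISeries

__all__ = [
    "CATALOG_VERSION",
    "BandDefinition",
    "time_domain_features",
    "frequency_domain_features",
    "poincare_features",
    "pmsc_summary_features",
    "generic_ts_features",
    "extract_all",
    "catalog_size",
]

#: Bumped whenever the feature catalog changes; echoed into results metadata.
CATALOG_VERSION = "1.0"

_ACF_LAGS = 10
_PACF_LAGS = 5
_QUANTILES = (1, 5, 25, 50, 75, 95, 99)
_JUMP_KS = (1, 2, 3)

#: Features per generic catalog application: 10 acf + 5 pacf + 1 diff-acf
#: + 7 quantiles + 3 jump proportions.
GENERIC_CATALOG_SIZE = _ACF_LAGS + _PACF_LAGS + 1 + len(_QUANTILES) + len(_JUMP_KS)


@dataclass(frozen=True)
class BandDefinition:
    """HRV spectral bands in Hz (contiguous, increasing)."""

    vlf: tuple[float, float] = (0.003, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self) -> None:
        increasing = self.vlf[0] < self.vlf[1] and self.lf[0] < self.lf[1] and self.hf[0] < self.hf[1]
        contiguous = self.vlf[1] == self.lf[0] and self.lf[1] == self.hf[0]
        if not (increasing and contiguous):
            raise ValueError("bands must be contiguous, non-overlapping and increasing")


def time_domain_features(nni: NNISeries, hr: MinuteSeries) -> dict[str, float]:
    """Time-domain NNI and per-minute HR statistics.

    pNN50 is the percentage of successive NNI differences exceeding 50 ms in
    magnitude; RMSSD the root mean square of those differences; ``nni_rms``
    additionally reports the RMS of the NNI values themselves.
    """
    if len(nni) < 2:
        raise ValueError("need at least 2 NNIs for successive differences")
    if len(hr) < 1:
        raise ValueError("need at least 1 HR minute")
    v = nni.values
    d = np.diff(v)
    return {
        "nni_median": float(np.median(v)),
        "nni_mean": float(np.mean(v)),
        "nni_sd": float(np.std(v)),
        "nni_rmssd": float(np.sqrt(np.mean(d**2))),
        "nni_rms": float(np.sqrt(np.mean(v**2))),
        "nni_range": float(np.ptp(v)),
        "nni_pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)),
        "hr_max": float(np.max(hr.values)),
        "hr_min": float(np.min(hr.values)),
        "hr_mean": float(np.mean(hr.values)),
        "hr_sd": float(np.std(hr.values)),
    }


def frequency_domain_features(
    nni: NNISeries,
    bands: BandDefinition | None = None,
    resample_hz: float = 4.0,
) -> dict[str, float]:
    """Band powers of the NNI tachogram.

    The irregular beat series is linearly interpolated to a uniform
    ``resample_hz`` grid and its power spectral density estimated by Welch's
    method with a segment long enough to resolve at least two VLF periods;
    band powers are the integrated PSD over each band.
    """
    bands = bands or BandDefinition()
    span = nni.times[-1] - nni.times[0] if len(nni) else 0.0
    if span < 300.0:
        raise ValueError(f"NNI span of {span:.0f} s too short for VLF estimation (need >= 300 s)")
    grid = np.arange(nni.times[0], nni.times[-1], 1.0 / resample_hz)
    tachogram = np.interp(grid, nni.times, nni.values)
    nperseg = min(tachogram.size, 4096)
    freqs, psd = signal.welch(tachogram, fs=resample_hz, nperseg=nperseg)
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(np.sum(psd[m]) * df)

    vlf = band_power(*bands.vlf)
    lf = band_power(*bands.lf)
    hf = band_power(*bands.hf)
    if hf == 0.0:
        raise ValueError("HF band power is zero; LF/HF ratio undefined")
    return {
        "nni_vlf_power": vlf,
        "nni_lf_power": lf,
        "nni_hf_power": hf,
        "nni_lf_hf_ratio": lf / hf,
        "nni_lf_norm": lf / (lf + hf),
        "nni_hf_norm": hf / (lf + hf),
    }


def poincare_features(nni: NNISeries) -> dict[str, float]:
    """Poincaré plot dispersion of successive NNI pairs.

    SD1 and SD2 are the standard deviations of the (NNI[i], NNI[i+1]) cloud
    projected perpendicular to and onto the line of identity:
    SD1² = ½·var(ΔNNI), SD2² = 2·var(NNI) − ½·var(ΔNNI).
    """
    if len(nni) < 3:
        raise ValueError("need at least 3 NNIs for Poincaré statistics")
    v = nni.values
    d = np.diff(v)
    sd1_sq = 0.5 * np.var(d)
    sd2_sq = 2.0 * np.var(v) - 0.5 * np.var(d)
    sd1 = float(np.sqrt(sd1_sq))
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    if sd2 == 0.0:
        raise ValueError("SD2 is zero (degenerate Poincaré plot); ratio undefined")
    return {"nni_sd1": sd1, "nni_sd2": sd2, "nni_sd_ratio": sd1 / sd2}


def pmsc_summary_features(pmsc: MinuteSeries) -> dict[str, float]:
    """Max, median and quartiles of the per-minute step count."""
    if len(pmsc) == 0:
        raise ValueError("empty PMSC series")
    v = pmsc.values
    return {
        "pmsc_max": float(np.max(v)),
        "pmsc_median": float(np.quantile(v, 0.50)),
        "pmsc_q25": float(np.quantile(v, 0.25)),
        "pmsc_q75": float(np.quantile(v, 0.75)),
    }


def generic_ts_features(values: np.ndarray, prefix: str) -> dict[str, float]:
    """The fixed generic catalog on one value sequence (see module docstring).

    Constant series get 0 for every correlation feature by convention, and 0
    jump proportions (the jump threshold k·SD degenerates to 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < _ACF_LAGS + 2:
        raise ValueError(f"series of length {x.size} too short for lag-{_ACF_LAGS} features")
    out: dict[str, float] = {}
    constant = np.std(x) == 0.0
    if constant:
        ac = np.zeros(_ACF_LAGS)
        pac = np.zeros(_PACF_LAGS)
        diff_ac1 = 0.0
    else:
        ac = np.nan_to_num(_sm_acf(x, nlags=_ACF_LAGS, fft=True)[1:])
        pac = np.nan_to_num(_sm_pacf(x, nlags=_PACF_LAGS, method="ywm")[1:])
        dx = np.diff(x)
        diff_ac1 = 0.0 if np.std(dx) == 0.0 else float(np.nan_to_num(_sm_acf(dx, nlags=1, fft=True)[1]))
    for k in range(_ACF_LAGS):
        out[f"{prefix}_acf_{k + 1}"] = float(ac[k])
    for k in range(_PACF_LAGS):
        out[f"{prefix}_pacf_{k + 1}"] = float(pac[k])
    out[f"{prefix}_diff_acf_1"] = diff_ac1
    for q in _QUANTILES:
        out[f"{prefix}_quant_{q:02d}"] = float(np.quantile(x, q / 100.0))
    sd = np.std(x)
    jumps = np.abs(np.diff(x))
    for k in _JUMP_KS:
        out[f"{prefix}_jump_gt{k}sd"] = (
            0.0 if constant else float(np.mean(jumps > k * sd))
        )
    return out


def catalog_size() -> int:
    """Total number of features emitted by :func:`extract_all`."""
    return 11 + 6 + 3 + 4 + 3 * GENERIC_CATALOG_SIZE


def extract_all(record: PreprocessedRecord) -> dict[str, float]:
    """Union of all feature families over HR, NNI and PMSC series.

    Deterministic; raises if any family's preconditions fail (features of
    empty or degenerate inputs are rejected rather than silently imputed).
    """
    out: dict[str, float] = {}
    out.update(time_domain_features(record.nni, record.hr))
    out.update(frequency_domain_features(record.nni))
    out.update(poincare_features(record.nni))
    out.update(pmsc_summary_features(record.pmsc))
    out.update(generic_ts_features(record.hr.values, "hr"))
    out.update(generic_ts_features(record.nni.values, "nni"))
    out.update(generic_ts_features(record.pmsc.values, "pmsc"))
    assert len(out) == catalog_size()
    return out
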