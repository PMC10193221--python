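"""Feature families against independent oracles and invariance properties."""

import numpy as np
import pytest

from wearsim.features import (
    BandDefinition,
    catalog_size,
    extract_all,
    frequency_domain_features,
    generic_ts_features,
    pmsc_summary_features,
    poincare_features,
    time_domain_features,
)
from wearsim.preprocess import preprocess_record
from wearsim.types import MinuteSeries, NNISeries

from conftest import make_minutes, make_nni


class TestTimeDomain:
    def test_pnn50_worked_example(self):
        # diffs 60, 10, 120 -> 2 of 3 exceed 50 ms
        fv = time_domain_features(make_nni([800, 860, 870, 990]), make_minutes([70.0]))
        assert fv["nni_pnn50"] == pytest.approx(200.0 / 3.0)

    def test_constant_series_degenerate_stats(self):
        fv = time_domain_features(make_nni([900.0] * 50), make_minutes([66.7]))
        assert fv["nni_sd"] == 0 and fv["nni_range"] == 0
        assert fv["nni_pnn50"] == 0 and fv["nni_rmssd"] == 0

    def test_against_brute_force(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(500, 1200, size=100)
        hrv = rng.uniform(50, 150, size=30)
        fv = time_domain_features(make_nni(v), make_minutes(hrv))
        d = [b - a for a, b in zip(v, v[1:])]
        s = sorted(v)
        assert fv["nni_median"] == pytest.approx((s[49] + s[50]) / 2)
        assert fv["nni_mean"] == pytest.approx(sum(v) / len(v))
        assert fv["nni_sd"] == pytest.approx(np.sqrt(sum((x - v.mean()) ** 2 for x in v) / len(v)))
        assert fv["nni_rmssd"] == pytest.approx(np.sqrt(sum(x**2 for x in d) / len(d)))
        assert fv["nni_rms"] == pytest.approx(np.sqrt(sum(x**2 for x in v) / len(v)))
        assert fv["nni_range"] == pytest.approx(max(v) - min(v))
        assert fv["nni_pnn50"] == pytest.approx(100 * sum(abs(x) > 50 for x in d) / len(d))
        assert fv["hr_max"] == max(hrv) and fv["hr_min"] == min(hrv)
        assert fv["hr_mean"] == pytest.approx(hrv.mean())
        assert fv["hr_sd"] == pytest.approx(hrv.std())

    def test_single_nni_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features(make_nni([800.0]), make_minutes([60.0]))


class TestFrequencyDomain:
    def test_normalized_powers_sum_to_one(self):
        rng = np.random.default_rng(0)
        fv = frequency_domain_features(make_nni(rng.uniform(700, 900, size=600)))
        assert fv["nni_lf_norm"] + fv["nni_hf_norm"] == pytest.approx(1.0)

    def test_pure_hf_sinusoid_dominates(self):
        # 0.25 Hz modulation of the tachogram lands in the HF band
        n = 1200
        mean_nni = 800.0
        t = np.cumsum(np.full(n, mean_nni)) / 1000.0
        values = mean_nni + 50.0 * np.sin(2 * np.pi * 0.25 * t)
        fv = frequency_domain_features(NNISeries(t, values))
        assert fv["nni_hf_power"] >= 10 * fv["nni_lf_power"]

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        nni = make_nni(rng.uniform(700, 900, size=600))
        assert frequency_domain_features(nni) == frequency_domain_features(nni)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            frequency_domain_features(make_nni([800.0] * 10))

    def test_bad_bands_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition(vlf=(0.003, 0.04), lf=(0.05, 0.15), hf=(0.15, 0.4))


class TestPoincare:
    def test_constant_rejected_ratio(self):
        with pytest.raises(ValueError, match="SD2"):
            poincare_features(make_nni([800.0] * 10))

    @pytest.mark.parametrize("seed", range(5))
    def test_sd1_matches_projection_exactly(self, seed):
        """SD1 equals the SD of the projection onto the anti-identity line."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(600, 1100, size=500)
        fv = poincare_features(make_nni(v))
        perp = (v[1:] - v[:-1]) / np.sqrt(2)
        assert fv["nni_sd1"] == pytest.approx(np.std(perp))

    @pytest.mark.parametrize("seed", range(5))
    def test_sd2_matches_projection_asymptotically(self, seed):
        """SD2 via 2·var−½·var(diff) agrees with the identity-line projection
        up to O(1/n) edge terms."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(600, 1100, size=2000)
        fv = poincare_features(make_nni(v))
        ident = (v[1:] + v[:-1]) / np.sqrt(2)
        assert fv["nni_sd2"] == pytest.approx(np.std(ident - ident.mean()), rel=0.02)

    def test_alternating_series_wide_sd1(self):
        rng = np.random.default_rng(9)
        v = np.tile([800.0, 1000.0], 50) + rng.normal(0, 5, size=100)
        fv = poincare_features(make_nni(v))
        # successive jumps dominate: dispersion across identity exceeds along it
        assert fv["nni_sd1"] > fv["nni_sd2"]


class TestPmscSummary:
    def test_worked_example(self):
        fv = pmsc_summary_features(make_minutes([0, 10, 20, 30, 40], kind="pmsc"))
        assert (fv["pmsc_max"], fv["pmsc_median"], fv["pmsc_q25"], fv["pmsc_q75"]) == (
            40, 20, 10, 30,
        )

    def test_constant(self):
        fv = pmsc_summary_features(make_minutes([7.0] * 9, kind="pmsc"))
        assert set(fv.values()) == {7.0}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.integers(0, 150, size=50).astype(float)
        a = pmsc_summary_features(make_minutes(v, kind="pmsc"))
        b = pmsc_summary_features(make_minutes(rng.permutation(v), kind="pmsc"))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pmsc_summary_features(make_minutes([], kind="pmsc"))


class TestGenericCatalog:
    def test_constant_series_convention(self):
        fv = generic_ts_features(np.full(50, 3.0), "x")
        for k in [f"x_acf_{i}" for i in range(1, 11)] + [f"x_pacf_{i}" for i in range(1, 6)]:
            assert fv[k] == 0.0
        assert fv["x_diff_acf_1"] == 0.0
        assert fv["x_jump_gt1sd"] == 0.0

    def test_ar1_acf_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + eps[i]
        fv = generic_ts_features(x, "x")
        assert fv["x_acf_1"] == pytest.approx(0.8, abs=0.05)

    def test_quantiles_match_sorting(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        fv = generic_ts_features(x, "x")
        s = np.sort(x)
        for q in (1, 5, 25, 50, 75, 95, 99):
            h = (len(s) - 1) * q / 100.0
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expect = s[lo] + (h - lo) * (s[hi] - s[lo])
            assert fv[f"x_quant_{q:02d}"] == pytest.approx(expect)

    def test_scale_invariance_of_autocorrelations(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        a = generic_ts_features(x, "x")
        b = generic_ts_features(5.0 * x + 2.0, "x")
        for i in range(1, 11):
            assert a[f"x_acf_{i}"] == pytest.approx(b[f"x_acf_{i}"], abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generic_ts_features(np.arange(5.0), "x")


class TestExtractAll:
    def test_composition_and_count(self, small_cohort):
        rec = preprocess_record(small_cohort[0])
        fv = extract_all(rec)
        assert len(fv) == catalog_size()
        assert all(np.isfinite(v) for v in fv.values())
        # composition: each family value equals its direct call
        td = time_domain_features(rec.nni, rec.hr)
        for k, v in td.items():
            assert fv[k] == v
        pc = poincare_features(rec.nni)
        for k, v in pc.items():
            assert fv[k] == v

    def test_identical_records_identical_vectors(self, small_cohort):
        rec = preprocess_record(small_cohort[0])
        assert extract_all(rec) == extract_all(rec)

    def test_all_finite_on_cohort(self, small_cohort):
        for r in small_cohort:
            fv = extract_all(preprocess_record(r))
            assert all(np.isfinite(v) for v in fv.values())
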