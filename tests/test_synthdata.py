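"""Synthetic cohort generator: schedule, streams, determinism, round-trip."""

import numpy as np
import pytest

from wearsim.preprocess import preprocess_record, read_mmash_participant
from wearsim.synthdata import (
    CohortConfig,
    DiaryConfig,
    StepRateConfig,
    generate_activity_diary,
    generate_cohort,
    generate_nni_stream,
    generate_step_stream,
    write_mmash_participant,
)
from wearsim.types import ActivityInterval, SynthTruth


class TestDiary:
    def test_gap_free_partition(self):
        diary = generate_activity_diary(24 * 3600.0, seed=7)
        assert diary[0].start == 0.0
        assert diary[-1].end == 24 * 3600.0
        for a, b in zip(diary, diary[1:]):
            assert a.end == b.start
        # total duration conserved exactly
        assert sum(iv.duration for iv in diary) == pytest.approx(24 * 3600.0, abs=1e-9)

    def test_required_categories_present(self):
        cats = {iv.category for iv in generate_activity_diary(24 * 3600.0, seed=7)}
        assert {"sleep", "rest", "heavy_exercise"} <= cats

    def test_deterministic(self):
        d1 = generate_activity_diary(24 * 3600.0, seed=7)
        d2 = generate_activity_diary(24 * 3600.0, seed=7)
        assert d1 == d2

    def test_infeasible_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_activity_diary(60.0, seed=0)


class TestNNIStream:
    def test_zero_jitter_rest_nni_is_1000ms(self, simple_diary):
        truth = SynthTruth(baseline_hr_true=60.0, peak_hr_true=180.0, age=25)
        nni = generate_nni_stream(simple_diary, truth, seed=0, jitter_bpm=0.0)
        # beats well inside the first rest block, past the transition ramp
        inside = (nni.times > 3700.0) & (nni.times < 7200.0)
        assert np.allclose(nni.values[inside], 1000.0)

    def test_zero_jitter_exercise_nni(self, simple_diary):
        truth = SynthTruth(baseline_hr_true=60.0, peak_hr_true=180.0, age=25)
        nni = generate_nni_stream(simple_diary, truth, seed=0, jitter_bpm=0.0)
        inside = (nni.times > 7300.0) & (nni.times < 9000.0)
        assert np.allclose(nni.values[inside], 60000.0 / 180.0, rtol=1e-9)

    def test_times_match_values(self, simple_diary):
        truth = SynthTruth(baseline_hr_true=60.0, peak_hr_true=180.0, age=25)
        nni = generate_nni_stream(simple_diary, truth, seed=3, jitter_bpm=2.0)
        assert np.all(nni.values > 0)
        np.testing.assert_allclose(
            np.diff(nni.times) * 1000.0, nni.values[1:], rtol=1e-9
        )

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            SynthTruth(baseline_hr_true=90.0, peak_hr_true=80.0, age=25)


class TestStepStream:
    def test_all_sleep_all_zero(self):
        diary = [ActivityInterval(0.0, 3600.0, "sleep")]
        steps = generate_step_stream(diary, seed=1)
        assert np.all(steps.values == 0)

    def test_exercise_exceeds_rest(self):
        diary = [
            ActivityInterval(0.0, 3600.0, "rest"),
            ActivityInterval(3600.0, 7200.0, "heavy_exercise"),
        ]
        steps = generate_step_stream(diary, seed=5)
        rest = steps.values[steps.times < 3600.0]
        exer = steps.values[steps.times >= 3600.0]
        assert exer.mean() > rest.mean()

    def test_deterministic(self, simple_diary):
        s1 = generate_step_stream(simple_diary, seed=9)
        s2 = generate_step_stream(simple_diary, seed=9)
        assert np.array_equal(s1.values, s2.values)

    def test_negative_rate_rejected(self, simple_diary):
        with pytest.raises(ValueError):
            generate_step_stream(simple_diary, seed=0, rate_cfg=StepRateConfig(rest=-1.0))


class TestCohort:
    def test_count_and_truth_invariants(self, small_cohort):
        assert len(small_cohort) == 3
        for rec in small_cohort:
            t = rec.latent
            assert t.peak_hr_true > t.baseline_hr_true
            assert 0 < t.cci_true <= 1.2
            assert 18 <= rec.age <= 80
            expected = (t.peak_hr_true - t.baseline_hr_true) / (
                (220 - rec.age) - t.baseline_hr_true
            )
            assert t.cci_true == pytest.approx(expected)

    def test_bit_identical_for_same_seed(self):
        cfg = CohortConfig(n=2, duration_s=2.5 * 3600.0)
        a = generate_cohort(seed=3, config=cfg)
        b = generate_cohort(seed=3, config=cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.nni.values, rb.nni.values)
            assert np.array_equal(ra.steps.values, rb.steps.values)
            assert ra.diary == rb.diary

    def test_seed_sensitivity(self):
        cfg = CohortConfig(n=2, duration_s=2.5 * 3600.0)
        a = generate_cohort(seed=3, config=cfg)
        b = generate_cohort(seed=4, config=cfg)
        assert not np.array_equal(a[0].nni.values, b[0].nni.values)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n=1, seed=0)


class TestMmashRoundTrip:
    def test_writer_reader_round_trip(self, small_cohort, tmp_path):
        rec = small_cohort[0]
        write_mmash_participant(rec, str(tmp_path / "p1"))
        back = read_mmash_participant(str(tmp_path / "p1"))
        assert back.id == rec.id and back.age == rec.age
        np.testing.assert_array_equal(back.nni.values, rec.nni.values)
        np.testing.assert_array_equal(back.steps.values, rec.steps.values)
        assert [iv.category for iv in back.diary] == [iv.category for iv in rec.diary]

    def test_missing_file_named_in_error(self, small_cohort, tmp_path):
        rec = small_cohort[0]
        write_mmash_participant(rec, str(tmp_path / "p1"))
        (tmp_path / "p1" / "RR.csv").unlink()
        with pytest.raises(FileNotFoundError, match="RR.csv"):
            read_mmash_participant(str(tmp_path / "p1"))

    def test_unordered_diary_sorted_with_warning(self, small_cohort, tmp_path):
        rec = small_cohort[0]
        write_mmash_participant(rec, str(tmp_path / "p1"))
        f = tmp_path / "p1" / "Activity.csv"
        lines = f.read_text().splitlines()
        lines[1:] = lines[1:][::-1]  # reverse the diary rows
        f.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="out of order"):
            back = read_mmash_participant(str(tmp_path / "p1"))
        starts = [iv.start for iv in back.diary]
        assert starts == sorted(starts)


def test_end_to_end_cci_recovery_zero_jitter():
    """Full pipeline on a zero-jitter cohort recovers the latent CCI."""
    cfg = CohortConfig(n=2, duration_s=3 * 3600.0, jitter_bpm=0.0)
    for rec in generate_cohort(seed=5, config=cfg):
        from wearsim.cci import compute_cci

        got = compute_cci(preprocess_record(rec)).cci
        assert got == pytest.approx(rec.latent.cci_true, abs=0.02)
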