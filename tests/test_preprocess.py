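"""Preprocessing: parsing, resampling/clipping, non-wear, QC, epoching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepstagekit.core import RawRecording
from sleepstagekit.preprocess import (
    PreprocessConfig,
    detect_nonwear,
    epochize,
    quality_check,
    read_recording,
    resample_clip,
)
from tests.conftest import constant_recording


def _write_csv(path, rows, header="time,x,y,z"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestReadRecording:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, [
            "2024-01-01T00:00:00.000,0.1,0.2,0.9",
            "2024-01-01T00:00:00.033,0.1,0.2,0.9",
            "2024-01-01T00:00:00.067,0.1,0.2,0.9",
        ])
        rec, qc = read_recording(p)
        assert qc.parse_ok and not qc.excluded
        assert rec.n_samples == 3
        assert abs(rec.sample_rate - 30) < 1

    def test_non_numeric_value_is_unparseable(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, [
            "2024-01-01T00:00:00.000,0.1,0.2,0.9",
            "2024-01-01T00:00:00.033,oops,0.2,0.9",
        ])
        rec, qc = read_recording(p)
        assert rec is None
        assert qc.excluded and not qc.parse_ok
        assert "unparseable" in qc.reasons

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("")
        rec, qc = read_recording(p)
        assert rec is None and qc.excluded

    def test_non_monotone_timestamps(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, [
            "2024-01-01T00:00:01,0.1,0.2,0.9",
            "2024-01-01T00:00:00,0.1,0.2,0.9",
        ])
        rec, qc = read_recording(p)
        assert rec is None and "unparseable" in qc.reasons

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "r.csv"
        _write_csv(p, ["2024-01-01T00:00:00,0.1"], header="time,x")
        rec, qc = read_recording(p)
        assert rec is None and qc.excluded


class TestResampleClip:
    def test_constant_signal_preserved(self):
        rec = RawRecording("s", "2024-01-01", 100.0,
                           np.full((1000, 3), 0.5))
        out = resample_clip(rec)
        assert out.sample_rate == 30.0
        # 10 s short of one sample: ~300 output samples on the anchored grid
        assert out.n_samples in (300, 301)
        assert np.allclose(out.samples, 0.5)

    def test_clipping_at_3g(self):
        samples = np.zeros((100, 3))
        samples[:, 0] = 5.0
        samples[:, 1] = -4.0
        rec = RawRecording("s", "2024-01-01", 30.0, samples)
        out = resample_clip(rec)
        assert (out.samples[:, 0] == 3.0).all()
        assert (out.samples[:, 1] == -3.0).all()

    def test_linear_ramp_interpolation_oracle(self):
        """Values on the 30 Hz grid equal the ramp evaluated at grid times."""
        t = np.arange(1000) / 100.0  # 10 s at 100 Hz
        samples = np.column_stack([t / 10.0, np.zeros_like(t), np.ones_like(t)])
        rec = RawRecording("s", "2024-01-01", 100.0, samples)
        out = resample_clip(rec)
        t_grid = np.arange(out.n_samples) / 30.0
        assert np.allclose(out.samples[:, 0], t_grid / 10.0, atol=1e-9)

    def test_idempotent_on_clean_recording(self):
        rng = np.random.default_rng(0)
        rec = RawRecording("s", "2024-01-01", 30.0,
                           np.clip(rng.normal(0, 0.5, (900, 3)), -3, 3))
        once = resample_clip(rec)
        twice = resample_clip(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-12)

    def test_too_short_rejected(self):
        rec = RawRecording("s", "2024-01-01", 100.0, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            resample_clip(rec)


def _with_constant_block(active_minutes, const_minutes, seed=0):
    """Noisy wear signal with an embedded exactly-constant block."""
    rng = np.random.default_rng(seed)
    spm = 30 * 60  # samples per minute

    def noisy(minutes):
        return 0.1 * rng.standard_normal((int(minutes * spm), 3)) + [0, 0, 1]

    parts = [noisy(active_minutes),
             np.tile([0.0, 0.0, 1.0], (int(const_minutes * spm), 1)),
             noisy(active_minutes)]
    return RawRecording("s", "2024-01-01", 30.0, np.vstack(parts)), active_minutes


class TestDetectNonwear:
    def test_61_min_constant_is_nonwear(self):
        rec, lead = _with_constant_block(10, 61)
        intervals = detect_nonwear(rec)
        assert len(intervals) == 1
        start, end = intervals[0]
        assert (end - start).total_seconds() == 61 * 60
        assert (start - rec.start_time).total_seconds() == lead * 60

    def test_59_min_constant_is_not_nonwear(self):
        rec, _ = _with_constant_block(10, 59)
        assert detect_nonwear(rec) == []

    def test_exactly_60_min_is_not_nonwear(self):
        """'Greater than 60 min' is strict: a 120-epoch run does not qualify."""
        rec, _ = _with_constant_block(10, 60)
        assert detect_nonwear(rec) == []

    def test_low_amplitude_motion_above_sd_threshold(self):
        rng = np.random.default_rng(1)
        samples = 0.020 * rng.standard_normal((61 * 1800, 3)) + [0, 0, 1]
        rec = RawRecording("s", "2024-01-01", 30.0, samples)
        assert detect_nonwear(rec) == []

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_bruteforce_epoch_scan(self, seed):
        """Agreement with a direct scan of per-epoch sds on random input."""
        rng = np.random.default_rng(seed)
        n_epochs = int(rng.integers(5, 40))
        quiet = rng.random(n_epochs) < 0.5
        sig = np.vstack([
            (np.tile([0, 0, 1.0], (900, 1)) if q
             else 0.05 * rng.standard_normal((900, 3)) + [0, 0, 1])
            for q in quiet
        ])
        cfg = PreprocessConfig(nonwear_min_minutes=1.5)  # 3 epochs at test scale
        rec = RawRecording("s", "2024-01-01", 30.0, sig)
        got = detect_nonwear(rec, cfg)
        # brute force: per-epoch sd, runs strictly longer than 3 epochs
        sds = sig.reshape(n_epochs, 900, 3).std(axis=1)
        is_quiet = (sds < 0.013).all(axis=1)
        expected = []
        i = 0
        while i < n_epochs:
            if is_quiet[i]:
                j = i
                while j < n_epochs and is_quiet[j]:
                    j += 1
                if (j - i) > 3:
                    expected.append((i, j))
                i = j
            else:
                i += 1
        got_epochs = [
            (int((s - rec.start_time).total_seconds() // 30),
             int((e - rec.start_time).total_seconds() // 30))
            for s, e in got
        ]
        assert got_epochs == expected


class TestQualityCheck:
    def test_pure_gravity_passes(self, gravity_recording):
        qc = quality_check(gravity_recording)
        assert not qc.excluded
        assert qc.calibration_error_mg == pytest.approx(0.0, abs=1e-9)

    def test_unrealistic_mean_excluded(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(0, 0.8, (30 * 60 * 5, 3)) + [0, 0, 1]
        rec = RawRecording("s", "2024-01-01", 30.0, samples)
        qc = quality_check(rec)
        assert qc.mean_acc_mg > 200
        assert qc.excluded and "unrealistic high values" in qc.reasons

    def test_calibration_error_of_inflated_sphere(self):
        """Stationary recording with all norms 1.05 g -> 50 mg error."""
        rec = constant_recording(value=(0.0, 0.0, 1.05), minutes=5)
        qc = quality_check(rec)
        assert qc.calibration_error_mg == pytest.approx(50.0, abs=1e-9)
        assert qc.excluded and "poorly calibrated" in qc.reasons

    def test_no_stationary_epochs_flagged_not_excluded(self):
        rng = np.random.default_rng(3)
        samples = 0.05 * rng.standard_normal((30 * 60 * 5, 3)) + [0, 0, 1]
        rec = RawRecording("s", "2024-01-01", 30.0, samples)
        qc = quality_check(rec)
        assert qc.calibration_error_mg is None
        assert not qc.excluded
        assert any("calibration undefined" in r for r in qc.reasons)


class TestEpochize:
    def test_five_minutes_gives_ten_epochs(self):
        tensor = epochize(constant_recording(minutes=5))
        assert tensor.epochs.shape == (10, 3, 900)

    def test_trailing_partial_window_dropped(self):
        tensor = epochize(constant_recording(minutes=5 + 10 / 60))
        assert tensor.epochs.shape == (10, 3, 900)

    def test_epoch_count_conservation(self):
        for minutes in (0.4, 1.0, 2.51, 7.49):
            rec = constant_recording(minutes=minutes)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tensor = epochize(rec)
            n = tensor.n_epochs
            assert n * 900 <= rec.n_samples < (n + 1) * 900

    def test_wear_mask_false_on_known_nonwear_block(self):
        rec, lead = _with_constant_block(10, 90)
        tensor = epochize(rec)
        n_lead = lead * 2
        expected = np.ones(tensor.n_epochs, dtype=bool)
        expected[n_lead : n_lead + 180] = False
        assert (tensor.wear_mask == expected).all()
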