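"""Cleaning, segmentation and QC: identities, filters, thresholds, recovery."""

import numpy as np
import pytest

from pupilsync import (
    ConfigurationError,
    SubjectParams,
    UnusableSignalError,
    clean_for_trials,
    condition_average,
    despike,
    detrend,
    generate_pupil_session,
    generate_stimulus_sequence,
    interpolate_gaps,
    listener_qc,
    segment_trials,
    session_qc,
)

from conftest import make_trace


class TestInterpolateGaps:
    def test_fully_valid_unchanged(self):
        ts = make_trace(np.sin(np.arange(100) / 10) + 5)
        out = interpolate_gaps(ts, "linear")
        assert np.array_equal(out.diameter, ts.diameter)
        assert out.interpolated_fraction == 0.0
        assert out.valid.all()

    def test_linear_gap_in_ramp_restored_exactly(self):
        values = np.linspace(3, 4, 50)
        valid = np.ones(50, bool)
        valid[20:23] = False
        corrupted = values.copy()
        corrupted[20:23] = np.nan
        ts = make_trace(corrupted, valid=valid)
        out = interpolate_gaps(ts, "linear")
        assert np.allclose(out.diameter, values)
        assert out.interpolated_fraction == pytest.approx(3 / 50)

    def test_cubic_beats_linear_on_sinusoid(self):
        rate = 30.0
        t = np.arange(0, 20, 1 / rate)
        truth = 5 + np.sin(2 * np.pi * 0.5 * t)
        valid = np.ones(len(t), bool)
        # 200 ms gaps sprinkled through the trace
        for start in range(60, len(t) - 60, 90):
            valid[start:start + 6] = False
        ts = make_trace(truth, rate_hz=rate, valid=valid)
        err_lin = np.abs(
            interpolate_gaps(ts, "linear").diameter - truth
        )[~valid].max()
        err_cub = np.abs(
            interpolate_gaps(ts, "cubic_spline").diameter - truth
        )[~valid].max()
        assert err_cub < err_lin

    def test_edge_gaps_take_nearest_valid(self):
        valid = np.ones(30, bool)
        valid[:4] = False
        valid[-3:] = False
        ts = make_trace(np.linspace(4, 5, 30), valid=valid)
        for method in ("linear", "cubic_spline"):
            out = interpolate_gaps(ts, method)
            assert np.allclose(out.diameter[:4], ts.diameter[4])
            assert np.allclose(out.diameter[-3:], ts.diameter[-4])

    def test_all_invalid_raises(self):
        ts = make_trace(np.full(20, np.nan), valid=np.zeros(20, bool))
        with pytest.raises(UnusableSignalError):
            interpolate_gaps(ts, "linear")


class TestDespike:
    def test_constant_unchanged(self):
        ts = make_trace(np.full(300, 5.0))
        out = despike(ts)
        assert np.allclose(out.diameter, 5.0, atol=1e-9)

    def test_single_spike_removed(self):
        values = np.full(300, 5.0)
        values[150] = 15.0
        out = despike(make_trace(values))
        assert np.allclose(out.diameter, 5.0, atol=0.01)

    def test_12hz_attenuated_below_10_percent(self):
        rate = 30.0
        t = np.arange(0, 30, 1 / rate)
        ts = make_trace(np.sin(2 * np.pi * 12 * t), rate_hz=rate)
        out = despike(ts, median_order=1)  # isolate the low-pass stage
        interior = slice(150, -150)
        assert out.diameter[interior].std() < 0.10 * ts.diameter[interior].std()

    def test_cutoff_above_nyquist_rejected(self):
        ts = make_trace(np.full(100, 5.0))
        with pytest.raises(ConfigurationError, match="Nyquist"):
            despike(ts, lowpass_hz=20.0)


class TestDetrend:
    def test_ramp_removed(self):
        ts = make_trace(np.linspace(2, 8, 200))
        out = detrend(ts)
        assert np.allclose(out.diameter, 0.0, atol=1e-9)

    def test_sinusoid_recovered_from_ramp(self):
        rate = 30.0
        t = np.arange(0, 300, 1 / rate)
        sine = np.sin(2 * np.pi * 0.5 * t)
        out = detrend(make_trace(5 + 0.05 * t + sine, rate_hz=rate))
        rms = np.sqrt(np.mean((out.diameter - (sine - sine.mean())) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(sine**2))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ts = make_trace(5 + rng.standard_normal(500).cumsum() / 50)
        once = detrend(ts)
        twice = detrend(once)
        assert np.allclose(once.diameter, twice.diameter, atol=1e-9)


@pytest.fixture(scope="module")
def mini_seq():
    return generate_stimulus_sequence(
        n_blocks=1, tones_per_block=40, seed=3,
        proportions={"standard": 0.65, "target": 0.20, "novel": 0.10,
                     "omission": 0.05},
    )


class TestSegmentTrials:
    def test_small_pupil_trial_dropped(self, mini_seq):
        rate = 30.0
        n = int((mini_seq.duration_ms / 1000 + 4) * rate)
        values = np.full(n, 5.0)
        onset = mini_seq.onsets_ms[5] / 1000
        values[int(onset * rate) + 10] = 1.9  # below the 2 mm floor
        trials = segment_trials(make_trace(values, rate), mini_seq)
        assert not trials.kept[5]
        assert trials.reasons[5] == "small_pupil"
        assert trials.kept[6]

    def test_constant_trace_gives_zero_epochs(self, mini_seq):
        rate = 30.0
        n = int((mini_seq.duration_ms / 1000 + 4) * rate)
        trials = segment_trials(make_trace(np.full(n, 5.0), rate), mini_seq)
        assert trials.n_kept > 0
        assert np.allclose(trials.epochs[trials.kept], 0.0, atol=1e-12)

    def test_baseline_mean_zero_after_correction(self, mini_seq):
        """Corrected pre-onset baseline means vanish to float tolerance."""
        rng = np.random.default_rng(1)
        rate = 30.0
        n = int((mini_seq.duration_ms / 1000 + 4) * rate)
        raw = 5 + 0.3 * rng.standard_normal(n)
        ts = make_trace(raw, rate)
        trials = segment_trials(ts, mini_seq)
        # recompute the z-trace independently and check the corrected baseline
        z = (raw - raw.mean()) / raw.std()
        n_base = 3
        for i in np.flatnonzero(trials.kept):
            start = int(round(mini_seq.onsets_ms[i] / 1000 * rate))
            corrected = z[start - n_base:start] - trials.baseline_means[i]
            assert abs(corrected.mean()) < 1e-9

    def test_window_beyond_trace_dropped_not_raised(self, mini_seq):
        rate = 30.0
        n = int(mini_seq.duration_ms / 1000 * rate) - 30  # cut the last second
        trials = segment_trials(make_trace(np.full(n, 5.0), rate), mini_seq)
        assert not trials.kept[-1]
        assert trials.reasons[-1] == "window_out_of_bounds"

    def test_evoked_amplitude_recovery(self):
        """Mean target epoch peak recovers the generative evoked amplitude."""
        seq = generate_stimulus_sequence(n_blocks=1, tones_per_block=80, seed=5)
        params = SubjectParams(
            gain_isi=0.0, gain_tsi=0.0,
            evoked_amp={"target": 0.3},
            noise_sd=0.05, drift_coef=0.0, blink_rate=0.0,
        )
        peaks = []
        for seed in range(20):
            ts = generate_pupil_session(seq, params, seed=seed)
            clean = clean_for_trials(ts)
            trials = segment_trials(clean, seq, zscore="none")
            curve = condition_average(trials, "target")
            peaks.append(curve.max())
        assert np.mean(peaks) == pytest.approx(0.3, abs=0.05)


class TestQC:
    def test_mostly_missing_session_unusable(self):
        valid = np.zeros(100, bool)
        valid[:5] = True
        ts = make_trace(np.full(100, 5.0), valid=valid)
        verdict = session_qc(ts)
        assert not verdict.usable
        assert "missing_fraction" in verdict.reason

    def test_boundary_missing_fraction_usable(self):
        valid = np.ones(100, bool)
        valid[:90] = False  # exactly 90%: strict inequality keeps it
        ts = make_trace(np.where(valid, 5.0, np.nan), valid=valid)
        assert session_qc(ts).usable

    def test_interpolation_thresholds(self):
        base = make_trace(np.full(100, 5.0))
        assert not listener_qc(base.copy_with(interpolated_fraction=0.30)).usable
        assert listener_qc(base.copy_with(interpolated_fraction=0.25)).usable

    def test_clean_trace_usable_no_reason(self):
        verdict = session_qc(make_trace(np.full(100, 5.0)))
        assert verdict.usable
        assert verdict.reason == ""
        assert verdict.missing_fraction == 0.0
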