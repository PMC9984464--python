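"""Generators: exact design counts, determinism, and ground-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilsync import (
    ConfigurationError,
    SubjectParams,
    band_z_power,
    block_periodogram,
    classify_presses,
    generate_behavior,
    generate_dyad,
    generate_pupil_session,
    generate_stimulus_sequence,
)
from pupilsync.entrain import ISI_BAND_HZ

from conftest import entrained_trace


class TestStimulusSequence:
    def test_default_design_counts(self, default_seq):
        """65/20/10/5% of 800 tones: 520 standard, 160 target, 80 novel, 40 omission."""
        counts = default_seq.condition_counts()
        assert default_seq.n_events == 800
        assert counts["standard"] == 520
        assert counts["target"] == 160
        assert counts["novel"] == 80
        assert counts["omission"] == 40
        per_block = default_seq.events.groupby("block")["condition"].value_counts()
        for b in range(1, 6):
            assert per_block[b]["standard"] == 104
            assert per_block[b]["target"] == 32
            assert per_block[b]["novel"] == 16
            assert per_block[b]["omission"] == 8

    def test_isochronous_spacing(self, default_seq):
        assert np.all(np.diff(default_seq.onsets_ms) == 1200)

    def test_fourth_beat_closure(self, default_seq):
        ev = default_seq.events
        on_fourth = ev["beat_position"] == 4
        assert set(ev.loc[on_fourth, "condition"]) == {"target", "omission"}
        assert not ev.loc[~on_fourth, "condition"].isin(["target", "omission"]).any()

    def test_minimal_sequence_onsets(self):
        seq = generate_stimulus_sequence(
            n_blocks=1,
            tones_per_block=4,
            proportions={"standard": 0.75, "target": 0.25},
            seed=0,
        )
        assert list(seq.onsets_ms) == [0, 1200, 2400, 3600]
        assert seq.events["condition"].iloc[3] == "target"

    def test_determinism(self):
        a = generate_stimulus_sequence(seed=7)
        b = generate_stimulus_sequence(seed=7)
        assert a.events.to_csv() == b.events.to_csv()

    def test_novel_tone_frequencies(self, default_seq):
        ev = default_seq.events
        novel_hz = ev.loc[ev["condition"] == "novel", "tone_hz"]
        assert ((novel_hz >= 1320.0) & (novel_hz <= 5280.0)).all()
        assert (ev.loc[ev["condition"].isin(["standard", "target"]), "tone_hz"] == 880.0).all()
        assert ev.loc[ev["condition"] == "omission", "tone_hz"].isna().all()

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(proportions={"standard": 0.7, "target": 0.2, "omission": 0.05}), "sum to 1"),
            (dict(tones_per_block=150), "multiple of 4"),
            (dict(proportions={"standard": 0.643, "target": 0.2, "novel": 0.107,
                               "omission": 0.05}), "integer"),
            (dict(proportions={"standard": 0.55, "target": 0.30, "novel": 0.10,
                               "omission": 0.05}), "fourth-beat"),
        ],
    )
    def test_invalid_designs_name_constraint(self, kwargs, match):
        with pytest.raises(ConfigurationError, match=match):
            generate_stimulus_sequence(**kwargs, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        quarters=st.integers(min_value=1, max_value=10),
        target_frac=st.integers(min_value=0, max_value=4),
        novel_quads=st.integers(min_value=0, max_value=2),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_count_conservation_property(self, quarters, target_frac, novel_quads, seed):
        """Any consistent design yields exact integer counts on the right beats."""
        tpb = 20 * quarters
        n_target = (tpb // 4) * target_frac // 4
        n_omission = tpb // 4 - n_target
        n_novel = novel_quads * quarters
        n_standard = tpb - n_target - n_omission - n_novel
        props = {
            "standard": n_standard / tpb,
            "target": n_target / tpb,
            "novel": n_novel / tpb,
            "omission": n_omission / tpb,
        }
        seq = generate_stimulus_sequence(2, tpb, 1200, props, seed=seed)
        counts = seq.condition_counts()
        assert counts.get("target", 0) == 2 * n_target
        assert counts.get("omission", 0) == 2 * n_omission
        assert counts.get("novel", 0) == 2 * n_novel
        assert counts.sum() == 2 * tpb
        ev = seq.events
        fourth = ev["beat_position"] == 4
        assert set(ev.loc[fourth, "condition"]) <= {"target", "omission"}
        assert not ev.loc[~fourth, "condition"].isin(["target", "omission"]).any()


class TestPupilSession:
    def test_zero_params_constant_baseline(self, short_seq):
        params = SubjectParams(
            gain_isi=0.0, gain_tsi=0.0, evoked_amp={}, noise_sd=0.0,
            drift_coef=0.0, blink_rate=0.0,
        )
        ts = generate_pupil_session(short_seq, params, seed=0)
        assert np.allclose(ts.diameter, params.baseline_mm)
        assert ts.valid.all()

    def test_rate_below_nyquist_rejected(self, short_seq):
        with pytest.raises(ConfigurationError, match="twice the highest"):
            generate_pupil_session(short_seq, SubjectParams(), rate_hz=1.0)

    def test_determinism(self, short_seq):
        params = SubjectParams()
        a = generate_pupil_session(short_seq, params, seed=3)
        b = generate_pupil_session(short_seq, params, seed=3)
        assert np.array_equal(a.diameter, b.diameter, equal_nan=True)
        assert np.array_equal(a.valid, b.valid)

    def test_noise_degrades_isi_band_power(self, short_seq):
        """Doubling the noise SD lowers the beat-band z-power on average."""
        def mean_z(noise_sd):
            zs = []
            for seed in range(20):
                ts = entrained_trace(0.3, 0.0, noise_sd, short_seq, seed, 300.0)
                zs.append(band_z_power(block_periodogram(ts), ISI_BAND_HZ))
            return np.mean(zs)

        assert mean_z(0.6) < mean_z(0.3)


class TestBehaviorGenerator:
    def test_chance_performance(self):
        """d'=0, c=0: hit and false-alarm rates both near 1/2."""
        seq = generate_stimulus_sequence(n_blocks=5, tones_per_block=200, seed=2)
        params = SubjectParams(dprime_true=0.0, criterion=0.0)
        log = generate_behavior(seq, params, seed=2)
        s = classify_presses(seq, log)
        assert s.hits / s.n_targets == pytest.approx(0.5, abs=0.07)
        assert s.false_alarms / s.n_distractors == pytest.approx(0.5, abs=0.05)

    def test_determinism(self, default_seq):
        params = SubjectParams()
        a = generate_behavior(default_seq, params, seed=11)
        b = generate_behavior(default_seq, params, seed=11)
        assert np.array_equal(a.press_times_ms, b.press_times_ms)

    def test_presses_within_one_second_of_tone(self, default_seq):
        log = generate_behavior(default_seq, SubjectParams(), seed=4)
        onsets = default_seq.onsets_ms
        for press in log.press_times_ms:
            idx = np.searchsorted(onsets, press, side="right") - 1
            assert 0 < press - onsets[idx] <= 1000


class TestDyadGenerator:
    def test_default_rates(self):
        speaker, listener = generate_dyad(10.0, coupling=0.5, seed=0)
        assert speaker.rate_hz == 120.0
        assert listener.rate_hz == 30.0

    def test_identity_limit(self):
        """Full coupling with zero noise and lag: traces are the same signal."""
        from pupilsync import resample_common

        speaker, listener = generate_dyad(60.0, coupling=1.0, seed=3, noise_sd=0.0)
        a, b = resample_common(speaker, listener)
        assert np.corrcoef(a.diameter, b.diameter)[0, 1] > 0.99

    def test_coupling_bounds(self):
        with pytest.raises(ConfigurationError):
            generate_dyad(10.0, coupling=1.5, seed=0)

    def test_determinism(self):
        a = generate_dyad(20.0, 0.5, seed=9)
        b = generate_dyad(20.0, 0.5, seed=9)
        assert np.array_equal(a[0].diameter, b[0].diameter)
        assert np.array_equal(a[1].diameter, b[1].diameter)
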