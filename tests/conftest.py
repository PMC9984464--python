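import numpy as np
import pytest

from pupilsync import (
    PupilTimeSeries,
    SubjectParams,
    generate_pupil_session,
    generate_stimulus_sequence,
)


@pytest.fixture(scope="session")
def default_seq():
    """One default oddball session: 5 blocks of 160 tones, 1200 ms ISI."""
    return generate_stimulus_sequence(seed=1)


@pytest.fixture(scope="session")
def short_seq():
    """A single 260-tone block (~312 s), handy for spectral checks."""
    return generate_stimulus_sequence(n_blocks=1, tones_per_block=260, seed=1)


def make_trace(values, rate_hz=30.0, valid=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return PupilTimeSeries(
        t=np.arange(n) / rate_hz,
        diameter=values,
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        rate_hz=rate_hz,
    )


def entrained_trace(gain_isi, gain_tsi, noise_sd, seq, seed, duration_s=None):
    """A pupil trace with only entrained oscillations plus Gaussian noise.

    ``osc_amp_mm=1`` makes the gains read directly as amplitudes in mm.
    """
    params = SubjectParams(
        gain_isi=gain_isi,
        gain_tsi=gain_tsi,
        osc_amp_mm=1.0,
        evoked_amp={},
        noise_sd=noise_sd,
        drift_coef=0.0,
        blink_rate=0.0,
    )
    ts = generate_pupil_session(seq, params, rate_hz=30.0, seed=seed)
    if duration_s is not None:
        ts = ts.slice_time(0.0, duration_s)
    return ts
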