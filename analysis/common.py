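"""Shared demo cohort for the numbered analysis scripts.

One latent "tendency to synchronize" per participant drives their
entrainment gains, their oddball sensitivity and their coupling to the
storyteller, so the downstream analyses have a known ground truth.  All
scripts regenerate the same cohort deterministically from SEED.
"""

from pathlib import Path

import numpy as np

import pupilsync as ps

SEED = 2026
N_PARTICIPANTS = 12
N_SESSIONS = 2
N_STORIES = 4
STORY_DURATION_S = 60.0
RATE_HZ = 30.0
BLOCK_S = 160 * 1.2

RESULTS = Path(__file__).resolve().parent.parent / "results"


def tendency(participant: int) -> float:
    rng = np.random.default_rng((SEED, 100 + participant))
    return float(rng.uniform(0.0, 1.0))


def subject_params(participant: int) -> ps.SubjectParams:
    rng = np.random.default_rng((SEED, 200 + participant))
    t = tendency(participant)
    return ps.SubjectParams(
        gain_isi=0.1 + 1.8 * t,
        gain_tsi=0.1 + 1.8 * t,
        blink_rate=rng.uniform(5.0, 20.0),
        dprime_true=0.5 + 2.0 * t + rng.normal(0.0, 0.25),
        criterion=rng.normal(0.0, 0.2),
    )


def coupling(participant: int) -> float:
    rng = np.random.default_rng((SEED, 300 + participant))
    return float(np.clip(0.15 + 0.7 * tendency(participant) + rng.normal(0, 0.05), 0, 1))


def session_seed(participant: int, session: int) -> int:
    return int(np.random.default_rng((SEED, participant, session)).integers(2**31))


def make_session(participant: int, session: int):
    """(sequence, pupil trace, press log) for one oddball session."""
    seq = ps.generate_stimulus_sequence(seed=session_seed(participant, session))
    params = subject_params(participant)
    s = session_seed(participant, session)
    ts = ps.generate_pupil_session(seq, params, RATE_HZ, seed=s + 1)
    log = ps.generate_behavior(seq, params, seed=s + 2)
    return seq, ts, log


def make_dyad(participant: int, story: int):
    s = int(np.random.default_rng((SEED, 400, participant, story)).integers(2**31))
    return ps.generate_dyad(
        STORY_DURATION_S, coupling(participant), seed=s
    )


def split_blocks(ts, n_blocks=5):
    return [ts.slice_time(b * BLOCK_S, (b + 1) * BLOCK_S) for b in range(n_blocks)]
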