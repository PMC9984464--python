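"""Synthetic oddball sessions, pupil traces, button presses, and coupled dyads.

Everything downstream (preprocessing, entrainment scoring, d' recovery,
dyadic synchrony) is validated against the ground-truth parameters used
here.  All generators are pure functions of their arguments and a seed.

The simulated task is an auditory oddball stream: tones every 1200 ms
(0.83 Hz), organised in four-beat groups of 4800 ms (0.21 Hz).  Every
fourth beat carries either a quiet target tone or a silent omission;
rare novel tones occur unpredictably on beats 1-3.  Default condition
proportions are 65% standard / 20% target / 10% novel / 5% omission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import norm

from .errors import ConfigurationError

__all__ = [
    "CONDITIONS",
    "DEFAULT_PROPORTIONS",
    "StimulusSequence",
    "SubjectParams",
    "PupilTimeSeries",
    "ResponseLog",
    "pupil_kernel",
    "generate_stimulus_sequence",
    "generate_pupil_session",
    "generate_behavior",
    "generate_dyad",
]

CONDITIONS = ("standard", "target", "novel", "omission")

#: Per-session design proportions of the four tone conditions.
DEFAULT_PROPORTIONS: Mapping[str, float] = {
    "standard": 0.65,
    "target": 0.20,
    "novel": 0.10,
    "omission": 0.05,
}

STANDARD_TONE_HZ = 880.0
#: Novel tones are drawn log-uniformly from this frequency band (Hz).
NOVEL_TONE_BAND_HZ = (1320.0, 5280.0)

EVENT_COLUMNS = ["onset_ms", "condition", "tone_hz", "block", "beat_position"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StimulusSequence:
    """Ordered tone events of one oddball session.

    ``events`` holds one row per tone slot with columns ``onset_ms``
    (integer), ``condition``, ``tone_hz`` (NaN for omissions), ``block``
    (1-based) and ``beat_position`` (1..4).
    """

    events: pd.DataFrame
    isi_ms: int = 1200

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table lacks columns {missing}")
        if self.isi_ms <= 0:
            raise ConfigurationError("isi_ms must be positive")
        self.events = self.events.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets_ms(self) -> np.ndarray:
        return self.events["onset_ms"].to_numpy()

    @property
    def duration_ms(self) -> int:
        return int(self.events["onset_ms"].iloc[-1]) + self.isi_ms

    @property
    def f_isi(self) -> float:
        """Beat frequency of the tone train (1/ISI), Hz."""
        return 1000.0 / self.isi_ms

    @property
    def f_tsi(self) -> float:
        """Frequency of the fourth-beat (target) slot, Hz."""
        return self.f_isi / 4.0

    def condition_counts(self) -> pd.Series:
        return self.events["condition"].value_counts()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path, isi_ms: int | None = None) -> "StimulusSequence":
        events = pd.read_csv(path, sep="\t", comment="#")
        if isi_ms is None:
            onsets = events["onset_ms"].to_numpy()
            isi_ms = int(np.min(np.diff(onsets))) if len(onsets) > 1 else 1200
        return cls(events=events, isi_ms=isi_ms)


@dataclass
class SubjectParams:
    """Ground-truth generative parameters of one simulated subject.

    ``gain_isi`` / ``gain_tsi`` are dimensionless multipliers of the base
    entrained-oscillation amplitude ``osc_amp_mm`` (0.15 mm by default, the
    order of magnitude of beat-locked pupil oscillations) at the beat and
    fourth-beat frequencies.  ``evoked_amp`` holds the peak event-evoked
    dilation per condition in millimetres; ``drift_coef`` scales a 1/f slow
    wander (mm SD); ``dprime_true`` and ``criterion`` parameterise the
    equal-variance signal-detection observer.
    """

    baseline_mm: float = 5.0
    gain_isi: float = 1.0
    gain_tsi: float = 1.0
    osc_amp_mm: float = 0.15  # entrained oscillation amplitude per unit gain
    evoked_amp: Mapping[str, float] = field(
        default_factory=lambda: {
            "standard": 0.05,
            "target": 0.25,
            "novel": 0.30,
            "omission": 0.20,
        }
    )
    noise_sd: float = 0.15
    drift_coef: float = 0.30
    blink_rate: float = 15.0  # blinks per minute
    dprime_true: float = 2.0
    criterion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gain_isi", "gain_tsi", "noise_sd", "blink_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for cond, amp in self.evoked_amp.items():
            if amp < 0:
                raise ConfigurationError(f"evoked_amp[{cond!r}] must be non-negative")


@dataclass
class PupilTimeSeries:
    """A single eye's diameter trace on a uniform time grid.

    ``valid`` is False during blinks/dropout.  ``interpolated_fraction``
    tracks the proportion of samples that were reconstructed by gap
    interpolation (0 for a raw trace).
    """

    t: np.ndarray
    diameter: np.ndarray
    valid: np.ndarray
    rate_hz: float
    interpolated_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.diameter) == len(self.valid)):
            raise ValueError("t, diameter and valid must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not 0.0 <= self.interpolated_fraction <= 1.0:
            raise ValueError("interpolated_fraction must lie in [0, 1]")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(steps, 1.0 / self.rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly sampled at rate_hz")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.rate_hz

    def copy_with(self, **changes) -> "PupilTimeSeries":
        base = dict(
            t=self.t.copy(),
            diameter=self.diameter.copy(),
            valid=self.valid.copy(),
            rate_hz=self.rate_hz,
            interpolated_fraction=self.interpolated_fraction,
        )
        base.update(changes)
        return PupilTimeSeries(**base)

    def slice_time(self, start_s: float, stop_s: float) -> "PupilTimeSeries":
        i0 = int(np.searchsorted(self.t, start_s - 1e-9))
        i1 = int(np.searchsorted(self.t, stop_s - 1e-9))
        return PupilTimeSeries(
            t=self.t[i0:i1] - self.t[i0] if i0 else self.t[i0:i1],
            diameter=self.diameter[i0:i1],
            valid=self.valid[i0:i1],
            rate_hz=self.rate_hz,
            interpolated_fraction=self.interpolated_fraction,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "diameter_mm": self.diameter,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class ResponseLog:
    """Button-press timestamps (ms from session start), strictly increasing."""

    press_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.press_times_ms = np.asarray(self.press_times_ms, dtype=np.int64)
        if len(self.press_times_ms) > 1 and np.any(np.diff(self.press_times_ms) <= 0):
            raise ValueError("press times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.press_times_ms)


# ---------------------------------------------------------------------------
# stimulus sequence
# ---------------------------------------------------------------------------


def _validate_design(
    tones_per_block: int, proportions: Mapping[str, float]
) -> dict[str, int]:
    """Check the condition proportions against the four-beat design.

    Returns exact per-block condition counts or raises ConfigurationError
    naming the violated constraint.
    """
    if tones_per_block <= 0 or tones_per_block % 4 != 0:
        raise ConfigurationError(
            f"tones_per_block must be a positive multiple of 4, got {tones_per_block}"
        )
    unknown = set(proportions) - set(CONDITIONS)
    if unknown:
        raise ConfigurationError(f"unknown conditions in proportions: {sorted(unknown)}")
    props = {c: float(proportions.get(c, 0.0)) for c in CONDITIONS}
    if any(p < 0 for p in props.values()):
        raise ConfigurationError("proportions must be non-negative")
    total = sum(props.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ConfigurationError(f"proportions must sum to 1, got {total}")
    counts = {}
    for cond, p in props.items():
        c = p * tones_per_block
        if not math.isclose(c, round(c), abs_tol=1e-6):
            raise ConfigurationError(
                f"proportion {p} of condition {cond!r} does not yield an integer "
                f"count for {tones_per_block} tones per block"
            )
        counts[cond] = int(round(c))
    fourth = counts["target"] + counts["omission"]
    if fourth != tones_per_block // 4:
        raise ConfigurationError(
            "target + omission proportions must fill the fourth-beat slots "
            f"exactly (need {tones_per_block // 4} per block, got {fourth})"
        )
    if counts["novel"] > 3 * tones_per_block // 4:
        raise ConfigurationError("too many novel tones for beats 1-3")
    return counts


def generate_stimulus_sequence(
    n_blocks: int = 5,
    tones_per_block: int = 160,
    isi_ms: int = 1200,
    proportions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> StimulusSequence:
    """Generate the oddball tone schedule.

    Tones are spaced ``isi_ms`` apart on a single continuous grid.  Within
    each block, targets and omissions are randomly distributed over the
    fourth-beat slots and novel tones over beats 1-3; condition counts per
    block are exact.  Deterministic for a fixed seed.
    """
    if n_blocks <= 0:
        raise ConfigurationError("n_blocks must be positive")
    proportions = dict(proportions) if proportions is not None else dict(DEFAULT_PROPORTIONS)
    counts = _validate_design(tones_per_block, proportions)
    rng = np.random.default_rng(seed)

    rows = []
    for block in range(1, n_blocks + 1):
        conds = np.empty(tones_per_block, dtype=object)
        idx = np.arange(tones_per_block)
        beat = idx % 4 + 1
        fourth_slots = idx[beat == 4]
        other_slots = idx[beat != 4]

        fourth_perm = rng.permutation(fourth_slots)
        conds[fourth_perm[: counts["target"]]] = "target"
        conds[fourth_perm[counts["target"]:]] = "omission"

        novel_slots = rng.permutation(other_slots)[: counts["novel"]]
        conds[novel_slots] = "novel"
        conds[[i for i in other_slots if conds[i] is None]] = "standard"

        tone_hz = np.full(tones_per_block, STANDARD_TONE_HZ)
        lo, hi = NOVEL_TONE_BAND_HZ
        n_novel = counts["novel"]
        tone_hz[conds == "novel"] = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=n_novel)
        )
        tone_hz[conds == "omission"] = np.nan

        offset = (block - 1) * tones_per_block
        for i in range(tones_per_block):
            rows.append(
                (
                    (offset + i) * isi_ms,
                    conds[i],
                    tone_hz[i],
                    block,
                    int(beat[i]),
                )
            )

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["onset_ms"] = events["onset_ms"].astype(np.int64)
    return StimulusSequence(events=events, isi_ms=isi_ms)


# ---------------------------------------------------------------------------
# pupil sessions
# ---------------------------------------------------------------------------


def pupil_kernel(
    rate_hz: float,
    n: float = 10.1,
    t_max_s: float = 0.93,
    duration_s: float = 4.0,
) -> np.ndarray:
    """Event-related pupil response kernel, peak-normalised to 1.

    Erlang/gamma-family impulse response
    ``h(t) = (t/t_max)^n * exp(n * (1 - t/t_max))``
    with shape ``n`` and peak latency ``t_max`` — the standard unimodal,
    ~1 s-lagged pupillary response shape.
    """
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (t / t_max_s) ** n * np.exp(n * (1.0 - t / t_max_s))
    h[0] = 0.0
    return h


def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f ("pink") noise via FFT amplitude shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate_pupil_session(
    seq: StimulusSequence,
    params: SubjectParams,
    rate_hz: float = 30.0,
    seed: int = 0,
    pad_s: float = 4.0,
    kernel_n: float = 10.1,
    kernel_t_max_s: float = 0.93,
) -> PupilTimeSeries:
    """Simulate one continuous pupil-diameter trace for an oddball session.

    diameter = baseline
             + osc_amp_mm * (gain_isi * sin(2*pi*f_isi*t)
                             + gain_tsi * sin(2*pi*f_tsi*t))
             + sum over events of evoked_amp[condition] * K(t - onset)
             + drift_coef * pink drift + Gaussian noise,

    with blink dropouts (valid=False, diameter NaN) inserted as bursts of
    100-400 ms at ``params.blink_rate`` per minute.
    """
    f_max = max(seq.f_isi, seq.f_tsi)
    if rate_hz < 2.0 * f_max:
        raise ConfigurationError(
            f"rate_hz must be at least twice the highest modeled frequency "
            f"({f_max:.3g} Hz), got {rate_hz}"
        )
    rng = np.random.default_rng(seed)
    n = int(round((seq.duration_ms / 1000.0 + pad_s) * rate_hz))
    t = np.arange(n) / rate_hz

    diameter = np.full(n, params.baseline_mm, dtype=float)
    amp = params.osc_amp_mm
    # entrainment phase varies from session to session
    phi_isi, phi_tsi = rng.uniform(0.0, 2 * np.pi, size=2)
    diameter += params.gain_isi * amp * np.sin(2 * np.pi * seq.f_isi * t + phi_isi)
    diameter += params.gain_tsi * amp * np.sin(2 * np.pi * seq.f_tsi * t + phi_tsi)

    impulses = np.zeros(n)
    for onset_ms, cond in zip(seq.events["onset_ms"], seq.events["condition"]):
        amp = params.evoked_amp.get(cond, 0.0)
        if amp == 0.0:
            continue
        i = int(round(onset_ms / 1000.0 * rate_hz))
        if 0 <= i < n:
            impulses[i] += amp
    if np.any(impulses):
        kernel = pupil_kernel(rate_hz, n=kernel_n, t_max_s=kernel_t_max_s)
        diameter += np.convolve(impulses, kernel)[:n]

    if params.drift_coef > 0:
        diameter += params.drift_coef * _one_over_f_noise(n, rng)
    if params.noise_sd > 0:
        diameter += rng.normal(0.0, params.noise_sd, n)

    valid = np.ones(n, dtype=bool)
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * (n / rate_hz) / 60.0)
        starts = rng.uniform(0.0, n / rate_hz, size=n_blinks)
        durations = rng.uniform(0.1, 0.4, size=n_blinks)
        for s, d in zip(starts, durations):
            i0 = int(s * rate_hz)
            i1 = min(n, int((s + d) * rate_hz) + 1)
            valid[i0:i1] = False
        diameter[~valid] = np.nan

    return PupilTimeSeries(t=t, diameter=diameter, valid=valid, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------


def generate_behavior(
    seq: StimulusSequence,
    params: SubjectParams,
    seed: int = 0,
    lag_range_ms: tuple[int, int] = (200, 1000),
) -> ResponseLog:
    """Simulate spacebar presses of an equal-variance Gaussian observer.

    Each target tone elicits a press with probability Phi(d'/2 - c), each
    non-target *tone* (standards and novels) with probability
    Phi(-d'/2 - c).  Presses land within 1000 ms of the eliciting tone.
    Omission slots are silent and draw no press.
    """
    if not np.isfinite(params.dprime_true):
        raise ConfigurationError("dprime_true must be finite")
    lo, hi = lag_range_ms
    if not (0 <= lo < hi <= 1000):
        raise ConfigurationError("lag_range_ms must lie within (0, 1000]")
    rng = np.random.default_rng(seed)
    p_hit = norm.cdf(params.dprime_true / 2.0 - params.criterion)
    p_fa = norm.cdf(-params.dprime_true / 2.0 - params.criterion)

    presses = []
    for onset_ms, cond in zip(seq.events["onset_ms"], seq.events["condition"]):
        if cond == "omission":
            continue
        p = p_hit if cond == "target" else p_fa
        if rng.random() < p:
            presses.append(int(onset_ms) + int(rng.integers(lo, hi)))
    return ResponseLog(press_times_ms=np.asarray(presses, dtype=np.int64))


# ---------------------------------------------------------------------------
# dyads
# ---------------------------------------------------------------------------


def _latent_ar1(
    t_grid: np.ndarray, rng: np.random.Generator, ar_coef: float
) -> CubicSpline:
    """Smooth unit-variance latent attention process on a 1 s grid."""
    m = len(t_grid)
    x = np.empty(m)
    x[0] = rng.standard_normal()
    innov_sd = math.sqrt(max(1.0 - ar_coef**2, 1e-12))
    eps = rng.standard_normal(m - 1) * innov_sd
    for k in range(1, m):
        x[k] = ar_coef * x[k - 1] + eps[k - 1]
    return CubicSpline(t_grid, x)


def generate_dyad(
    duration_s: float,
    coupling: float,
    speaker_rate_hz: float = 120.0,
    listener_rate_hz: float = 30.0,
    seed: int = 0,
    lag_s: float = 0.0,
    noise_sd: float = 0.05,
    latent_sd_mm: float = 0.5,
    ar_coef: float = 0.9,
    baseline_mm: float = 5.0,
) -> tuple[PupilTimeSeries, PupilTimeSeries]:
    """Simulate a speaker-listener pupil pair coupled through shared attention.

    A smooth latent attention process A(t) (AR(1) on a 1 s grid, spline
    upsampled) drives the speaker; the listener mixes the (optionally
    lagged) same process with an independent process B(t):

        speaker  = A(t) + noise                       at ``speaker_rate_hz``
        listener = coupling*A(t-lag) + (1-coupling)*B(t) + noise
                                                      at ``listener_rate_hz``

    ``coupling`` in [0, 1] is the ground-truth shared-attention strength.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ConfigurationError("coupling must lie in [0, 1]")
    if duration_s <= 2.0:
        raise ConfigurationError("duration_s must exceed 2 s")
    rng = np.random.default_rng(seed)
    grid = np.arange(-math.ceil(abs(lag_s)) - 2.0, duration_s + 3.0, 1.0)
    A = _latent_ar1(grid, rng, ar_coef)
    B = _latent_ar1(grid, rng, ar_coef)

    def trace(rate_hz: float, latent_vals: np.ndarray) -> PupilTimeSeries:
        n = int(round(duration_s * rate_hz))
        t = np.arange(n) / rate_hz
        d = baseline_mm + latent_sd_mm * latent_vals
        if noise_sd > 0:
            d = d + rng.normal(0.0, noise_sd, n)
        return PupilTimeSeries(
            t=t, diameter=d, valid=np.ones(n, dtype=bool), rate_hz=rate_hz
        )

    t_sp = np.arange(int(round(duration_s * speaker_rate_hz))) / speaker_rate_hz
    t_li = np.arange(int(round(duration_s * listener_rate_hz))) / listener_rate_hz
    speaker = trace(speaker_rate_hz, A(t_sp))
    listener_latent = coupling * A(t_li - lag_s) + (1.0 - coupling) * B(t_li)
    listener = trace(listener_rate_hz, listener_latent)
    return speaker, listener
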