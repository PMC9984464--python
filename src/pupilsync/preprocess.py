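"""Pupil-trace cleaning, trial segmentation and quality control.

Two preprocessing paths share the same front end:

* trial path:      interpolate (linear) -> despike -> segment into 3 s epochs
* continuous path: interpolate (cubic spline) -> despike -> detrend

Epochs are z-scored against the whole cleaned session and baseline-corrected
by *subtracting* the mean of the 100 ms before tone onset.  Trials with any
raw diameter below 2 mm are dropped.  Sessions missing more than 90% of
samples, and listening traces needing more than 25% interpolation, are
rejected; both thresholds are strict inequalities, so boundary values stay
usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, UnusableSignalError
from .synth import PupilTimeSeries, StimulusSequence

__all__ = [
    "TrialMatrix",
    "QCVerdict",
    "interpolate_gaps",
    "despike",
    "detrend",
    "segment_trials",
    "session_qc",
    "listener_qc",
    "clean_continuous",
    "clean_for_trials",
]


@dataclass
class TrialMatrix:
    """Baseline-corrected 3 s epochs, one row per tone event.

    Dropped rows are NaN; ``kept`` and ``reasons`` record why.  Epoch values
    are in z-units when ``zscore="session"`` (the default) or raw millimetres
    when segmentation was run with ``zscore="none"``.
    """

    epochs: np.ndarray
    condition: np.ndarray
    kept: np.ndarray
    reasons: list[str]
    window_s: float
    baseline_ms: float
    rate_hz: float
    baseline_means: np.ndarray = field(default=None)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def times(self) -> np.ndarray:
        """Time axis of one epoch, seconds from tone onset."""
        return np.arange(self.epochs.shape[1]) / self.rate_hz


@dataclass
class QCVerdict:
    usable: bool
    missing_fraction: float
    interpolated_fraction: float
    reason: str = ""


def _invalid_mask(ts: PupilTimeSeries) -> np.ndarray:
    return ~ts.valid | ~np.isfinite(ts.diameter)


def interpolate_gaps(
    ts: PupilTimeSeries, method: str = "linear"
) -> PupilTimeSeries:
    """Reconstruct blink/dropout gaps; returns a fully valid trace.

    ``method`` is ``"linear"`` or ``"cubic_spline"``.  Leading/trailing gaps
    are filled with the nearest valid value.  ``interpolated_fraction`` is
    incremented by the fraction of reconstructed samples.
    """
    if method not in ("linear", "cubic_spline"):
        raise ConfigurationError(f"unknown interpolation method {method!r}")
    bad = _invalid_mask(ts)
    if not bad.any():
        return ts.copy_with(valid=np.ones(len(ts), dtype=bool))
    good = ~bad
    if good.sum() < 2:
        raise UnusableSignalError(
            "fewer than two valid samples; trace cannot be interpolated"
        )
    t, d = ts.t, ts.diameter
    out = d.copy()
    if method == "linear":
        out[bad] = np.interp(t[bad], t[good], d[good])
    else:
        cs = CubicSpline(t[good], d[good])
        out[bad] = cs(t[bad])
        # clamp extrapolated edges to the nearest valid value
        first, last = t[good][0], t[good][-1]
        out[bad & (t < first)] = d[good][0]
        out[bad & (t > last)] = d[good][-1]
    frac = min(1.0, ts.interpolated_fraction + bad.mean())
    return ts.copy_with(
        diameter=out, valid=np.ones(len(ts), dtype=bool), interpolated_fraction=frac
    )


def despike(
    ts: PupilTimeSeries, median_order: int = 5, lowpass_hz: float = 10.0,
    butter_order: int = 3,
) -> PupilTimeSeries:
    """Median filter (kernel ``median_order`` samples) then zero-phase
    Butterworth low-pass at ``lowpass_hz``."""
    if lowpass_hz >= ts.rate_hz / 2.0:
        raise ConfigurationError(
            f"lowpass_hz={lowpass_hz} must be below the Nyquist frequency "
            f"{ts.rate_hz / 2.0:g} Hz for rate_hz={ts.rate_hz:g}"
        )
    if median_order % 2 == 0 or median_order < 1:
        raise ConfigurationError("median_order must be a positive odd integer")
    if _invalid_mask(ts).any():
        raise UnusableSignalError("despike requires an interpolated (gap-free) trace")
    d = signal.medfilt(ts.diameter, kernel_size=median_order)
    b, a = signal.butter(butter_order, lowpass_hz / (ts.rate_hz / 2.0))
    d = signal.filtfilt(b, a, d)
    return ts.copy_with(diameter=d)


def detrend(ts: PupilTimeSeries) -> PupilTimeSeries:
    """Remove the least-squares linear trend (output has zero mean)."""
    if _invalid_mask(ts).any():
        raise UnusableSignalError("detrend requires an interpolated (gap-free) trace")
    return ts.copy_with(diameter=signal.detrend(ts.diameter, type="linear"))


def segment_trials(
    ts: PupilTimeSeries,
    seq: StimulusSequence,
    window_s: float = 3.0,
    baseline_ms: float = 100.0,
    min_mm: float = 2.0,
    zscore: str = "session",
) -> TrialMatrix:
    """Cut the cleaned trace into per-tone epochs.

    Per trial: drop if any raw sample in the epoch falls below ``min_mm``;
    z-score against the whole-session mean/SD (``zscore="session"``) or keep
    raw units (``zscore="none"``); subtract the mean of the ``baseline_ms``
    window before onset.  Out-of-bounds windows are dropped with a reason,
    never raised.
    """
    if zscore not in ("session", "none"):
        raise ConfigurationError(f"unknown zscore mode {zscore!r}")
    rate = ts.rate_hz
    n = len(ts)
    n_win = int(round(window_s * rate))
    n_base = max(1, int(round(baseline_ms / 1000.0 * rate)))
    raw = ts.diameter
    if zscore == "session":
        mu = np.nanmean(raw)
        sd = np.nanstd(raw)
        z = (raw - mu) / sd if sd > 0 else np.zeros_like(raw)
    else:
        z = raw

    n_trials = seq.n_events
    epochs = np.full((n_trials, n_win), np.nan)
    kept = np.zeros(n_trials, dtype=bool)
    reasons = [""] * n_trials
    baseline_means = np.full(n_trials, np.nan)
    conditions = seq.events["condition"].to_numpy()

    for i, onset_ms in enumerate(seq.events["onset_ms"]):
        start = int(round(onset_ms / 1000.0 * rate))
        if start < 0 or start + n_win > n:
            reasons[i] = "window_out_of_bounds"
            continue
        if start - n_base < 0:
            reasons[i] = "insufficient_baseline"
            continue
        window = raw[start:start + n_win]
        if not np.all(np.isfinite(window)):
            reasons[i] = "missing_samples"
            continue
        if np.any(window < min_mm):
            reasons[i] = "small_pupil"
            continue
        base = float(np.mean(z[start - n_base:start]))
        epochs[i] = z[start:start + n_win] - base
        baseline_means[i] = base
        kept[i] = True

    return TrialMatrix(
        epochs=epochs,
        condition=conditions,
        kept=kept,
        reasons=reasons,
        window_s=window_s,
        baseline_ms=baseline_ms,
        rate_hz=rate,
        baseline_means=baseline_means,
    )


def session_qc(ts: PupilTimeSeries, max_missing: float = 0.90) -> QCVerdict:
    """Reject a session recorded for too small a portion of the experiment.

    Unusable iff the missing fraction *strictly* exceeds ``max_missing``.
    """
    missing = float(_invalid_mask(ts).mean())
    usable = not (missing > max_missing)
    reason = "" if usable else (
        f"missing_fraction {missing:.3f} > {max_missing:g}"
    )
    return QCVerdict(
        usable=usable,
        missing_fraction=missing,
        interpolated_fraction=ts.interpolated_fraction,
        reason=reason,
    )


def listener_qc(ts: PupilTimeSeries, max_interp: float = 0.25) -> QCVerdict:
    """Reject a listening trace needing too much interpolation.

    Unusable iff ``interpolated_fraction`` *strictly* exceeds ``max_interp``.
    """
    interp = float(ts.interpolated_fraction)
    usable = not (interp > max_interp)
    reason = "" if usable else (
        f"interpolated_fraction {interp:.3f} > {max_interp:g}"
    )
    return QCVerdict(
        usable=usable,
        missing_fraction=float(_invalid_mask(ts).mean()),
        interpolated_fraction=interp,
        reason=reason,
    )


def clean_for_trials(
    ts: PupilTimeSeries, median_order: int = 5, lowpass_hz: float = 10.0
) -> PupilTimeSeries:
    """Trial-path front end: linear gap interpolation, then despike."""
    return despike(interpolate_gaps(ts, "linear"), median_order, lowpass_hz)


def clean_continuous(
    ts: PupilTimeSeries,
    median_order: int = 5,
    lowpass_hz: float = 10.0,
    do_detrend: bool = True,
) -> PupilTimeSeries:
    """Continuous-path front end: cubic-spline interpolation, despike,
    optional linear detrend (used for the listening traces)."""
    out = despike(interpolate_gaps(ts, "cubic_spline"), median_order, lowpass_hz)
    if do_detrend:
        out = detrend(out)
    return out
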