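"""Entrainment-synchrony scoring from continuous per-block pupil signals.

Each task block is demeaned, Hamming-windowed and turned into a
single-segment periodogram.  Power is z-scored across frequency bins
(DC excluded) and averaged inside the beat band (0.8-0.9 Hz, the 1200 ms
inter-stimulus interval) and the fourth-beat band (0.2-0.3 Hz, the
4800 ms target-stimulus interval).  The per-block band z-scores are
summed and aggregated across blocks into one session score: the
entrainment-synchrony score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, ResolutionError, UnusableSignalError
from .synth import PupilTimeSeries

__all__ = [
    "ISI_BAND_HZ",
    "TSI_BAND_HZ",
    "Spectrum",
    "EntrainmentScore",
    "block_periodogram",
    "band_z_power",
    "entrainment_score",
]

#: Band around the tone-train beat frequency (1/1200 ms = 0.83 Hz).
ISI_BAND_HZ = (0.8, 0.9)
#: Band around the fourth-beat frequency (1/4800 ms = 0.21 Hz).
TSI_BAND_HZ = (0.2, 0.3)


@dataclass
class Spectrum:
    """One-sided periodogram: frequencies (Hz) and squared-amplitude power."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be monotone increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    @property
    def argmax_freq(self) -> float:
        """Frequency of the maximum-power non-DC bin."""
        nz = self.freqs > 0
        return float(self.freqs[nz][np.argmax(self.power[nz])])


@dataclass
class EntrainmentScore:
    """Per-block band z-powers and the aggregated session score."""

    per_block: list[tuple[float, float]]  # (z_isi, z_tsi) per block
    score: float
    bands: tuple[tuple[float, float], tuple[float, float]] = (ISI_BAND_HZ, TSI_BAND_HZ)
    aggregate: str = "mean"


def block_periodogram(
    ts: PupilTimeSeries, min_duration_s: float = 60.0
) -> Spectrum:
    """Hamming-windowed single-segment periodogram of one task block.

    The block must be gap-free (interpolate first) and at least
    ``min_duration_s`` long; bin spacing is ``rate_hz / len``.
    """
    if (~ts.valid).any() or not np.all(np.isfinite(ts.diameter)):
        raise UnusableSignalError(
            "periodogram requires an interpolated (gap-free) block"
        )
    if ts.duration_s < min_duration_s:
        raise InsufficientDataError(
            f"block of {ts.duration_s:.1f} s is shorter than the minimum "
            f"{min_duration_s:g} s"
        )
    x = ts.diameter - ts.diameter.mean()
    freqs, power = signal.periodogram(
        x, fs=ts.rate_hz, window="hamming", detrend=False, scaling="spectrum"
    )
    return Spectrum(freqs=freqs, power=power)


def band_z_power(spec: Spectrum, band: tuple[float, float]) -> float:
    """Mean z-scored power of the bins inside ``band``.

    Every bin's power is z-scored against the mean/SD of all non-DC bins;
    the returned value is the mean z of the bins with lo <= f <= hi.  A
    zero-variance (e.g. flat or all-zero) spectrum returns 0.
    """
    lo, hi = band
    nyquist = spec.freqs[-1]
    if not (0.0 < lo < hi) or lo >= nyquist:
        raise ResolutionError(f"band {band} must lie within (0, {nyquist:g}) Hz")
    ref = spec.freqs > 0
    in_band = ref & (spec.freqs >= lo) & (spec.freqs <= hi)
    if not in_band.any():
        raise ResolutionError(
            f"no spectral bins inside {band} Hz at resolution "
            f"{spec.freqs[1] - spec.freqs[0]:.4g} Hz"
        )
    mu = spec.power[ref].mean()
    sd = spec.power[ref].std()
    if sd == 0.0:
        return 0.0
    return float(((spec.power[in_band] - mu) / sd).mean())


def entrainment_score(
    blocks: Sequence[PupilTimeSeries],
    bands: tuple[tuple[float, float], tuple[float, float]] = (ISI_BAND_HZ, TSI_BAND_HZ),
    aggregate: str = "mean",
    min_duration_s: float = 60.0,
) -> EntrainmentScore:
    """Entrainment-synchrony score of a session from its usable blocks.

    Per block the beat-band and fourth-beat-band z-powers are summed;
    blocks are aggregated by ``aggregate`` ("mean", robust to a dropped
    block, or "sum").
    """
    if len(blocks) == 0:
        raise InsufficientDataError("need at least one usable block")
    if aggregate not in ("mean", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    per_block = []
    for block in blocks:
        spec = block_periodogram(block, min_duration_s=min_duration_s)
        per_block.append((band_z_power(spec, bands[0]), band_z_power(spec, bands[1])))
    block_sums = np.array([z_isi + z_tsi for z_isi, z_tsi in per_block])
    score = float(block_sums.mean() if aggregate == "mean" else block_sums.sum())
    return EntrainmentScore(
        per_block=per_block, score=score, bands=bands, aggregate=aggregate
    )
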