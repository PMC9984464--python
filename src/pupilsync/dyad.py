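"""Speaker-listener pupillary synchrony via segment-wise warping cost.

The two traces are brought to a common rate (anti-alias resampling of the
faster speaker trace to the listener's 30 Hz), trimmed to shared support
and z-scored per story.  Sliding 3 s windows with 1.5 s hop are compared
with a segment-level dynamic-time-warping cost: each window is split into
``n_segments`` equal segments, adjacent segments may be paired one step
ahead on either signal, and the minimal accumulated cosine distance along
an admissible alignment path is the window's cost (0 for identical
windows; higher = more dissimilar).  Window costs are averaged into
non-overlapping 6 s bins and log-transformed; a story's synchrony value is
the negated mean log cost, so larger values mean more synchronous pupils.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import ConfigurationError, InsufficientDataError, UnusableSignalError
from .preprocess import QCVerdict
from .synth import PupilTimeSeries

__all__ = [
    "SynchronyTrace",
    "resample_common",
    "dtw_cost",
    "windowed_synchrony",
    "story_table",
]

logger = logging.getLogger(__name__)

LOG_EPS = 1e-6


@dataclass
class SynchronyTrace:
    """Windowed warping costs for one dyad-story and the story-level value."""

    window_starts: np.ndarray  # seconds
    costs: np.ndarray  # cost per sliding window, >= 0
    bin_starts: np.ndarray  # seconds, one per 6 s bin
    six_s_costs: np.ndarray  # mean cost per non-overlapping 6 s bin
    story_value: float  # -mean(log(six_s_costs + eps)); larger = more synchronous
    n_segments: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def resample_common(
    speaker: PupilTimeSeries, listener: PupilTimeSeries
) -> tuple[PupilTimeSeries, PupilTimeSeries]:
    """Align a dyad at the listener's rate, trimmed and z-scored per story.

    The speaker trace (120 Hz by default) is anti-alias filtered and
    decimated to the listener rate with polyphase resampling; both traces
    are trimmed to overlapping support and z-scored over the whole story.
    """
    for ts in (speaker, listener):
        if (~ts.valid).any() or not np.all(np.isfinite(ts.diameter)):
            raise UnusableSignalError("resample_common requires gap-free traces")
    rate = listener.rate_hz
    if speaker.rate_hz != rate:
        frac = Fraction(rate / speaker.rate_hz).limit_denominator(1000)
        d = _signal.resample_poly(
            speaker.diameter, frac.numerator, frac.denominator, padtype="line"
        )
        t = speaker.t[0] + np.arange(len(d)) / rate
    else:
        d = speaker.diameter.copy()
        t = speaker.t.copy()

    start = max(t[0], listener.t[0])
    stop = min(t[-1], listener.t[-1])
    if stop <= start:
        raise InsufficientDataError("speaker and listener traces do not overlap")

    def trim(tv, dv):
        i0 = int(np.searchsorted(tv, start - 1e-9))
        i1 = int(np.searchsorted(tv, stop + 1e-9, side="right"))
        return tv[i0:i1], dv[i0:i1]

    t_sp, d_sp = trim(t, d)
    t_li, d_li = trim(listener.t, listener.diameter)
    n = min(len(d_sp), len(d_li))
    if n < 2:
        raise InsufficientDataError("overlap too short after alignment")

    def build(tv, dv, interp):
        return PupilTimeSeries(
            t=tv[:n] - tv[0],
            diameter=_zscore(dv[:n]),
            valid=np.ones(n, dtype=bool),
            rate_hz=rate,
            interpolated_fraction=interp,
        )

    return (
        build(t_sp, d_sp, speaker.interpolated_fraction),
        build(t_li, d_li, listener.interpolated_fraction),
    )


def _cosine_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine distance (1 - cosine similarity) between segment rows.

    A zero-norm segment is treated as orthogonal to everything (distance 1)
    except to another zero segment (distance 0).
    """
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    dots = A @ B.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = dots / np.outer(na, nb)
    zero_a = na == 0
    zero_b = nb == 0
    sim[zero_a, :] = 0.0
    sim[:, zero_b] = 0.0
    sim[np.ix_(zero_a, zero_b)] = 1.0
    return 1.0 - sim


def dtw_cost(a: np.ndarray, b: np.ndarray, n_segments: int) -> float:
    """Minimal accumulated cosine-distance alignment cost of two windows.

    Both windows are split into ``n_segments`` equal segments.  An
    alignment path starts at the first segment pair, ends at the last, and
    advances by one segment on either signal or both (the three admissible
    comparisons); every segment pair on the path accrues its cosine
    distance as a penalty.  The returned cost is the minimum total penalty,
    found by dynamic programming.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("windows must be 1-D and of equal length")
    m = len(a)
    if n_segments < 1 or m % n_segments != 0:
        valid = [k for k in range(1, m + 1) if m % k == 0]
        raise ConfigurationError(
            f"window of {m} samples is not divisible into {n_segments} "
            f"segments; valid counts: {valid}"
        )
    seg = m // n_segments
    A = a.reshape(n_segments, seg)
    B = b.reshape(n_segments, seg)
    D = _cosine_distance_matrix(A, B)

    C = np.full((n_segments, n_segments), np.inf)
    C[0, 0] = D[0, 0]
    for i in range(n_segments):
        for j in range(n_segments):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = C[i - 1, j - 1]
            if i > 0:
                best = min(best, C[i - 1, j])
            if j > 0:
                best = min(best, C[i, j - 1])
            C[i, j] = D[i, j] + best
    return float(C[-1, -1])


def windowed_synchrony(
    speaker: PupilTimeSeries,
    listener: PupilTimeSeries,
    window_s: float = 3.0,
    hop_s: float = 1.5,
    n_segments: int = 10,
    bin_s: float = 6.0,
    eps: float = LOG_EPS,
) -> SynchronyTrace:
    """Sliding-window warping costs, 6 s binning, and the story value.

    The pair is aligned with :func:`resample_common` first.  Window costs
    are grouped into non-overlapping ``bin_s`` bins by window start time
    and averaged; the story value is ``-mean(log(bin_cost + eps))`` so that
    larger values mean higher synchrony.
    """
    sp, li = resample_common(speaker, listener)
    rate = li.rate_hz
    n = len(li)
    if n / rate < bin_s:
        raise InsufficientDataError(
            f"story of {n / rate:.1f} s is shorter than one {bin_s:g} s bin"
        )
    win = int(round(window_s * rate))
    hop = int(round(hop_s * rate))
    if win % n_segments != 0:
        valid = [k for k in range(1, win + 1) if win % k == 0]
        raise ConfigurationError(
            f"{win}-sample windows are not divisible into {n_segments} "
            f"segments; valid counts: {valid}"
        )
    starts = np.arange(0, n - win + 1, hop)
    costs = np.array(
        [dtw_cost(sp.diameter[s:s + win], li.diameter[s:s + win], n_segments)
         for s in starts],
        dtype=float,
    )
    start_times = starts / rate

    bin_idx = np.floor(start_times / bin_s).astype(int)
    bins = np.unique(bin_idx)
    six_s = np.array([costs[bin_idx == k].mean() for k in bins])
    story_value = float(-np.mean(np.log(six_s + eps)))
    return SynchronyTrace(
        window_starts=start_times,
        costs=costs,
        bin_starts=bins * bin_s,
        six_s_costs=six_s,
        story_value=story_value,
        n_segments=n_segments,
    )


def story_table(
    values: Mapping[tuple, "SynchronyTrace | float"],
    qc: Mapping[object, QCVerdict] | None = None,
    expected_stories: list | None = None,
) -> pd.DataFrame:
    """Long table of story-level synchrony: one row per listener-story.

    ``values`` maps (participant, story) to a SynchronyTrace or a bare
    story value.  Listeners whose QC verdict is unusable are excluded (and
    logged); when ``expected_stories`` is given, missing listener-story
    combinations appear as NaN rows so they stay visible downstream.
    """
    rows = []
    excluded = set()
    if qc is not None:
        for participant, verdict in qc.items():
            if not verdict.usable:
                excluded.add(participant)
                logger.warning(
                    "excluding listener %r: %s", participant, verdict.reason
                )
    for (participant, story), value in values.items():
        if participant in excluded:
            continue
        sv = value.story_value if isinstance(value, SynchronyTrace) else float(value)
        rows.append((participant, story, sv))
    df = pd.DataFrame(rows, columns=["participant", "story", "story_value"])
    if expected_stories is not None and len(df):
        grid = pd.MultiIndex.from_product(
            [df["participant"].unique(), expected_stories],
            names=["participant", "story"],
        )
        df = (
            df.set_index(["participant", "story"])
            .reindex(grid)
            .reset_index()
        )
        n_missing = int(df["story_value"].isna().sum())
        if n_missing:
            logger.warning("%d listener-story values missing", n_missing)
    return df
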