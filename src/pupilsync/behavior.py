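"""Oddball task performance: press classification and d-prime.

d' = Z(hits / n_targets) - Z(false_alarms / n_distractors), with the
log-linear correction (add 0.5 to counts, 1 to totals) applied when a
rate is exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError
from .synth import ResponseLog, StimulusSequence

__all__ = ["ResponseSummary", "classify_presses", "dprime", "score_session"]


@dataclass
class ResponseSummary:
    hits: int
    n_targets: int
    false_alarms: int
    n_distractors: int
    dprime: float | None = None

    def __post_init__(self) -> None:
        if self.hits > self.n_targets:
            raise ValueError("hits cannot exceed n_targets")
        if self.false_alarms > self.n_distractors:
            raise ValueError("false_alarms cannot exceed n_distractors")

    @property
    def hit_rate(self) -> float:
        return self.hits / self.n_targets

    @property
    def fa_rate(self) -> float:
        return self.false_alarms / self.n_distractors


def classify_presses(
    seq: StimulusSequence,
    log: ResponseLog,
    response_window_ms: int | None = None,
) -> ResponseSummary:
    """Assign each press to the most recent tone slot and count hits/FAs.

    A press within ``response_window_ms`` (default one ISI) after a target
    onset is a hit; at most one press counts per slot (extra presses in the
    same slot are ignored).  Presses attributed to any non-target slot —
    including omission slots — are false alarms.  ``n_distractors`` is the
    number of non-target *tones* (standards + novels).
    """
    if response_window_ms is None:
        response_window_ms = seq.isi_ms
    onsets = seq.onsets_ms
    conditions = seq.events["condition"].to_numpy()
    n_targets = int((conditions == "target").sum())
    n_distractors = int(np.isin(conditions, ("standard", "novel")).sum())

    hit_slots: set[int] = set()
    fa_slots: set[int] = set()
    for press in log.press_times_ms:
        idx = int(np.searchsorted(onsets, press, side="right")) - 1
        if idx < 0:
            continue  # press before the first tone: not attributable
        if press - onsets[idx] >= response_window_ms:
            continue  # after the last tone's window
        if conditions[idx] == "target":
            hit_slots.add(idx)
        else:
            fa_slots.add(idx)
    return ResponseSummary(
        hits=len(hit_slots),
        n_targets=n_targets,
        false_alarms=len(fa_slots),
        n_distractors=n_distractors,
    )


def dprime(summary: ResponseSummary, correction: str = "loglinear") -> float:
    """Sensitivity d' from a response summary.

    ``correction="loglinear"`` rescues extreme rates (0 or 1) by adding 0.5
    to both counts and 1 to both totals; non-extreme rates are untouched.
    ``correction="none"`` uses raw rates (infinite for extreme rates).
    """
    if correction not in ("loglinear", "none"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    h, nt = summary.hits, summary.n_targets
    f, nd = summary.false_alarms, summary.n_distractors
    if nt == 0 or nd == 0:
        raise ConfigurationError(
            "d' is undefined without both targets and distractors"
        )
    extreme = h in (0, nt) or f in (0, nd)
    if correction == "loglinear" and extreme:
        hr = (h + 0.5) / (nt + 1)
        far = (f + 0.5) / (nd + 1)
    else:
        hr = h / nt
        far = f / nd
    return float(norm.ppf(hr) - norm.ppf(far))


def score_session(
    seq: StimulusSequence,
    log: ResponseLog,
    response_window_ms: int | None = None,
    correction: str = "loglinear",
) -> ResponseSummary:
    """Classify presses and fill in d' in one step."""
    summary = classify_presses(seq, log, response_window_ms)
    summary.dprime = dprime(summary, correction)
    return summary
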