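"""Within- vs between-participant reliability of pupil responses and scores.

Response curves (per-condition mean epochs) are compared with Pearson
correlations: every same-participant cross-session pair contributes a
"within" r, every cross-participant session pair a "between" r.  The two
sets are contrasted with a Mann-Whitney U test plus Cohen's d (pooled SD).
Entrainment scores are compared the same way on absolute cross-session
difference scores, where reliable individual differences make the within
differences *smaller* (negative d).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .preprocess import TrialMatrix

__all__ = [
    "ResponseCurve",
    "ReliabilityResult",
    "TrialFeatures",
    "condition_average",
    "curve_reliability",
    "score_reliability",
    "trial_features",
    "cohens_d",
]


@dataclass
class ResponseCurve:
    """Mean 3 s epoch of one condition for one participant-session."""

    samples: np.ndarray
    condition: str
    participant: str | int | None = None
    session: str | int | None = None


@dataclass
class ReliabilityResult:
    within: np.ndarray
    between: np.ndarray
    U: float
    p: float
    d: float
    statistic: str = "pearson_r"

    @property
    def n_within(self) -> int:
        return len(self.within)

    @property
    def n_between(self) -> int:
        return len(self.between)

    @property
    def mean_within(self) -> float:
        return float(np.mean(self.within))

    @property
    def mean_between(self) -> float:
        return float(np.mean(self.between))


@dataclass
class TrialFeatures:
    """Shape features of a mean trial response curve.

    ``amplitude``: peak value; ``latency_s``: time to peak; ``width_s``:
    total duration above half of the peak (NaN when the curve is flat or
    non-positive, i.e. the width is undefined).
    """

    amplitude: float
    latency_s: float
    width_s: float


def condition_average(
    trials: TrialMatrix,
    condition: str,
    correct_only: bool = False,
    correct: np.ndarray | None = None,
) -> np.ndarray | None:
    """Pointwise mean epoch over kept trials of one condition.

    For target trials, pass ``correct_only=True`` with a per-trial
    ``correct`` mask to average correct (hit) trials only.  Returns None
    when no trial survives, so callers can exclude the missing curve.
    """
    mask = (trials.condition == condition) & trials.kept
    if correct_only:
        if correct is None:
            raise ValueError("correct_only requires a per-trial correct mask")
        mask &= np.asarray(correct, dtype=bool)
    if not mask.any():
        return None
    return trials.epochs[mask].mean(axis=0)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (a minus b) with pooled SD.

    Returns 0 when both groups are constant (no variance to standardize by).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
    if pooled == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _pairings(units: Mapping) -> tuple[list[tuple], list[tuple]]:
    """Enumerate same-participant and cross-participant session pairs."""
    within, between = [], []
    participants = list(units)
    for p in participants:
        for s1, s2 in itertools.combinations(sorted(units[p]), 2):
            within.append(((p, s1), (p, s2)))
    for p1, p2 in itertools.combinations(participants, 2):
        for s1 in units[p1]:
            for s2 in units[p2]:
                between.append(((p1, s1), (p2, s2)))
    return within, between


def _contrast(within: np.ndarray, between: np.ndarray, statistic: str) -> ReliabilityResult:
    if np.ptp(np.concatenate([within, between])) == 0.0:
        # degenerate: all values identical -> no separation by construction
        U = len(within) * len(between) / 2.0
        return ReliabilityResult(within, between, U=U, p=1.0, d=0.0, statistic=statistic)
    U, p = stats.mannwhitneyu(within, between, alternative="two-sided")
    return ReliabilityResult(
        within, between, U=float(U), p=float(p),
        d=cohens_d(within, between), statistic=statistic,
    )


def curve_reliability(
    curves: Mapping[object, Mapping[object, np.ndarray]]
) -> ReliabilityResult:
    """Contrast within- vs between-participant response-curve correlations.

    ``curves[participant][session]`` is a mean epoch (missing curves simply
    absent).  Requires at least two participants and at least one
    same-participant session pair.
    """
    if len(curves) < 2:
        raise InsufficientDataError("need curves from at least two participants")
    within_pairs, between_pairs = _pairings(curves)
    if not within_pairs:
        raise InsufficientDataError(
            "no participant has two sessions; within-participant "
            "correlations are undefined"
        )

    def r(pair):
        (p1, s1), (p2, s2) = pair
        a, b = curves[p1][s1], curves[p2][s2]
        if np.std(a) == 0 or np.std(b) == 0:
            return 1.0 if np.allclose(a, b) else 0.0
        return float(np.corrcoef(a, b)[0, 1])

    within = np.array([r(pair) for pair in within_pairs])
    between = np.array([r(pair) for pair in between_pairs])
    return _contrast(within, between, "pearson_r")


def score_reliability(
    scores: Mapping[object, Mapping[object, float]]
) -> ReliabilityResult:
    """Contrast within- vs between-participant |score difference| values.

    Stable per-subject entrainment makes within-participant differences
    stochastically smaller than between-participant ones (negative d).
    """
    if len(scores) < 2:
        raise InsufficientDataError("need scores from at least two participants")
    within_pairs, between_pairs = _pairings(scores)
    if not within_pairs:
        raise InsufficientDataError(
            "no participant has two sessions; within-participant "
            "difference scores are undefined"
        )

    def diff(pair):
        (p1, s1), (p2, s2) = pair
        return abs(scores[p1][s1] - scores[p2][s2])

    within = np.array([diff(pair) for pair in within_pairs])
    between = np.array([diff(pair) for pair in between_pairs])
    return _contrast(within, between, "abs_score_difference")


def trial_features(
    trials: TrialMatrix,
    condition: str,
    correct_only: bool = False,
    correct: np.ndarray | None = None,
) -> TrialFeatures:
    """Amplitude, peak latency and half-max width of the mean curve."""
    curve = condition_average(trials, condition, correct_only, correct)
    if curve is None:
        raise InsufficientDataError(f"no kept trials of condition {condition!r}")
    dt = 1.0 / trials.rate_hz
    amplitude = float(curve.max())
    latency = float(np.argmax(curve) * dt)
    if amplitude <= 0.0 or np.ptp(curve) == 0.0:
        width = float("nan")
    else:
        width = float(np.sum(curve > amplitude / 2.0) * dt)
    return TrialFeatures(amplitude=amplitude, latency_s=latency, width_s=width)
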