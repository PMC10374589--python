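"""Trial exclusion rules and data-selection bookkeeping.

Saccades are detected from per-trial eye traces (250 Hz, 40 px per degree)
as any sample whose distance from the trial's mean eye position exceeds both
2 standard deviations of those distances and 20 px (0.5 degrees).  Pointing
movements are scored correct when the executed left/right direction matches
the trial's movement-goal side.  Excluded trials are counted in exactly one
of three mutually exclusive categories (wrong movement only, saccade only,
combined); trials with missing hand or eye data are tallied but not
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .design import goal_side

PIXELS_PER_DEGREE = 40.0
EYE_SAMPLING_HZ = 250.0


def _pct(n: int, total: int) -> float:
    """Percentage of total, one decimal, half-up (presentation convention)."""
    if total == 0:
        return 0.0
    return float(Decimal(100.0 * n / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def detect_saccade(trace, sd_multiplier: float = 2.0, min_px: float = 20.0) -> bool:
    """Flag a trial whose gaze deviates >2 s.d. and >20 px from its mean.

    The deviation is the Euclidean distance of each sample from the trial's
    mean 2D eye position, making the rule translation- and rotation-
    invariant.  Both criteria must be exceeded by the same sample.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 2:
        raise ValueError("eye trace needs at least 2 samples of 2D positions")
    if not np.isfinite(trace).all():
        raise ValueError("eye trace contains non-finite samples")
    dist = np.linalg.norm(trace - trace.mean(axis=0), axis=1)
    sd = dist.std()
    return bool(np.any((dist > sd_multiplier * sd) & (dist > min_px)))


def score_movement(executed_direction, trial) -> str:
    """Score a pointing movement: 'correct', 'wrong', or 'missing'."""
    if executed_direction is None:
        return "missing"
    if executed_direction not in ("left", "right"):
        raise ValueError(f"invalid movement direction {executed_direction!r}")
    target = goal_side(trial.foot, trial.posture, trial.task_rule)
    return "correct" if executed_direction == target else "wrong"


@dataclass
class ExclusionReport:
    n_total: int
    n_wrong_movement: int
    n_saccade: int
    n_combined: int
    n_missing_hand: int
    n_missing_eye: int
    n_included: int
    pct_wrong_movement: float
    pct_saccade: float
    pct_combined: float
    pct_included: float

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(trials, saccade_flags, movement_scores, eye_available=None):
    """Partition trials into included / excluded-by-category sets.

    ``movement_scores`` entries are 'correct' / 'wrong' / 'missing';
    ``saccade_flags`` are booleans (None marks missing eye data, which is
    counted but never excludes a trial).  Returns
    (ExclusionReport, included_trials).
    """
    n = len(trials)
    if len(saccade_flags) != n or len(movement_scores) != n:
        raise ValueError("trials, saccade_flags and movement_scores must align")
    if eye_available is None:
        eye_available = [f is not None for f in saccade_flags]

    wrong_only = saccade_only = combined = missing_hand = missing_eye = 0
    included = []
    for trial, sacc, score, eye_ok in zip(trials, saccade_flags, movement_scores, eye_available):
        is_wrong = score == "wrong"
        is_sacc = bool(sacc) if sacc is not None else False
        if score == "missing":
            missing_hand += 1
        if not eye_ok:
            missing_eye += 1
        if is_wrong and is_sacc:
            combined += 1
        elif is_wrong:
            wrong_only += 1
        elif is_sacc:
            saccade_only += 1
        else:
            included.append(trial)
    n_included = n - wrong_only - saccade_only - combined
    report = ExclusionReport(
        n_total=n,
        n_wrong_movement=wrong_only,
        n_saccade=saccade_only,
        n_combined=combined,
        n_missing_hand=missing_hand,
        n_missing_eye=missing_eye,
        n_included=n_included,
        pct_wrong_movement=_pct(wrong_only, n),
        pct_saccade=_pct(saccade_only, n),
        pct_combined=_pct(combined, n),
        pct_included=_pct(n_included, n),
    )
    return report, included
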