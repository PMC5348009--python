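"""Trial- and subject-level rejection rules.

Trials are dropped when the key was not released during the inter-trial
interval, when no-or-double-press time within the 2-s trial exceeds 1 s, or
when blinks + saccades + tracker dropouts within the trial exceed 1 s.  A
subject is dropped when more than half of their rivalrous or non-rivalrous
trials fail the button criteria (or, separately, the eye criteria), and —
after those rejections — when fewer than 3 kept rivalrous trials are
labelled dominantly-left or fewer than 3 dominantly-right.

"More than half" is strict: rejecting exactly half keeps the subject.
First-of-block trials carry no pre-onset gaze recording; they are excluded
from eye-movement analyses and do not enter the eye-rejection denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .button_press import TrialLabel
from .okn import ArtifactInterval, artifact_time_in_window
from .session_io import ButtonTrace, ITI_S, TRIAL_S, Trial

__all__ = [
    "TrialReason",
    "SubjectReason",
    "RejectionRecord",
    "SubjectDecision",
    "reject_trial_bp",
    "reject_trial_eye",
    "decide_subject",
    "MAX_BAD_PRESS_S",
    "MAX_ARTIFACT_S",
    "MIN_LABELLED_PER_SIDE",
]

#: no-or-double-press time within the 2-s trial beyond which it is rejected
MAX_BAD_PRESS_S = 1.0
#: artifact time within the 2-s trial beyond which it is rejected
MAX_ARTIFACT_S = 1.0
#: minimum kept rivalrous trials per labelled direction
MIN_LABELLED_PER_SIDE = 3


class TrialReason(enum.Enum):
    NOT_RELEASED_ITI = "NOT_RELEASED_ITI"
    NO_OR_DOUBLE_GT_1S = "NO_OR_DOUBLE_GT_1S"
    EYE_ARTIFACT_GT_1S = "EYE_ARTIFACT_GT_1S"
    FIRST_OF_BLOCK = "FIRST_OF_BLOCK"


#: reasons attributable to the button-press criteria
BP_REASONS = frozenset({TrialReason.NOT_RELEASED_ITI, TrialReason.NO_OR_DOUBLE_GT_1S})
#: reasons attributable to the eye-movement criteria
EYE_REASONS = frozenset({TrialReason.EYE_ARTIFACT_GT_1S})


class SubjectReason(enum.Enum):
    BP_HALF = "BP_HALF"
    EYE_HALF = "EYE_HALF"
    IMBALANCE = "IMBALANCE"


@dataclass
class RejectionRecord:
    trial: Trial
    reasons: set[TrialReason] = field(default_factory=set)

    @property
    def kept(self) -> bool:
        return not self.reasons


@dataclass
class SubjectDecision:
    subject_id: str
    reasons: set[SubjectReason] = field(default_factory=set)

    @property
    def kept(self) -> bool:
        return not self.reasons


def reject_trial_bp(raw: ButtonTrace) -> set[TrialReason]:
    """Button-press rejection reasons for one trial.

    ``raw`` is the segment on [0, 3] s relative to onset (trial + following
    inter-trial interval).  NOT_RELEASED_ITI: no released sample
    (``raw_bp == 0``) anywhere in the ITI (2, 3] s — a single released
    instant counts as a release.  NO_OR_DOUBLE_GT_1S: total ``raw_bp == 0``
    time within [0, 2] s exceeds 1 s, counting each sample as one sampling
    interval.
    """
    t, b = raw.time_s, raw.raw_bp
    dt = 1.0 / raw.rate_hz
    iti = (t > TRIAL_S) & (t <= TRIAL_S + ITI_S)
    reasons: set[TrialReason] = set()
    if iti.any() and not (b[iti] == 0).any():
        reasons.add(TrialReason.NOT_RELEASED_ITI)
    in_trial = (t >= 0.0) & (t < TRIAL_S)
    if np.count_nonzero(b[in_trial] == 0) * dt > MAX_BAD_PRESS_S:
        reasons.add(TrialReason.NO_OR_DOUBLE_GT_1S)
    return reasons


def reject_trial_eye(
    intervals: list[ArtifactInterval], onset_s: float = 0.0
) -> set[TrialReason]:
    """Eye-movement rejection for one trial: artifact time within its 2-s
    window (``onset_s`` in the intervals' time base) exceeding 1 s."""
    total = artifact_time_in_window(intervals, onset_s, onset_s + TRIAL_S)
    return {TrialReason.EYE_ARTIFACT_GT_1S} if total > MAX_ARTIFACT_S else set()


def decide_subject(
    subject_id: str,
    records: list[RejectionRecord],
    labels: dict[tuple[int, int], TrialLabel | None] | None = None,
) -> SubjectDecision:
    """Apply the subject-level rejection rules to one session's records.

    ``labels`` maps (block_index, trial_index_in_block) of rivalrous trials
    to their dominant-direction labels (None for unlabelled trials); only
    needed for the imbalance rule.  An empty rivalrous or non-rivalrous
    subset rejects the subject outright with the corresponding reason.
    """
    labels = labels or {}
    decision = SubjectDecision(subject_id=subject_id)

    riv = [r for r in records if r.trial.condition.rivalrous]
    nonriv = [r for r in records if not r.trial.condition.rivalrous]

    for subset in (riv, nonriv):
        if _reject_fraction(subset, BP_REASONS, exclude_first=False):
            decision.reasons.add(SubjectReason.BP_HALF)
        if _reject_fraction(subset, EYE_REASONS, exclude_first=True):
            decision.reasons.add(SubjectReason.EYE_HALF)

    kept_riv = [r for r in riv if r.kept]
    counts = {-1: 0, +1: 0}
    for r in kept_riv:
        lab = labels.get((r.trial.block_index, r.trial.trial_index_in_block))
        if lab is not None and lab.label_dir is not None:
            counts[lab.label_dir] += 1
    if min(counts.values()) < MIN_LABELLED_PER_SIDE:
        decision.reasons.add(SubjectReason.IMBALANCE)
    return decision


def _reject_fraction(
    subset: list[RejectionRecord],
    reasons: frozenset[TrialReason],
    exclude_first: bool,
) -> bool:
    """True when the subset trips the strict more-than-half rule for the
    given criterion family (or is empty)."""
    if exclude_first:
        subset = [r for r in subset if not r.trial.first_of_block]
    if not subset:
        return True
    n_rej = sum(1 for r in subset if r.reasons & reasons)
    return n_rej > 0.5 * len(subset)
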