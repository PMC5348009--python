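import numpy as np
import pytest

from oknbr import qc
from oknbr.button_press import TrialLabel
from oknbr.okn import ArtifactInterval, ArtifactKind
from oknbr.session_io import ButtonTrace, Condition, Trial

RATE = 60.0


def buttons_from_segments(segments, duration_s=3.0):
    """Build a [0, 3] s trial+ITI button segment from (start, end, value)."""
    n = int(duration_s * RATE) + 1
    t = np.arange(n) / RATE
    raw = np.zeros(n, int)
    for start, end, value in segments:
        raw[(t >= start) & (t < end)] = value
    return ButtonTrace(t, raw)


def make_trial(idx, condition=Condition.RIVALROUS, block=0):
    return Trial(block_index=block, trial_index_in_block=idx,
                 onset_s=1.0 + 3.0 * idx, condition=condition)


class TestRejectTrialBp:
    def test_held_through_iti(self):
        raw = buttons_from_segments([(0.5, 3.1, 1)])
        assert qc.reject_trial_bp(raw) == {qc.TrialReason.NOT_RELEASED_ITI}

    def test_no_press_whole_trial(self):
        raw = buttons_from_segments([])
        assert qc.reject_trial_bp(raw) == {qc.TrialReason.NO_OR_DOUBLE_GT_1S}

    def test_normal_trial_kept_by_sample_count(self):
        # press at 0.4 s, held to 1.9 s, released in ITI: 0.5 s unpressed < 1 s
        raw = buttons_from_segments([(0.4, 1.9, 1)])
        assert qc.reject_trial_bp(raw) == set()

    def test_unpressed_time_just_over_threshold(self):
        # exactly 1 s unpressed is fine; more than 1 s is rejected
        ok = buttons_from_segments([(1.0, 2.0, -1)])
        assert qc.TrialReason.NO_OR_DOUBLE_GT_1S not in qc.reject_trial_bp(ok)
        late = buttons_from_segments([(1.1, 2.0, -1)])
        assert qc.TrialReason.NO_OR_DOUBLE_GT_1S in qc.reject_trial_bp(late)

    def test_single_released_instant_counts_as_release(self):
        n = int(3.0 * RATE) + 1
        t = np.arange(n) / RATE
        raw = np.ones(n, int)
        raw[t == 2.5] = 0
        assert qc.TrialReason.NOT_RELEASED_ITI not in qc.reject_trial_bp(
            ButtonTrace(t, raw)
        )


class TestRejectTrialEye:
    def test_clean_trial(self):
        assert qc.reject_trial_eye([], onset_s=0.0) == set()

    def test_long_blink_rejected(self):
        ivs = [ArtifactInterval(0.3, 1.5, ArtifactKind.BLINK_OR_MISSING)]
        assert qc.reject_trial_eye(ivs) == {qc.TrialReason.EYE_ARTIFACT_GT_1S}

    def test_many_short_saccades_total_under_threshold(self):
        # ten 90-ms saccades: 0.9 s total, kept
        ivs = [
            ArtifactInterval(0.05 + 0.2 * i, 0.14 + 0.2 * i, ArtifactKind.SACCADE)
            for i in range(10)
        ]
        assert qc.reject_trial_eye(ivs) == set()

    def test_intersection_with_trial_window(self):
        # 2 s artifact, but only 0.5 s inside the trial
        ivs = [ArtifactInterval(1.5, 3.5, ArtifactKind.BLINK_OR_MISSING)]
        assert qc.reject_trial_eye(ivs, onset_s=0.0) == set()
        assert qc.reject_trial_eye(ivs, onset_s=2.0) == {
            qc.TrialReason.EYE_ARTIFACT_GT_1S
        }


def _records(cond, reasons_list, start_idx=1):
    out = []
    for i, reasons in enumerate(reasons_list):
        out.append(
            qc.RejectionRecord(
                trial=make_trial(start_idx + i, condition=cond),
                reasons=set(reasons),
            )
        )
    return out


class TestDecideSubject:
    def test_more_than_half_bp_rejected(self):
        nonriv = _records(
            Condition.NONRIV_LEFT,
            [{qc.TrialReason.NOT_RELEASED_ITI}] * 6 + [set()] * 4,
        )
        riv = _records(Condition.RIVALROUS, [set()] * 10)
        labels = {
            (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                p_bp=(-1.0) ** i
            )
            for i, r in enumerate(riv)
        }
        d = qc.decide_subject("s", nonriv + riv, labels)
        assert d.reasons == {qc.SubjectReason.BP_HALF}

    def test_exactly_half_keeps_subject(self):
        nonriv = _records(
            Condition.NONRIV_RIGHT,
            [{qc.TrialReason.NO_OR_DOUBLE_GT_1S}] * 5 + [set()] * 5,
        )
        riv = _records(Condition.RIVALROUS, [set()] * 10)
        labels = {
            (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                p_bp=(-1.0) ** i
            )
            for i, r in enumerate(riv)
        }
        d = qc.decide_subject("s", nonriv + riv, labels)
        assert d.kept

    def test_imbalance_needs_three_per_side(self):
        riv = _records(Condition.RIVALROUS, [set()] * 14)
        nonriv = _records(Condition.NONRIV_LEFT, [set()] * 6)
        labels = {}
        for i, r in enumerate(riv):
            p = 1.0 if i < 12 else -1.0  # 12 right, 2 left
            labels[(r.trial.block_index, r.trial.trial_index_in_block)] = TrialLabel(p)
        d = qc.decide_subject("s", riv + nonriv, labels)
        assert d.reasons == {qc.SubjectReason.IMBALANCE}

    def test_all_kept_balanced(self):
        riv = _records(Condition.RIVALROUS, [set()] * 10)
        nonriv = _records(Condition.NONRIV_RIGHT, [set()] * 10)
        labels = {
            (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                p_bp=(-1.0) ** i
            )
            for i, r in enumerate(riv)
        }
        assert qc.decide_subject("s", riv + nonriv, labels).kept

    def test_empty_subset_rejects(self):
        riv = _records(Condition.RIVALROUS, [set()] * 10)
        labels = {
            (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                p_bp=(-1.0) ** i
            )
            for i, r in enumerate(riv)
        }
        d = qc.decide_subject("s", riv, labels)  # no non-rivalrous trials at all
        assert not d.kept

    def test_monotonicity_adding_reasons_never_rescues(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            riv = _records(
                Condition.RIVALROUS,
                [
                    {qc.TrialReason.NOT_RELEASED_ITI} if rng.random() < 0.4 else set()
                    for _ in range(10)
                ],
            )
            nonriv = _records(
                Condition.NONRIV_LEFT,
                [
                    {qc.TrialReason.EYE_ARTIFACT_GT_1S} if rng.random() < 0.4 else set()
                    for _ in range(10)
                ],
            )
            labels = {
                (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                    p_bp=(-1.0) ** i
                )
                for i, r in enumerate(riv)
            }
            records = riv + nonriv
            before = qc.decide_subject("s", records, labels)
            victim = records[int(rng.integers(len(records)))]
            victim.reasons.add(qc.TrialReason.NO_OR_DOUBLE_GT_1S)
            after = qc.decide_subject("s", records, labels)
            if not before.kept:
                assert not after.kept


class TestToyCohortOracle:
    """A constructed 40-trial cohort whose per-reason counts are enumerated
    by hand and must be reproduced exactly."""

    def build(self):
        # subject A: 20 trials (10 nonriv, 10 riv).
        #   nonriv: 2 held-through-ITI, 1 long-gap, 7 clean
        #   riv: 1 eye artifact, 9 clean; labels 5 right / 4 left / 1 right
        a_nonriv = _records(
            Condition.NONRIV_LEFT,
            [{qc.TrialReason.NOT_RELEASED_ITI}] * 2
            + [{qc.TrialReason.NO_OR_DOUBLE_GT_1S}]
            + [set()] * 7,
        )
        a_riv = _records(
            Condition.RIVALROUS,
            [{qc.TrialReason.EYE_ARTIFACT_GT_1S}] + [set()] * 9,
            start_idx=11,
        )
        a_labels = {}
        for i, r in enumerate(a_riv):
            key = (r.trial.block_index, r.trial.trial_index_in_block)
            a_labels[key] = TrialLabel(1.0 if i % 2 == 0 else -1.0)
        # subject B: 20 trials; 6 of 10 nonriv rejected by BP -> BP_HALF
        b_nonriv = _records(
            Condition.NONRIV_RIGHT,
            [{qc.TrialReason.NOT_RELEASED_ITI}] * 6 + [set()] * 4,
        )
        b_riv = _records(Condition.RIVALROUS, [set()] * 10, start_idx=11)
        b_labels = {
            (r.trial.block_index, r.trial.trial_index_in_block): TrialLabel(
                1.0 if i % 2 else -1.0
            )
            for i, r in enumerate(b_riv)
        }
        return (a_nonriv + a_riv, a_labels), (b_nonriv + b_riv, b_labels)

    def test_per_reason_counts(self):
        (a_recs, _), (b_recs, _) = self.build()
        counts = {}
        for rec in a_recs + b_recs:
            for reason in rec.reasons:
                counts[reason] = counts.get(reason, 0) + 1
        assert counts == {
            qc.TrialReason.NOT_RELEASED_ITI: 8,
            qc.TrialReason.NO_OR_DOUBLE_GT_1S: 1,
            qc.TrialReason.EYE_ARTIFACT_GT_1S: 1,
        }
        assert sum(1 for r in a_recs + b_recs if not r.kept) == 10

    def test_subject_decisions(self):
        (a_recs, a_labels), (b_recs, b_labels) = self.build()
        da = qc.decide_subject("A", a_recs, a_labels)
        db = qc.decide_subject("B", b_recs, b_labels)
        assert da.kept
        assert db.reasons == {qc.SubjectReason.BP_HALF}
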