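"""End-to-end analysis: sessions in, tidy result tables out.

Wires the stages together in the order the method runs: per-trial button
metrics -> QC -> slow-phase velocity -> per-subject mean curves and
discriminability curves -> latencies -> trial images -> group comparisons.
Everything is deterministic given the analysis seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import button_press as bp
from . import discriminability as dd
from . import group_stats as gs
from . import okn
from . import qc
from . import trial_image as ti
from .session_io import (
    Condition,
    ITI_S,
    POST_ONSET_S,
    PRE_ONSET_S,
    Session,
    TRIAL_S,
    segment,
)

__all__ = ["AnalysisParams", "SubjectResult", "CohortResult", "analyze_session",
           "analyze_cohort", "write_cohort_tables"]


@dataclass
class AnalysisParams:
    """Tunable parameters, defaulting to the printed analysis constants.

    The saccade thresholds default to the printed 6 deg/s / 1 deg/s^2; for
    synthetic sessions pass the generator's recommended velocity threshold
    (slow phases exceed 6 deg/s whenever okn_gain > 0.27) and disable the
    acceleration criterion.  ``time_stride`` thins the time grid on which
    discriminability is evaluated (1 = every sample).
    """

    v_thresh: float = okn.SACCADE_V_THRESH_DEG_S
    a_thresh: float = okn.SACCADE_A_THRESH_DEG_S2
    reps: int = dd.DEFAULT_REPS
    time_stride_okn: int = 1
    time_stride_bp: int = 1
    fdr_q: float = gs.FDR_Q
    equal_var: bool = True
    image_rows: int = ti.N_IMAGE_ROWS
    image_kernel: int = ti.ROW_SMOOTH_POINTS


@dataclass
class TrialResult:
    subject_id: str
    block: int
    trial: int
    condition: str
    onset_s: float
    label_dir: int | None
    p_bp: float
    first_press_s: float | None
    first_consistent_s: float | None
    accuracy: float | None
    reject_reasons: str
    kept: bool


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    trials: list[TrialResult]
    decision: qc.SubjectDecision
    #: per-condition mean consistency / velocity curves and their time bases
    bp_time_s: np.ndarray | None = None
    okn_time_s: np.ndarray | None = None
    mean_consistency: dict[str, np.ndarray] = field(default_factory=dict)
    mean_velocity: dict[str, np.ndarray] = field(default_factory=dict)
    discrim: dict[tuple[str, str], dd.DiscriminabilityCurve] = field(default_factory=dict)
    images: dict[str, ti.TrialImage] = field(default_factory=dict)
    latencies: list[dict] = field(default_factory=list)


def _trial_direction(trial, label: bp.TrialLabel) -> int | None:
    """Direction against which consistency is scored: the stimulus for
    non-rivalrous trials, the dominant-percept label for rivalrous ones."""
    if trial.condition.rivalrous:
        return label.label_dir
    return trial.stim_dir


def analyze_session(
    session: Session,
    params: AnalysisParams | None = None,
    rng: np.random.Generator | None = None,
) -> SubjectResult:
    params = params or AnalysisParams()
    rng = rng or np.random.default_rng(0)

    trial_rows: list[TrialResult] = []
    records: list[qc.RejectionRecord] = []
    labels: dict[tuple[int, int], bp.TrialLabel] = {}
    # per-trial signal stores, filled for kept trials
    bp_seg: dict[tuple[int, int], bp.BPTrace] = {}
    cons_seg: dict[tuple[int, int], bp.ConsistencyTrace] = {}
    vel_seg: dict[tuple[int, int], okn.VelocityTrace] = {}
    eye_ok: dict[tuple[int, int], bool] = {}

    for block in session.blocks:
        # block-level preprocessing so kernels never see window edges
        smoothed = bp.BPTrace(
            time_s=block.buttons.time_s,
            bp=bp.boxcar_smooth(block.buttons.raw_bp.astype(float),
                                bp.BP_KERNEL_S, block.buttons.rate_hz),
        )
        intervals = okn.detect_artifacts(block.gaze, params.v_thresh, params.a_thresh)
        velocity = okn.slow_phase_velocity(okn.integrate_okn(block.gaze, intervals))

        for trial in block.trials:
            key = (block.index, trial.trial_index_in_block)
            raw_trial = segment(block.buttons, trial.onset_s, 0.0, TRIAL_S)
            raw_iti = segment(block.buttons, trial.onset_s, 0.0, TRIAL_S + ITI_S + 1e-6)
            tsel = (smoothed.time_s >= trial.onset_s + PRE_ONSET_S - 1e-9) & (
                smoothed.time_s < trial.onset_s + POST_ONSET_S - 1e-9
            )
            bp_trace = bp.BPTrace(
                time_s=smoothed.time_s[tsel] - trial.onset_s, bp=smoothed.bp[tsel]
            )
            label = bp.dominant_label(bp_trace)
            labels[key] = label

            reasons = qc.reject_trial_bp(raw_iti)
            if trial.first_of_block:
                reasons |= {qc.TrialReason.FIRST_OF_BLOCK}
            else:
                reasons |= qc.reject_trial_eye(intervals, trial.onset_s)
            eye_ok[key] = not (
                {qc.TrialReason.EYE_ARTIFACT_GT_1S, qc.TrialReason.FIRST_OF_BLOCK}
                & reasons
            )
            rec = qc.RejectionRecord(trial=trial, reasons=reasons)
            records.append(rec)

            direction = _trial_direction(trial, label)
            first = bp.first_press_time(raw_trial)
            if direction is not None:
                cons = bp.consistency(bp_trace, direction)
                first_cons = bp.first_consistent_press_time(bp_trace, direction)
                acc = bp.response_accuracy(cons, first)
            else:
                cons, first_cons, acc = None, None, None

            bp_rejected = bool(reasons & qc.BP_REASONS)
            if not bp_rejected and direction is not None:
                bp_seg[key] = bp_trace
                cons_seg[key] = cons
            if eye_ok[key] and not bp_rejected:
                try:
                    vel_seg[key] = okn.trial_velocity(block, trial, velocity=velocity)
                except okn.FirstTrialOfBlock:
                    pass

            trial_rows.append(
                TrialResult(
                    subject_id=session.subject_id,
                    block=block.index,
                    trial=trial.trial_index_in_block,
                    condition=trial.condition.value,
                    onset_s=trial.onset_s,
                    label_dir=label.label_dir,
                    p_bp=label.p_bp,
                    first_press_s=first,
                    first_consistent_s=first_cons,
                    accuracy=acc,
                    reject_reasons=";".join(sorted(r.value for r in reasons)),
                    kept=rec.kept,
                )
            )

    decision = qc.decide_subject(
        session.subject_id,
        records,
        {k: v for k, v in labels.items()},
    )
    result = SubjectResult(
        subject_id=session.subject_id,
        group=session.group.value,
        trials=trial_rows,
        decision=decision,
    )
    _subject_curves(result, session, records, labels, bp_seg, cons_seg, vel_seg,
                    params, rng)
    return result


def _condition_keys(records, labels, rivalrous: bool):
    """(block, trial) keys of kept trials of one condition class with a
    usable direction, plus that direction per key."""
    out = {}
    for rec in records:
        if rec.trial.condition.rivalrous != rivalrous:
            continue
        key = (rec.trial.block_index, rec.trial.trial_index_in_block)
        lab = labels.get(key)
        d = lab.label_dir if rivalrous else rec.trial.stim_dir
        if d is not None:
            out[key] = d
    return out


def _subject_curves(result, session, records, labels, bp_seg, cons_seg, vel_seg,
                    params, rng) -> None:
    for cond_name, rivalrous in (("NONRIV", False), ("RIV", True)):
        dirs = _condition_keys(records, labels, rivalrous)

        # button-press side
        keys = [k for k in dirs if k in bp_seg]
        if keys:
            t_bp = bp_seg[keys[0]].time_s
            n = min(len(bp_seg[k].bp) for k in keys)
            bp_mat = np.vstack([bp_seg[k].bp[:n] for k in keys])
            cons_mat = np.vstack([cons_seg[k].c[:n] for k in keys])
            lab_vec = np.array([dirs[k] for k in keys])
            result.bp_time_s = t_bp[:n]
            result.mean_consistency[cond_name] = cons_mat.mean(axis=0)
            fm = dd.FeatureMatrix(
                bp_mat[:, :: params.time_stride_bp],
                lab_vec,
                t_bp[:n][:: params.time_stride_bp],
            )
            if min(np.sum(lab_vec == -1), np.sum(lab_vec == 1)) >= 2:
                result.discrim[("BP", cond_name)] = dd.discriminability_curve(
                    fm, rng, params.reps
                )
            cons_keys = np.array([float(np.mean(cons_seg[k].c[:n])) for k in keys])
            in_trial = (t_bp[:n] >= 0) & (t_bp[:n] < TRIAL_S)
            result.images[f"BP_{cond_name}"] = ti.build_subject_image(
                cons_mat[:, in_trial], cons_keys, t_bp[:n][in_trial],
                n_rows=params.image_rows, k=params.image_kernel,
            )

        # OKN side (needs both bp label and clean eye data)
        vkeys = [k for k in dirs if k in vel_seg]
        if vkeys:
            t_v = vel_seg[vkeys[0]].time_s
            n = min(len(vel_seg[k].v_deg_s) for k in vkeys)
            v_mat = np.vstack([vel_seg[k].v_deg_s[:n] for k in vkeys])
            lab_vec = np.array([dirs[k] for k in vkeys])
            result.okn_time_s = t_v[:n]
            # sign flipped for leftward trials so "with the percept" is positive
            result.mean_velocity[cond_name] = (v_mat * lab_vec[:, None]).mean(axis=0)
            fm = dd.FeatureMatrix(
                v_mat[:, :: params.time_stride_okn],
                lab_vec,
                t_v[:n][:: params.time_stride_okn],
            )
            if min(np.sum(lab_vec == -1), np.sum(lab_vec == 1)) >= 2:
                result.discrim[("OKN", cond_name)] = dd.discriminability_curve(
                    fm, rng, params.reps
                )
            ckeys = np.array(
                [
                    float(np.mean(cons_seg[k].c)) if k in cons_seg else 0.0
                    for k in vkeys
                ]
            )
            in_trial = (t_v[:n] >= 0) & (t_v[:n] < TRIAL_S)
            result.images[f"OKN_{cond_name}"] = ti.build_subject_image(
                v_mat[:, in_trial], ckeys, t_v[:n][in_trial], stim_dirs=lab_vec,
                n_rows=params.image_rows, k=params.image_kernel,
            )

    _subject_latencies(result)


def _subject_latencies(result: SubjectResult) -> None:
    for cond, curve in result.mean_consistency.items():
        lr = dd.half_max_latency(result.bp_time_s, curve, baseline=0.0)
        result.latencies.append(
            {"subject": result.subject_id, "group": result.group, "signal": "BP",
             "condition": cond, "measure": "half_max",
             "latency_s": lr.latency_s, "max_value": lr.max_value}
        )
        result.latencies.append(
            {"subject": result.subject_id, "group": result.group, "signal": "BP",
             "condition": cond, "measure": "reach_0.5",
             "latency_s": dd.consistency_threshold_latency(result.bp_time_s, curve),
             "max_value": lr.max_value}
        )
    for cond, curve in result.mean_velocity.items():
        lr = dd.half_max_latency(result.okn_time_s, curve, baseline=0.0)
        result.latencies.append(
            {"subject": result.subject_id, "group": result.group, "signal": "OKN",
             "condition": cond, "measure": "half_max",
             "latency_s": lr.latency_s, "max_value": lr.max_value}
        )
    for (signal, cond), curve in result.discrim.items():
        lr = dd.half_max_latency(curve.time_s, curve.d, baseline=0.5)
        result.latencies.append(
            {"subject": result.subject_id, "group": result.group,
             "signal": f"{signal}_discrim", "condition": cond,
             "measure": "half_max_above_chance",
             "latency_s": lr.latency_s, "max_value": lr.max_value}
        )


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    trials: pd.DataFrame
    qc_subjects: pd.DataFrame
    latencies: pd.DataFrame
    stats: pd.DataFrame
    group_images: dict[str, ti.TrialImage] = field(default_factory=dict)


def analyze_cohort(
    sessions: list[Session],
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> CohortResult:
    """Analyze each session, pool kept subjects, compare groups pointwise."""
    params = params or AnalysisParams()
    rng = np.random.default_rng(seed)
    results = [analyze_session(s, params, rng) for s in sessions]

    trials = pd.DataFrame([asdict(t) for r in results for t in r.trials])
    qc_rows = [
        {"subject": r.subject_id, "group": r.group, "kept": r.decision.kept,
         "reasons": ";".join(sorted(x.value for x in r.decision.reasons))}
        for r in results
    ]
    lat = pd.DataFrame([row for r in results for row in r.latencies])

    kept = [r for r in results if r.decision.kept]
    stats_rows = []
    groups = sorted({r.group for r in kept})
    if len(groups) == 2:
        ga = [r for r in kept if r.group == groups[0]]
        gb = [r for r in kept if r.group == groups[1]]
        for cond in ("NONRIV", "RIV"):
            for attr, tattr, sig in (
                ("mean_consistency", "bp_time_s", "consistency"),
                ("mean_velocity", "okn_time_s", "okn_speed"),
            ):
                a = [getattr(r, attr).get(cond) for r in ga]
                b = [getattr(r, attr).get(cond) for r in gb]
                a = [c for c in a if c is not None]
                b = [c for c in b if c is not None]
                if len(a) >= 2 and len(b) >= 2:
                    n = min(min(map(len, a)), min(map(len, b)))
                    t_axis = getattr(ga[0], tattr)[:n]
                    res = gs.pointwise_comparison(
                        np.vstack([c[:n] for c in a]),
                        np.vstack([c[:n] for c in b]),
                        t_axis, q=params.fdr_q, equal_var=params.equal_var,
                    )
                    for pr in res:
                        stats_rows.append(
                            {"comparison": f"{sig}_{cond}_{groups[0]}_vs_{groups[1]}",
                             "time_s": pr.time_s, "t": pr.t_stat, "p": pr.p_value,
                             "significant": pr.significant}
                        )
    stats = pd.DataFrame(stats_rows)

    group_images: dict[str, ti.TrialImage] = {}
    for g in groups:
        members = [r for r in kept if r.group == g]
        for img_key in ("BP_NONRIV", "BP_RIV", "OKN_NONRIV", "OKN_RIV"):
            imgs = [r.images[img_key] for r in members if img_key in r.images]
            if imgs:
                group_images[f"{g}_{img_key}"] = ti.TrialImage(
                    values=ti.average_images([im.values for im in imgs]),
                    time_s=imgs[0].time_s,
                )

    return CohortResult(
        subjects=results,
        trials=trials,
        qc_subjects=pd.DataFrame(qc_rows),
        latencies=lat,
        stats=stats,
        group_images=group_images,
    )


def write_cohort_tables(res: CohortResult, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("trials", res.trials),
        ("qc_subjects", res.qc_subjects),
        ("latencies", res.latencies),
        ("stats", res.stats),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    curves_rows = []
    for r in res.subjects:
        for cond, c in r.mean_consistency.items():
            for t, v in zip(r.bp_time_s, c):
                curves_rows.append(
                    {"subject": r.subject_id, "signal": "BP", "condition": cond,
                     "time_s": t, "value": v}
                )
        for cond, c in r.mean_velocity.items():
            for t, v in zip(r.okn_time_s, c):
                curves_rows.append(
                    {"subject": r.subject_id, "signal": "OKN", "condition": cond,
                     "time_s": t, "value": v}
                )
        for (sig, cond), curve in r.discrim.items():
            for t, v in zip(curve.time_s, curve.d):
                curves_rows.append(
                    {"subject": r.subject_id, "signal": f"{sig}_discrim",
                     "condition": cond, "time_s": t, "value": v}
                )
    p = outdir / "curves.tsv"
    pd.DataFrame(curves_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths["curves"] = p
    for name, img in res.group_images.items():
        p = outdir / f"image_{name}.tsv"
        np.savetxt(p, img.values, delimiter="\t", fmt="%.5g")
        paths[f"image_{name}"] = p
    return paths
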