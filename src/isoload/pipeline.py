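"""End-to-end session analysis and study-level orchestration.

Glues the stages together: segment a recording into repetitions, derive the
per-repetition mechanics and EMG features, summarize systemic responses,
assemble the training-load record, and — across a cohort — calibrate the
fatigue rate constant from the intensity dependence of the peak-RFD decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .load import (
    DEFAULT_ALPHA,
    AlphaCalibration,
    TLRecord,
    calibrate_alpha,
    rpe_indexes,
    tl_rfd,
    tl_rfd_density,
    tl_rfd_star,
    volume_load,
)
from .neuromech import emg_rep_features, fatigue_slopes, session_rep_table
from .signals import RepetitionSegment, UniformSignal, segment_repetitions
from .synth import (
    NoiseConfig,
    ParticipantTruth,
    ProtocolSpec,
    SessionRecording,
    default_protocols,
    generate_participant,
    generate_session,
)
from .systemic import hr_from_rr, hr_recovery, marker_deltas, nirs_features, vo2_kinetics

logger = logging.getLogger(__name__)

__all__ = [
    "StudySession",
    "segment_recording",
    "analyze_mech",
    "session_tl_record",
    "session_systemic_summary",
    "simulate_study",
    "mean_rfd_slopes",
    "calibrate_from_study",
    "study_tables",
]


@dataclass
class StudySession:
    participant: ParticipantTruth
    protocol: ProtocolSpec
    recording: SessionRecording


def segment_recording(rec: SessionRecording, **kwargs) -> list[RepetitionSegment]:
    """Repetition segments of a recording from its velocity channel."""
    if rec.mech is None:
        raise ValueError("recording has no mechanical channels")
    vel = UniformSignal(rec.mech.fs, rec.mech.velocity)
    return segment_repetitions(
        vel, proto_velocity=rec.protocol.angular_velocity,
        rest_thresh_s=kwargs.pop("rest_thresh_s", 5.0), **kwargs)


def analyze_mech(rec: SessionRecording, mvc: float,
                 segs: list[RepetitionSegment] | None = None
                 ) -> tuple[pd.DataFrame, list]:
    """Per-repetition metrics table and per-session fatigue slopes."""
    if segs is None:
        segs = segment_recording(rec)
    table = session_rep_table(rec.mech, segs, mvc)
    return table, fatigue_slopes(table)


def session_tl_record(
    rec: SessionRecording,
    rep_table: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    alpha_source: str = "paper_default",
) -> TLRecord:
    """All training-load indexes of one session.

    Repetition counts and intensity come from the protocol; the impulse sum
    for TL_RFD* and the mechanical work come from the per-repetition table
    when available.
    """
    proto = rec.protocol
    I = proto.relative_intensity
    R = proto.total_rest_s
    vl, dens_vl = volume_load([proto.reps_per_set] * proto.n_sets, I, R)
    tl = tl_rfd(proto.n_reps, I, alpha)
    wmech = star = None
    if rep_table is not None and len(rep_table):
        wmech = float(rep_table["work"].sum()) / 1000.0  # kJ
        star = tl_rfd_star(rep_table["impulse"].to_list(), I, alpha)
    duration_min = rec.session_duration_s / 60.0
    rpe_fam = rpe_indexes(rec.rpe, rec.cr10, duration_min, proto.n_reps, R)
    return TLRecord(
        vl=vl, dens_vl=dens_vl, wmech=wmech, rpe=rec.rpe, cr10=rec.cr10,
        srpe=rpe_fam["srpe"], srpe_cr10=rpe_fam["srpe_cr10"],
        dens_rpe=rpe_fam["dens_rpe"], dens_rpe_cr10=rpe_fam["dens_rpe_cr10"],
        tl_rfd=tl, tl_rfd_dens=tl_rfd_density(tl, R), tl_rfd_star=star,
        alpha=alpha, alpha_source=alpha_source,
    )


def session_systemic_summary(rec: SessionRecording,
                             segs: list[RepetitionSegment] | None = None) -> dict:
    """HR/VO2/NIRS/lactate features of one session (channels that exist)."""
    out: dict = {}
    ev = rec.events
    ex_win = (ev["exercise_start_s"], ev["exercise_end_s"])
    rec_win = (ev["exercise_end_s"] + 2.0, rec.session_duration_s - 1.0)
    base_win = (0.0, ev["exercise_start_s"] - 1.0)
    if rec.rr_intervals is not None:
        hr = hr_from_rr(rec.rr_intervals)
        # inset the fit window so the 10 s moving average stays inside recovery
        fit_win = (rec_win[0] + 6.0, min(rec_win[1], hr.time[-1]) - 6.0)
        out["hr_recovery"] = hr_recovery(hr, fit_win, t_ref=ev["exercise_end_s"])
    if rec.vo2 is not None:
        out["vo2"] = vo2_kinetics(rec.vo2, ex_win, rec_win, base_win)
    if rec.nirs is not None and rec.mech is not None:
        if segs is None:
            segs = segment_recording(rec)
        windows: dict[int, list[tuple[float, float]]] = {}
        for s in segs:
            windows.setdefault(s.series, []).append(
                (s.i0 / rec.mech.fs, s.i1 / rec.mech.fs))
        out["nirs"] = nirs_features(rec.nirs, windows, base_win, ex_win)
    if rec.lactate is not None:
        out["markers"] = marker_deltas(rec.lactate)
    return out


# ---------------------------------------------------------------------------
# Study-level orchestration
# ---------------------------------------------------------------------------

def simulate_study(
    n_participants: int = 15,
    seed: int = 0,
    protocols: dict[str, ProtocolSpec] | None = None,
    noise: NoiseConfig | None = None,
    channels: tuple[str, ...] = ("mech", "lactate", "rpe"),
    participant_config: dict | None = None,
) -> list[StudySession]:
    """Simulate a cohort: every participant performs every protocol.

    Per-participant and per-session seeds are spawned deterministically
    from the study seed.
    """
    protocols = protocols or default_protocols()
    root = np.random.SeedSequence(seed)
    p_seeds = root.spawn(n_participants)
    sessions: list[StudySession] = []
    for i, ps in enumerate(p_seeds):
        p_seed = int(ps.generate_state(1)[0] % (2**31))
        participant = generate_participant(p_seed, participant_config,
                                           pid=f"P{i + 1:02d}")
        for j, (label, proto) in enumerate(sorted(protocols.items())):
            s_seed = int(ps.spawn(j + 1)[-1].generate_state(1)[0] % (2**31))
            rec = generate_session(participant, proto, s_seed,
                                   noise=noise, channels=channels)
            sessions.append(StudySession(participant, proto, rec))
    return sessions


def mean_rfd_slopes(study: list[StudySession]
                    ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-intensity mean of the per-session peak-RFD decay slopes."""
    rows = []
    for s in study:
        table, slopes = analyze_mech(s.recording, s.participant.mvc)
        by_name = {f.metric: f for f in slopes}
        if "rfd_peak" not in by_name:
            logger.warning("session %s/%s: no RFD slope",
                           s.participant.id, s.protocol.label)
            continue
        rows.append({"participant": s.participant.id,
                     "label": s.protocol.label,
                     "intensity": s.protocol.relative_intensity,
                     "rfd_peak_slope": by_name["rfd_peak"].slope})
    df = pd.DataFrame(rows)
    agg = df.groupby("intensity")["rfd_peak_slope"].mean().sort_index()
    return agg.index.to_numpy(float), agg.to_numpy(float), df


def calibrate_from_study(study: list[StudySession],
                         fix_asymptote_zero: bool = True) -> AlphaCalibration:
    """Fatigue-constant calibration from a full simulated (or measured) study."""
    intensities, slopes, _ = mean_rfd_slopes(study)
    return calibrate_alpha(list(slopes), list(intensities),
                           fix_asymptote_zero=fix_asymptote_zero)


def study_tables(
    study: list[StudySession],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature and response tables, one row per (participant, session).

    Features: training-load indexes plus training parameters. Responses:
    whatever physiological summaries the generated channels support
    (lactate deltas always when present; RFD slope from mechanics; EMG,
    HR, VO2 and NIRS summaries when those channels exist).
    """
    feats, resps, index = [], [], []
    for s in study:
        rec = s.recording
        segs = segment_recording(rec)
        table, slopes = analyze_mech(rec, s.participant.mvc, segs)
        tl = session_tl_record(rec, table, alpha=alpha)
        proto = s.protocol
        f = {
            "vl": tl.vl, "tl_rfd": tl.tl_rfd, "tl_rfd_star": tl.tl_rfd_star,
            "wmech": tl.wmech, "srpe": tl.srpe, "srpe_cr10": tl.srpe_cr10,
            "rpe": tl.rpe, "cr10": tl.cr10,
            "intensity": proto.relative_intensity,
            "velocity": proto.angular_velocity,
            "reps": proto.n_reps, "rest_s": proto.total_rest_s,
            "impulse": float(table["impulse"].sum()),
            "tut": float(table["tut"].sum()),
        }
        r: dict = {}
        by_name = {x.metric: x for x in slopes}
        if "rfd_peak" in by_name:
            r["rfd_peak_slope"] = by_name["rfd_peak"].slope
        syst = session_systemic_summary(rec, segs)
        if "markers" in syst:
            r["lact_delta_peak"] = syst["markers"]["lact_delta_peak"]
        if "vo2" in syst:
            r["ee_total_kj"] = syst["vo2"]["ee_total_kj"]
        if "hr_recovery" in syst:
            r["hr_recovery_amplitude"] = syst["hr_recovery"].amplitude
        if "nirs" in syst:
            r["hbdiff_rate"] = syst["nirs"]["hbdiff_rate"]
        if rec.emg is not None:
            emg_table = emg_rep_features(rec.emg, segs, rec.mech.fs)
            merged = table[["idx"]].merge(emg_table, on="idx")
            emg_slopes = fatigue_slopes(merged, metrics=("mdf_mean",))
            if emg_slopes:
                r["mdf_slope"] = emg_slopes[0].slope
        feats.append(f)
        resps.append(r)
        index.append((s.participant.id, proto.label))
    idx = pd.MultiIndex.from_tuples(index, names=["participant", "session"])
    return (pd.DataFrame(feats, index=idx), pd.DataFrame(resps, index=idx))
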