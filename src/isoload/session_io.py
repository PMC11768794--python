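"""Reading and writing session directories.

A session is a directory of delimited-text channel files plus JSON
metadata:

    mech.csv   t_s, torque, velocity, position   (148 Hz default)
    emg.csv    t_s, vlat, vmed, rfem             (2048 Hz default)
    rr.csv     rr_s                              (one interval per row)
    vo2.csv    t_s, vo2
    nirs.csv   t_s, do2hb, dhhb, tsi
    meta.json  protocol, events, RPE/CR10, lactate samples
    truth.json generator ground truth (synthetic sessions only)
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import (
    EMGChannels,
    MechChannels,
    NIRSChannels,
    ProtocolSpec,
    SampledSeries,
    SessionRecording,
    SessionTruth,
)

__all__ = ["write_session", "read_session"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a recording as a directory of CSV channels + JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if rec.mech is not None:
        pd.DataFrame({
            "t_s": rec.mech.time, "torque": rec.mech.torque,
            "velocity": rec.mech.velocity, "position": rec.mech.position,
        }).to_csv(path / "mech.csv", index=False)
    if rec.emg is not None:
        t = rec.emg.t0 + np.arange(rec.emg.vlat.size) / rec.emg.fs
        pd.DataFrame({"t_s": t, "vlat": rec.emg.vlat, "vmed": rec.emg.vmed,
                      "rfem": rec.emg.rfem}).to_csv(path / "emg.csv", index=False)
    if rec.rr_intervals is not None:
        pd.DataFrame({"rr_s": rec.rr_intervals}).to_csv(path / "rr.csv", index=False)
    if rec.vo2 is not None:
        pd.DataFrame({"t_s": rec.vo2.t, "vo2": rec.vo2.values}
                     ).to_csv(path / "vo2.csv", index=False)
    if rec.nirs is not None:
        pd.DataFrame({"t_s": rec.nirs.t, "do2hb": rec.nirs.do2hb,
                      "dhhb": rec.nirs.dhhb, "tsi": rec.nirs.tsi}
                     ).to_csv(path / "nirs.csv", index=False)
    meta = {
        "participant": rec.participant,
        "protocol": asdict(rec.protocol),
        "events": rec.events,
        "rpe": rec.rpe,
        "cr10": rec.cr10,
        "lactate": rec.lactate,
        "session_duration_s": rec.session_duration_s,
    }
    (path / "meta.json").write_text(json.dumps(_jsonable(meta), indent=1))
    (path / "truth.json").write_text(
        json.dumps(_jsonable(asdict(rec.truth)), indent=1))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Load a session directory written by :func:`write_session`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    proto = ProtocolSpec(**meta["protocol"])

    mech = emg = vo2 = nirs = rr = None
    if (path / "mech.csv").exists():
        df = pd.read_csv(path / "mech.csv")
        mech = MechChannels(fs=proto.fs_mech,
                            torque=df["torque"].to_numpy(),
                            velocity=df["velocity"].to_numpy(),
                            position=df["position"].to_numpy(),
                            t0=float(df["t_s"].iloc[0]))
    if (path / "emg.csv").exists():
        df = pd.read_csv(path / "emg.csv")
        emg = EMGChannels(fs=proto.fs_emg, vlat=df["vlat"].to_numpy(),
                          vmed=df["vmed"].to_numpy(), rfem=df["rfem"].to_numpy(),
                          t0=float(df["t_s"].iloc[0]))
    if (path / "rr.csv").exists():
        rr = pd.read_csv(path / "rr.csv")["rr_s"].to_numpy()
    if (path / "vo2.csv").exists():
        df = pd.read_csv(path / "vo2.csv")
        vo2 = SampledSeries(t=df["t_s"].to_numpy(), values=df["vo2"].to_numpy())
    if (path / "nirs.csv").exists():
        df = pd.read_csv(path / "nirs.csv")
        nirs = NIRSChannels(t=df["t_s"].to_numpy(), do2hb=df["do2hb"].to_numpy(),
                            dhhb=df["dhhb"].to_numpy(), tsi=df["tsi"].to_numpy())

    truth = SessionTruth(n_reps=proto.n_reps, rep_start_s=np.array([]),
                         rep_dur_s=np.array([]), rep_series=np.array([]),
                         peak_torque=np.array([]), ramp_s=np.array([]),
                         rfd_peak=np.array([]), rfd_0_100=np.array([]),
                         impulse=np.array([]), work=np.array([]),
                         rfd_slope=np.nan, mdf_hz=np.array([]),
                         emg_gain=np.array([]))
    if (path / "truth.json").exists():
        raw = json.loads((path / "truth.json").read_text())
        array_fields = {"rep_start_s", "rep_dur_s", "rep_series", "peak_torque",
                        "ramp_s", "rfd_peak", "rfd_0_100", "impulse", "work",
                        "mdf_hz", "emg_gain"}
        truth = SessionTruth(**{k: (np.asarray(v) if k in array_fields else v)
                                for k, v in raw.items()})

    return SessionRecording(
        participant=meta["participant"], protocol=proto, mech=mech, emg=emg,
        rr_intervals=rr, vo2=vo2, nirs=nirs, lactate=meta.get("lactate"),
        rpe=meta.get("rpe"), cr10=meta.get("cr10"),
        session_duration_s=meta["session_duration_s"],
        events=meta["events"], truth=truth,
    )
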