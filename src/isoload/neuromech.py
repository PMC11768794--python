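"""Per-repetition mechanical and EMG fatigue metrics.

From the torque/velocity/position channels of a segmented session this
module derives, for every repetition: mechanical work (integral of torque
over joint angle), torque impulse (integral of torque over time), the rate
of force development over the first 100 ms after torque onset (RFD0-100),
the peak rate of force development (RFDpeak), time under tension, and
normalized torque. From the EMG channels it derives per-repetition RMS
amplitude (normalized to the first repetition) and median frequency.
Per-session fatigue slopes are the ordinary-least-squares regressions of a
metric against the cumulative repetition index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import DataError, ParameterError
from .signals import (
    RepetitionSegment,
    UniformSignal,
    butter_lowpass,
    linear_slope,
    median_frequency,
    stft_psd,
)
from .synth import MechChannels, EMGChannels

logger = logging.getLogger(__name__)

__all__ = [
    "RepMetrics",
    "FatigueSlopes",
    "torque_onset",
    "rep_metrics",
    "session_rep_table",
    "emg_rep_features",
    "fatigue_slopes",
]

MUSCLES = ("vlat", "vmed", "rfem")


@dataclass
class RepMetrics:
    idx: int
    series: int
    work: float          # J
    impulse: float       # N.m.s
    rfd_0_100: float     # N.m/s (nan when the rep is too short)
    rfd_peak: float      # N.m/s
    peak_torque: float   # N.m
    mean_torque: float   # N.m
    norm_torque: float   # %MVC
    tut: float           # s


@dataclass
class FatigueSlopes:
    metric: str
    slope: float
    intercept: float
    r2: float
    n_reps: int


def torque_onset(torque: UniformSignal, seg: RepetitionSegment,
                 onset_frac: float = 0.025) -> int | None:
    """Torque-onset sample of one repetition.

    Scanning backward from the in-segment torque peak, the onset is the
    last sample at or below ``onset_frac`` of the peak. Returns ``None``
    (missing, logged) when the segment holds no torque rise.
    """
    t = torque.values[seg.i0:seg.i1]
    peak = t.max()
    if peak <= 0 or np.ptp(t) == 0:
        logger.warning("rep %d: flat torque, onset undetectable", seg.idx)
        return None
    ipk = int(np.argmax(t))
    thresh = onset_frac * peak
    below = np.flatnonzero(t[: ipk + 1] <= thresh)
    onset_rel = int(below[-1]) if below.size else 0
    return seg.i0 + onset_rel


def _smoothed_slope(values: np.ndarray, fs: float, window: int = 5) -> np.ndarray:
    """Local-polynomial (Savitzky-Golay) first derivative."""
    if values.size < window:
        return np.gradient(values) * fs
    return savgol_filter(values, window_length=window, polyorder=2,
                         deriv=1, delta=1.0 / fs)


def rep_metrics(
    mech: MechChannels,
    seg: RepetitionSegment,
    mvc: float,
    filtered_torque: np.ndarray | None = None,
    rfd_peak_mode: str = "instantaneous",
    sg_window: int = 5,
) -> RepMetrics:
    """All mechanical metrics of one repetition.

    RFD0-100 is the two-point secant of the raw torque over exactly 100 ms
    from onset (torque linearly interpolated at onset + 100 ms); RFDpeak is
    the maximum of the smoothed derivative of the 10 Hz low-passed torque
    (``instantaneous``) or the maximum 100 ms windowed mean slope
    (``windowed``). Impulse and work are trapezoidal integrals of torque
    over time and joint angle over the full segment.
    """
    if mvc <= 0:
        raise ParameterError("mvc must be positive")
    fs = mech.fs
    sl = slice(seg.i0, seg.i1)
    t_raw = mech.torque[sl]
    time = np.arange(seg.i0, seg.i1) / fs
    theta = mech.position[sl]

    impulse = float(np.trapezoid(t_raw, time))
    work = float(np.trapezoid(t_raw, theta))
    peak_torque = float(t_raw.max())
    mean_torque = float(t_raw.mean())
    tut = (seg.i1 - seg.i0) / fs

    if filtered_torque is None:
        filtered_torque = butter_lowpass(
            UniformSignal(fs, mech.torque), cutoff=10.0, order=2).values
    t_filt = filtered_torque[sl]

    onset = torque_onset(UniformSignal(fs, mech.torque), seg)
    rfd_0_100 = np.nan
    if onset is not None:
        # refine the onset to the sub-sample threshold crossing so the
        # 100 ms secant is free of sample-phase jitter
        thresh = 0.025 * peak_torque
        t_on = onset / fs
        torque_at_onset = float(mech.torque[onset])
        nxt = onset + 1
        if nxt < seg.i1 and mech.torque[nxt] > thresh >= torque_at_onset:
            frac = (thresh - torque_at_onset) / (mech.torque[nxt] - torque_at_onset)
            t_on += frac / fs
            torque_at_onset = thresh
        t_end = t_on + 0.1
        if t_end <= time[-1]:
            torque_at_end = float(np.interp(t_end, time, t_raw))
            rfd_0_100 = (torque_at_end - torque_at_onset) / 0.1
        else:
            logger.warning("rep %d shorter than 100 ms after onset", seg.idx)

    if rfd_peak_mode == "instantaneous":
        rfd_peak = float(_smoothed_slope(t_filt, fs, sg_window).max())
    elif rfd_peak_mode == "windowed":
        w = max(1, int(round(0.1 * fs)))
        if t_filt.size > w:
            rfd_peak = float(((t_filt[w:] - t_filt[:-w]) * fs / w).max())
        else:
            rfd_peak = float((t_filt[-1] - t_filt[0]) / ((t_filt.size - 1) / fs))
    else:
        raise ParameterError("rfd_peak_mode must be 'instantaneous' or 'windowed'")

    return RepMetrics(
        idx=seg.idx, series=seg.series, work=work, impulse=impulse,
        rfd_0_100=rfd_0_100, rfd_peak=rfd_peak, peak_torque=peak_torque,
        mean_torque=mean_torque, norm_torque=100.0 * mean_torque / mvc, tut=tut,
    )


def session_rep_table(mech: MechChannels, segs: list[RepetitionSegment],
                      mvc: float, **kwargs) -> pd.DataFrame:
    """Tidy per-repetition metrics table (one row per repetition)."""
    filt = butter_lowpass(UniformSignal(mech.fs, mech.torque), 10.0, 2).values
    rows = [rep_metrics(mech, s, mvc, filtered_torque=filt, **kwargs)
            for s in segs]
    return pd.DataFrame([r.__dict__ for r in rows])


def emg_rep_features(
    emg: EMGChannels,
    segs: list[RepetitionSegment],
    fs_mech: float,
    envelope_points: int = 101,
) -> pd.DataFrame:
    """Per-repetition EMG amplitude and median-frequency features.

    Chain per muscle: rectification, 10 Hz second-order zero-phase
    Butterworth low-pass, per-repetition RMS of the envelope, then
    normalization to the first repetition's mean (repetition 1 maps to
    1.0). The median frequency is computed from short-time (250 ms window,
    125 ms hop) power spectra of the raw signal and averaged over the
    windows falling inside the repetition; ``mdf_mean`` averages the three
    muscles.

    Columns: rms_<muscle>, mdf_<muscle>, mdf_mean, plus a time-normalized
    ``envelope_<muscle>`` array (``envelope_points`` samples per rep).
    """
    if not segs:
        raise DataError("no repetitions to extract EMG features from")
    records: list[dict] = [
        {"idx": s.idx, "series": s.series} for s in segs]
    for name, raw in emg.muscles.items():
        env = butter_lowpass(UniformSignal(emg.fs, np.abs(raw)), 10.0, 2).values
        psd = stft_psd(UniformSignal(emg.fs, raw))
        rms_vals, mdf_vals, envelopes = [], [], []
        for s in segs:
            t0, t1 = s.i0 / fs_mech, s.i1 / fs_mech
            j0, j1 = int(round(t0 * emg.fs)), int(round(t1 * emg.fs))
            j1 = min(j1, env.size)
            seg_env = env[j0:j1]
            rms_vals.append(float(np.sqrt(np.mean(seg_env**2))))
            grid = np.linspace(0.0, 1.0, envelope_points)
            envelopes.append(np.interp(grid, np.linspace(0, 1, seg_env.size), seg_env))
            in_rep = (psd.window_times >= t0) & (psd.window_times <= t1)
            if in_rep.any():
                mdfs = [median_frequency(psd.freqs, row)
                        for row in psd.power[in_rep] if row.sum() > 0]
                mdf_vals.append(float(np.mean(mdfs)) if mdfs else np.nan)
            else:
                mdf_vals.append(np.nan)
        ref = rms_vals[0]
        if ref <= 0:
            raise DataError(f"first-repetition RMS of {name} is zero; "
                            "cannot normalize")
        for rec, r, m, e in zip(records, rms_vals, mdf_vals, envelopes):
            rec[f"rms_{name}"] = r / ref
            rec[f"mdf_{name}"] = m
            rec[f"envelope_{name}"] = e
    df = pd.DataFrame(records)
    df["mdf_mean"] = df[[f"mdf_{m}" for m in MUSCLES]].mean(axis=1)
    return df


def fatigue_slopes(rep_table: pd.DataFrame,
                   metrics: tuple[str, ...] = ("rfd_peak", "rfd_0_100",
                                               "mdf_mean", "peak_torque"),
                   ) -> list[FatigueSlopes]:
    """OLS slope of each metric against the cumulative repetition index.

    Metrics with fewer than three non-missing repetitions are skipped with
    a log entry.
    """
    out: list[FatigueSlopes] = []
    for metric in metrics:
        if metric not in rep_table.columns:
            continue
        sub = rep_table[["idx", metric]].dropna()
        if len(sub) < 3:
            logger.warning("metric %s has < 3 repetitions; slope skipped", metric)
            continue
        fit = linear_slope(sub["idx"].to_numpy(float), sub[metric].to_numpy(float))
        out.append(FatigueSlopes(metric=metric, slope=fit.slope,
                                 intercept=fit.intercept, r2=fit.r2,
                                 n_reps=len(sub)))
    return out
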