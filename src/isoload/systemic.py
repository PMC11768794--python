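"""Systemic response features: heart rate, gas exchange, NIRS, blood markers.

Heart rate is reconstructed from R-R intervals, resampled to 1 Hz and
smoothed with a 10 s moving average; its recovery is summarized by a
mono-exponential fit. Breath-by-breath oxygen uptake is interpolated to a
second-by-second grid; the exercise response is summarized by a linear
slope, the recovery by a mono-exponential fit, and net energy expenditure
uses the 21.3 J per millilitre of O2 equivalent. NIRS contraction features
use the oxygenation index dHbdiff = dO2Hb - dHHb, whose within-contraction
decline rate proxies muscle oxygen consumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, DegenerateInputError, ParameterError
from .signals import (
    MonoExpFit,
    UniformSignal,
    fit_monoexp,
    linear_slope,
    moving_average,
)
from .synth import NIRSChannels, SampledSeries

logger = logging.getLogger(__name__)

__all__ = [
    "O2_ENERGY_EQUIVALENT_J_PER_ML",
    "RecoveryKinetics",
    "SystemicSummary",
    "hr_from_rr",
    "rr_from_hr",
    "interpolate_breaths",
    "energy_expenditure",
    "vo2_kinetics",
    "nirs_features",
    "marker_deltas",
]

#: Energy released per millilitre of oxygen consumed (glycolytic mix).
O2_ENERGY_EQUIVALENT_J_PER_ML = 21.3


@dataclass
class RecoveryKinetics:
    channel: str
    fit: MonoExpFit
    amplitude: float  # gain b, channel units
    rate: float       # alpha, 1/s (negative for an accepted recovery)
    window: tuple[float, float]
    accepted: bool = True


@dataclass
class SystemicSummary:
    hr_recovery: RecoveryKinetics | None = None
    vo2_exercise_slope: float | None = None
    vo2_recovery: RecoveryKinetics | None = None
    ee_exercise_kj: float | None = None
    ee_total_kj: float | None = None
    lact_delta_1min: float | None = None
    lact_delta_3min: float | None = None
    lact_delta_peak: float | None = None
    cort_delta: float | None = None
    hbdiff_rate: float | None = None
    tsi_delta: float | None = None


def hr_from_rr(rr: np.ndarray, smooth_s: float = 10.0) -> UniformSignal:
    """Heart-rate curve (bpm) from R-R intervals.

    Instantaneous HR (60 / RR) at the cumulative beat times is resampled to
    1 Hz and smoothed with a ``smooth_s`` bin moving average.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise DegenerateInputError("need at least two R-R intervals")
    if np.any(rr <= 0):
        raise DataError("R-R intervals must be positive")
    t_beats = np.cumsum(rr)
    hr_inst = 60.0 / rr
    grid = np.arange(0.0, t_beats[-1] + 1.0)
    hr = np.interp(grid, t_beats, hr_inst)
    return moving_average(UniformSignal(1.0, hr, 0.0), smooth_s)


def rr_from_hr(hr: UniformSignal, duration_s: float | None = None) -> np.ndarray:
    """Generate R-R intervals stepping through a heart-rate curve (inverse
    of :func:`hr_from_rr` up to smoothing)."""
    if duration_s is None:
        duration_s = hr.duration
    t_grid = hr.time
    beats = []
    t = 0.0
    while t < duration_s:
        h = float(np.interp(t, t_grid, hr.values))
        if h <= 0:
            raise DataError("heart rate must be positive")
        step = 60.0 / h
        beats.append(step)
        t += step
    return np.asarray(beats)


def interpolate_breaths(vo2: SampledSeries) -> UniformSignal:
    """Linear interpolation of breath-stamped VO2 onto a 1 s grid."""
    t = np.asarray(vo2.t, dtype=float)
    v = np.asarray(vo2.values, dtype=float)
    if t.size < 2:
        raise DegenerateInputError("need at least two breaths")
    if np.any(np.diff(t) <= 0):
        raise DataError("breath times must be strictly increasing")
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1.0)
    return UniformSignal(1.0, np.interp(grid, t, v), float(grid[0]))


def energy_expenditure(vo2_net: UniformSignal,
                       window: tuple[float, float] | None = None) -> float:
    """Net energy expenditure (kJ) from baseline-subtracted VO2 (mL/min).

    EE = 21.3 J/mL x integral of net VO2 over the window; VO2 in mL/min is
    converted to mL/s before integration.
    """
    t, v = vo2_net.time, vo2_net.values
    if window is not None:
        a, b = max(t[0], window[0]), min(t[-1], window[1])
        if b <= a:
            raise ParameterError("window outside the recording")
        inner = t[(t > a) & (t < b)]
        tt = np.concatenate([[a], inner, [b]])
        v = np.interp(tt, t, v)
        t = tt
    ml = float(np.trapezoid(v / 60.0, t))
    return ml * O2_ENERGY_EQUIVALENT_J_PER_ML / 1000.0


def _fit_recovery(sig: UniformSignal, window: tuple[float, float],
                  channel: str, t_ref: float | None = None) -> RecoveryKinetics:
    seg = sig.slice_time(*window)
    fit = fit_monoexp(seg.time - seg.time[0], seg.values, rate_sign=-1)
    accepted = bool(fit.converged and np.isfinite(fit.alpha) and fit.alpha < 0)
    if not accepted:
        logger.warning("%s recovery fit rejected (converged=%s, alpha=%s)",
                       channel, fit.converged, fit.alpha)
    # amplitude referenced to the recovery onset (the fit window may start
    # later to avoid smoothing edge effects)
    amp = fit.b
    if t_ref is not None and accepted:
        amp = fit.b * np.exp(fit.alpha * (t_ref - seg.time[0]))
    return RecoveryKinetics(channel=channel, fit=fit, amplitude=float(amp),
                            rate=fit.alpha, window=window, accepted=accepted)


def hr_recovery(hr: UniformSignal, window: tuple[float, float],
                t_ref: float | None = None) -> RecoveryKinetics:
    """Mono-exponential fit of the heart-rate recovery."""
    return _fit_recovery(hr, window, "hr", t_ref=t_ref)


def vo2_kinetics(
    vo2: SampledSeries,
    exercise_window: tuple[float, float],
    recovery_window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> dict:
    """Exercise slope, recovery kinetics and energy expenditure of VO2.

    The exercise slope is the OLS slope of second-by-second VO2 against
    time over the exercise window; the recovery is a mono-exponential fit.
    The baseline for net values is the mean over ``baseline_window``
    (default: everything before the exercise window).
    """
    sig = interpolate_breaths(vo2)
    ex = sig.slice_time(*exercise_window)
    slope_fit = linear_slope(ex.time, ex.values)
    rec = _fit_recovery(sig, recovery_window, "vo2", t_ref=exercise_window[1])
    if baseline_window is None:
        baseline_window = (sig.t0, exercise_window[0])
    base = float(np.mean(sig.slice_time(*baseline_window).values))
    net = UniformSignal(sig.fs, sig.values - base, sig.t0)
    ee_ex = max(0.0, energy_expenditure(net, exercise_window))
    ee_total = max(0.0, energy_expenditure(net, (exercise_window[0], sig.time[-1])))
    return {
        "exercise_slope": slope_fit.slope,
        "exercise_r2": slope_fit.r2,
        "recovery": rec,
        "baseline": base,
        "ee_exercise_kj": ee_ex,
        "ee_total_kj": ee_total,
    }


def nirs_features(
    nirs: NIRSChannels,
    rep_windows_by_series: dict[int, list[tuple[float, float]]],
    baseline_window: tuple[float, float],
    exercise_window: tuple[float, float],
    candidates_per_series: int = 3,
) -> dict:
    """Oxygenation-index decline rate and TSI shift.

    dHbdiff = dO2Hb - dHHb. Per series, the decline rate is the linear
    slope of dHbdiff over one of the first ``candidates_per_series``
    repetitions — the one whose linear fit has the highest r^2 (the most
    representative early contraction). ``tsi_delta`` is mean TSI during
    exercise minus mean TSI at baseline.
    """
    t = np.asarray(nirs.t, dtype=float)
    hbdiff = np.asarray(nirs.do2hb, dtype=float) - np.asarray(nirs.dhhb, dtype=float)
    rates: dict[int, float] = {}
    for series, windows in rep_windows_by_series.items():
        best_rate, best_r2 = None, -np.inf
        for (a, b) in windows[:candidates_per_series]:
            mask = (t >= a) & (t < b)
            if mask.sum() < 3:
                continue
            if np.ptp(hbdiff[mask]) == 0:
                best_rate, best_r2 = 0.0, max(best_r2, 0.0)
                continue
            fit = linear_slope(t[mask], hbdiff[mask])
            if fit.r2 > best_r2:
                best_rate, best_r2 = fit.slope, fit.r2
        if best_rate is None:
            logger.warning("series %d: no usable NIRS repetition window", series)
        else:
            rates[series] = float(best_rate)
    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    ex_mask = (t >= exercise_window[0]) & (t < exercise_window[1])
    if not base_mask.any() or not ex_mask.any():
        raise ParameterError("baseline/exercise window outside NIRS recording")
    tsi_delta = float(np.mean(nirs.tsi[ex_mask]) - np.mean(nirs.tsi[base_mask]))
    amplitude = float(hbdiff[ex_mask].min() - np.mean(hbdiff[base_mask]))
    return {
        "hbdiff_rate_by_series": rates,
        "hbdiff_rate": float(np.mean(list(rates.values()))) if rates else None,
        "tsi_delta": tsi_delta,
        "hbdiff_amplitude": amplitude,
    }


def marker_deltas(lactate: dict, cortisol: tuple[float, float] | None = None,
                  reference: str = "t_onset") -> dict:
    """Blood-marker changes relative to the pre-exercise reference sample.

    ``lactate`` maps sample labels (t_baseline, t_onset, t_post1, t_post3)
    to concentrations; the reference defaults to the onset sample (taken
    after the warm-up, immediately before exercise). Missing samples leave
    the corresponding delta missing.
    """
    if reference not in lactate or lactate[reference] is None:
        raise DataError(f"reference lactate sample {reference!r} missing")
    ref = float(lactate[reference])
    d1 = (float(lactate["t_post1"]) - ref
          if lactate.get("t_post1") is not None else None)
    d3 = (float(lactate["t_post3"]) - ref
          if lactate.get("t_post3") is not None else None)
    present = [d for d in (d1, d3) if d is not None]
    peak = max(present) if present else None
    cort = (float(cortisol[1]) - float(cortisol[0])) if cortisol is not None else None
    return {"lact_delta_1min": d1, "lact_delta_3min": d3,
            "lact_delta_peak": peak, "cort_delta": cort}
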